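"""Pixel-wise mono-exponential T2* relaxometry of multi-echo magnitude stacks.

The signal model is the standard gradient-echo magnitude decay

    S(TE) = S0 * exp(-TE / T2*)

fit independently at every pixel of a multi-gradient-echo (MGE) series.
T2* is reported in ms; the relaxation rate R2* = 1000 / T2* in s^-1.
Echoes whose magnitude falls at or below a configurable noise floor are
excluded from the fit, which limits the Rician-floor bias at long echo
times when fitting magnitude data directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "T2MAX",
    "EchoSeries",
    "RelaxationMap",
    "DecayFit",
    "fit_decay",
    "fit_map",
]

#: Cap on fitted T2* (ms) for non-decaying pixels; keeps R2* finite (~0).
T2MAX = 1000.0

#: Minimum number of usable (above-floor) echoes for a fit to be valid.
MIN_ECHOES = 4


@dataclass
class EchoSeries:
    """A multi-echo magnitude image stack with its echo-time vector.

    Parameters
    ----------
    stack : ndarray, shape (n_echoes, rows, cols)
        Magnitude images, one per echo, arbitrary signal units, all >= 0.
    echo_times : ndarray, shape (n_echoes,)
        Echo times in ms, strictly increasing and positive.
    pixel_size : float
        Edge length of one pixel in mm.
    """

    stack: np.ndarray
    echo_times: np.ndarray
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.stack.ndim != 3:
            raise ValueError("stack must be (n_echoes, rows, cols)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.stack.shape[0]:
            raise ValueError("echo_times length must match number of echoes")
        if self.echo_times.size < 3:
            raise ValueError("need at least 3 echoes")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        if np.any(self.stack < 0):
            raise ValueError("magnitude images must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_echoes(self) -> int:
        return self.stack.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    @property
    def pixel_area(self) -> float:
        """Pixel area in mm^2."""
        return self.pixel_size**2


@dataclass
class RelaxationMap:
    """Per-pixel results of mono-exponential fitting.

    Invariant: wherever ``valid``, ``t2star > 0`` and
    ``r2star == 1000 / t2star`` (ms -> s^-1).
    """

    s0: np.ndarray
    t2star: np.ndarray
    r2star: np.ndarray
    fit_r2: np.ndarray
    valid: np.ndarray
    pixel_area: float
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros(self.valid.shape, dtype=np.uint8)
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


class DecayFit(NamedTuple):
    """Result of a single-pixel exponential fit."""

    s0: float
    t2star: float
    fit_r2: float
    valid: bool
    flag: str  # "", "no_decay", "too_few_echoes", "degenerate"


def _goodness(signal: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((signal - model) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 * max(1.0, float(np.sum(signal**2))) else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def fit_decay(
    signal: np.ndarray,
    echo_times: np.ndarray,
    noise_floor: float = 0.0,
    min_echoes: int = MIN_ECHOES,
) -> DecayFit:
    """Fit S(TE) = S0 exp(-TE/T2*) to one pixel's echo series.

    Echoes with ``signal <= noise_floor`` are excluded. The fit is
    nonlinear least squares initialised by log-linear regression on the
    usable echoes. Pixels with fewer than ``min_echoes`` usable echoes, or
    a degenerate fit, are returned invalid. Non-decaying pixels have T2*
    capped at :data:`T2MAX` (flag ``"no_decay"``), giving R2* ~ 0.

    Returns
    -------
    DecayFit
        ``(s0, t2star_ms, fit_r2, valid, flag)``.
    """
    signal = np.asarray(signal, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if signal.shape != echo_times.shape:
        raise ValueError("signal and echo_times lengths differ")
    if np.any(np.diff(echo_times) <= 0):
        raise ValueError("echo_times must be strictly increasing")

    use = signal > noise_floor
    if int(use.sum()) < max(2, min_echoes):
        return DecayFit(0.0, 0.0, 0.0, False, "too_few_echoes")

    te = echo_times[use]
    s = signal[use]

    # log-linear initialisation: ln S = ln S0 - TE / T2*
    coeffs = np.polyfit(te, np.log(s), 1)
    slope, log_s0 = coeffs[0], coeffs[1]

    if slope >= 0:
        # signal does not decay with TE: report the capped-T2* limit
        s0 = float(s.mean())
        t2 = T2MAX
        model = s0 * np.exp(-te / t2)
        return DecayFit(s0, t2, _goodness(s, model), True, "no_decay")

    t2_init = min(-1.0 / slope, T2MAX)
    s0_init = float(np.exp(log_s0))

    def _model(t: np.ndarray, s0: float, t2: float) -> np.ndarray:
        return s0 * np.exp(-t / t2)

    # exact-data fast path: if the log-linear solution already reproduces the
    # signal to machine precision the nonlinear refinement is a no-op
    init_model = _model(te, s0_init, t2_init)
    if np.sum((s - init_model) ** 2) <= 1e-18 * np.sum(s**2):
        return DecayFit(s0_init, t2_init, _goodness(s, init_model), True, "")

    try:
        popt, _ = curve_fit(
            _model,
            te,
            s,
            p0=(s0_init, t2_init),
            bounds=([0.0, 1e-6], [np.inf, T2MAX]),
            maxfev=200,
        )
    except RuntimeError:
        return DecayFit(0.0, 0.0, 0.0, False, "degenerate")

    s0_fit, t2_fit = float(popt[0]), float(popt[1])
    if not np.isfinite(s0_fit) or not np.isfinite(t2_fit) or t2_fit <= 0:
        return DecayFit(0.0, 0.0, 0.0, False, "degenerate")
    flag = "no_decay" if t2_fit >= T2MAX else ""
    fit_r2 = _goodness(s, _model(te, s0_fit, t2_fit))
    return DecayFit(s0_fit, t2_fit, fit_r2, True, flag)


_FLAG_CODES = {"": 0, "no_decay": 1, "too_few_echoes": 2, "degenerate": 3}


def fit_map(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    noise_floor: float = 0.0,
    min_echoes: int = MIN_ECHOES,
) -> RelaxationMap:
    """Apply :func:`fit_decay` to every in-mask pixel of an echo series.

    Out-of-mask pixels are marked invalid. Deterministic given its input.
    """
    rows, cols = series.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError("mask shape does not match image shape")
    else:
        mask = np.ones((rows, cols), dtype=bool)

    s0 = np.zeros((rows, cols))
    t2 = np.zeros((rows, cols))
    fit_r2 = np.zeros((rows, cols))
    valid = np.zeros((rows, cols), dtype=bool)
    flags = np.zeros((rows, cols), dtype=np.uint8)

    te = series.echo_times
    for r, c in zip(*np.nonzero(mask)):
        res = fit_decay(series.stack[:, r, c], te, noise_floor, min_echoes)
        s0[r, c] = res.s0
        t2[r, c] = res.t2star
        fit_r2[r, c] = res.fit_r2
        valid[r, c] = res.valid
        flags[r, c] = _FLAG_CODES[res.flag]

    r2star = np.zeros((rows, cols))
    np.divide(1000.0, t2, out=r2star, where=valid & (t2 > 0))
    return RelaxationMap(
        s0=s0,
        t2star=t2,
        r2star=r2star,
        fit_r2=fit_r2,
        valid=valid,
        pixel_area=series.pixel_area,
        flags=flags,
    )


def estimate_noise_sigma(series: EchoSeries, background_mask: np.ndarray) -> float:
    """Estimate the magnitude-noise sigma from a signal-free background region.

    In a magnitude image the background follows a Rayleigh distribution with
    mean sigma*sqrt(pi/2); the estimate inverts that relation on the last
    echo, where tissue signal is weakest.
    """
    bg = series.stack[-1][np.asarray(background_mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("background mask selects no pixels")
    return float(bg.mean() / np.sqrt(np.pi / 2.0))
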