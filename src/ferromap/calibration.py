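"""R2*-to-iron(III) calibration and parametric iron concentration maps.

Over the working range (0.0-0.3 mg g^-1 at 7 T) the relaxation rate is
linear in iron(III) concentration, R2* = a*c + b. The calibration is an
ordinary least-squares fit of per-vial ROI mean R2* against known
concentration; its inverse c = (R2* - b) / a turns a fitted relaxation map
into a parametric iron map, clipped to the calibrated range so the map
stays dense. Aqueous standards make mg g^-1 and ug mL^-1 interchangeable
(density ~1 g mL^-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .relaxometry import RelaxationMap

__all__ = ["CalibrationCurve", "IronMap", "fit_calibration", "apply_calibration"]

#: Default working range of iron(III) concentration, mg g^-1.
DEFAULT_CONC_RANGE = (0.0, 0.3)


@dataclass
class CalibrationCurve:
    """OLS line R2* = slope * c + intercept with 95% confidence intervals.

    Units: slope in s^-1 per (mg g^-1), intercept in s^-1.
    """

    slope: float
    intercept: float
    ci95_slope: float
    ci95_intercept: float
    r_squared: float
    conc_range: tuple[float, float] = DEFAULT_CONC_RANGE

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("non-positive iron response")
        if not (self.conc_range[0] < self.conc_range[1]):
            raise ValueError("conc_range must satisfy c_min < c_max")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, r2star: np.ndarray | float) -> np.ndarray | float:
        """Invert the line: c = (R2* - b) / a (unclipped)."""
        return (np.asarray(r2star, dtype=float) - self.intercept) / self.slope

    def to_json(self) -> str:
        d = asdict(self)
        d["conc_range"] = list(self.conc_range)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


@dataclass
class IronMap:
    """Parametric iron(III) concentration image, mg g^-1 per pixel."""

    concentration: np.ndarray
    valid: np.ndarray
    pixel_area: float
    clip_range: tuple[float, float] = DEFAULT_CONC_RANGE

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        c = self.concentration[self.valid]
        if c.size and (c.min() < self.clip_range[0] - 1e-12 or c.max() > self.clip_range[1] + 1e-12):
            raise ValueError("valid concentrations escape clip_range")


def fit_calibration(
    concentrations: np.ndarray,
    r2star_means: np.ndarray,
    conc_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """OLS fit of ROI-mean R2* against vial iron(III) concentration.

    Requires at least 3 distinct concentrations. 95% confidence intervals
    for slope and intercept come from the t distribution with n-2 degrees
    of freedom. A non-positive fitted slope is rejected: iron must
    increase the relaxation rate.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(r2star_means, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("concentrations and r2star_means must be equal-length vectors")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    res = stats.linregress(c, y)
    if res.slope <= 0:
        raise ValueError("non-positive iron response")
    tcrit = stats.t.ppf(0.975, c.size - 2)
    if conc_range is None:
        conc_range = (float(c.min()), float(c.max()))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95_slope=float(tcrit * res.stderr),
        ci95_intercept=float(tcrit * res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        conc_range=conc_range,
    )


def apply_calibration(rmap: RelaxationMap, curve: CalibrationCurve) -> IronMap:
    """Invert a fitted relaxation map into an iron concentration map.

    Per valid pixel c = (R2* - b) / a, clipped into the curve's
    concentration range; invalid pixels stay invalid with c = 0.
    """
    lo, hi = curve.conc_range
    lo = max(lo, 0.0)
    conc = np.zeros_like(rmap.r2star)
    v = rmap.valid
    conc[v] = np.clip(curve.concentration(rmap.r2star[v]), lo, hi)
    return IronMap(
        concentration=conc,
        valid=v.copy(),
        pixel_area=rmap.pixel_area,
        clip_range=(lo, hi),
    )
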