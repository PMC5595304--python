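"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check:
connected components by breadth-first flood fill, Mann-Whitney p-values by
exhaustive enumeration of rank assignments, and OLS by the closed-form
normal equations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from ferromap.synthetic import Deposit, PhantomSpec, make_phantom
from ferromap import default_echo_times, simulate_echoes


# ---------------------------------------------------------------- oracles
def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force connected-component labeling by BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for r0, c0 in zip(*np.nonzero(mask)):
        if labels[r0, c0]:
            continue
        next_label += 1
        queue = deque([(r0, c0)])
        labels[r0, c0] = next_label
        while queue:
            r, c = queue.popleft()
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < mask.shape[0]
                    and 0 <= cc < mask.shape[1]
                    and mask[rr, cc]
                    and not labels[rr, cc]
                ):
                    labels[rr, cc] = next_label
                    queue.append((rr, cc))
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two label images define the same partition of the foreground."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for la, lb in zip(a[a > 0].ravel(), b[a > 0].ravel()):
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in seen:
                return False
            mapping[la] = lb
            seen.add(lb)
    return True


import functools


@functools.lru_cache(maxsize=None)
def mannwhitney_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U1 over all C(n1+n2, n1) rank assignments."""
    ranks = np.arange(1, n1 + n2 + 1)
    us = [
        sum(combo) - n1 * (n1 + 1) // 2
        for combo in itertools.combinations(ranks, n1)
    ]
    return np.array(us)


def mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (no ties allowed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    u1 = sum(1 for xi in x for yj in y if xi > yj)
    u_obs = min(u1, n1 * n2 - u1)
    dist = mannwhitney_u_distribution(n1, n2)
    extreme = np.minimum(dist, n1 * n2 - dist) <= u_obs
    return float(extreme.mean())


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope/intercept from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = (x**2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    return float(slope), float(y.mean() - slope * x.mean())


# --------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def echo_times() -> np.ndarray:
    return default_echo_times()


@pytest.fixture(scope="session")
def deposit_phantom():
    """32x32 low-iron background (40 ms) with one 5 ms deposit disk."""
    spec = PhantomSpec(
        width=32,
        height=32,
        background_t2star=40.0,
        deposits=[Deposit(row=16, col=16, radius=4, t2star=5.0)],
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_series(deposit_phantom, echo_times):
    t2map, s0map, _ = deposit_phantom
    return simulate_echoes(t2map, s0map, echo_times, 0.0, "none")
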