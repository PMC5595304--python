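"""Hot-spot cluster analysis of stratified iron maps and group statistics.

The iron map is stratified into a concentration band (the high-iron band is
0.15-0.3 mg g^-1), hot-spot clusters are the connected components of the
band mask, and their count and cross-sectional areas (mm^2) are the summary
statistics compared between groups with two-tailed unpaired t or
Mann-Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .calibration import IronMap

__all__ = [
    "StratifiedMask",
    "Cluster",
    "ClusterSet",
    "GroupComparison",
    "HIGH_IRON_BAND",
    "stratify",
    "find_clusters",
    "cluster_summary",
    "compare_groups",
]

#: The high-iron concentration band, mg g^-1.
HIGH_IRON_BAND = (0.15, 0.3)


@dataclass
class StratifiedMask:
    """Boolean membership mask for a concentration band (inclusive ends)."""

    mask: np.ndarray
    band: tuple[float, float]
    pixel_area: float


@dataclass
class Cluster:
    id: int
    pixel_count: int
    area_mm2: float
    centroid_row: float
    centroid_col: float


@dataclass
class ClusterSet:
    """Labeled connected components of a stratified mask.

    ``labels`` is an integer image with 0 background and cluster ids
    contiguous from 1; ``clusters[i].area_mm2 == pixel_count * pixel_area``.
    """

    labels: np.ndarray
    clusters: list[Cluster]
    connectivity: int
    pixel_area: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": c.id,
                    "pixels": c.pixel_count,
                    "area_mm2": c.area_mm2,
                    "centroid_row": c.centroid_row,
                    "centroid_col": c.centroid_col,
                }
                for c in self.clusters
            ],
            columns=["id", "pixels", "area_mm2", "centroid_row", "centroid_col"],
        )


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    flag: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def stratify(iron: IronMap, c_lo: float, c_hi: float) -> StratifiedMask:
    """Mask the pixels whose concentration falls in [c_lo, c_hi].

    Band membership is inclusive at both ends; invalid pixels are excluded.
    """
    if not (0 <= c_lo < c_hi):
        raise ValueError("need 0 <= c_lo < c_hi")
    mask = iron.valid & (iron.concentration >= c_lo) & (iron.concentration <= c_hi)
    return StratifiedMask(mask=mask, band=(c_lo, c_hi), pixel_area=iron.pixel_area)


def find_clusters(
    mask: StratifiedMask | np.ndarray,
    connectivity: int = 8,
    min_pixels: int = 1,
    pixel_area: float | None = None,
) -> ClusterSet:
    """Connected components of a boolean mask.

    ``connectivity`` is 4 (edge neighbours) or 8 (edges + diagonals).
    Components with fewer than ``min_pixels`` pixels are dropped and the
    survivors relabeled contiguously from 1.
    """
    if isinstance(mask, StratifiedMask):
        arr, px_area = mask.mask, mask.pixel_area
    else:
        arr = np.asarray(mask, dtype=bool)
        if pixel_area is None:
            raise ValueError("pixel_area required for a bare mask")
        px_area = pixel_area
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")

    labels = measure.label(arr, connectivity=1 if connectivity == 4 else 2)
    clusters: list[Cluster] = []
    relabeled = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if region.num_pixels < min_pixels:
            continue
        relabeled[labels == region.label] = next_id
        clusters.append(
            Cluster(
                id=next_id,
                pixel_count=int(region.num_pixels),
                area_mm2=float(region.num_pixels * px_area),
                centroid_row=float(region.centroid[0]),
                centroid_col=float(region.centroid[1]),
            )
        )
        next_id += 1
    return ClusterSet(labels=relabeled, clusters=clusters, connectivity=connectivity, pixel_area=px_area)


def cluster_summary(cs: ClusterSet) -> tuple[int, float | None, np.ndarray]:
    """Count and mean cross-sectional area (mm^2) of a cluster set.

    Returns ``(n_clusters, mean_area, areas)``; the mean is ``None`` for an
    empty set.
    """
    areas = np.array([c.area_mm2 for c in cs.clusters], dtype=float)
    n = len(cs.clusters)
    return n, (float(areas.mean()) if n else None), areas


def compare_groups(x: np.ndarray, y: np.ndarray, test: str = "student_t") -> GroupComparison:
    """Two-sample comparison of cluster statistics between groups.

    ``student_t`` is the two-tailed unpaired pooled-variance t-test;
    ``mann_whitney`` the two-tailed rank-sum U test with an exact p-value
    when min(n1, n2) <= 8 and the data are tie-free, and the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if test == "student_t":
        if n1 < 2 or n2 < 2:
            raise ValueError("t-test needs at least 2 observations per group")
        pooled = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        if pooled == 0.0:
            if x.mean() == y.mean():
                return GroupComparison("student_t", 0.0, 1.0, n1, n2)
            return GroupComparison("student_t", np.inf, 0.0, n1, n2, flag="zero_variance")
        stat, p = stats.ttest_ind(x, y, equal_var=True)
        return GroupComparison("student_t", float(stat), float(p), n1, n2)
    if test == "mann_whitney":
        if n1 < 1 or n2 < 1:
            raise ValueError("Mann-Whitney needs at least 1 observation per group")
        ties = np.unique(np.concatenate([x, y])).size < n1 + n2
        method = "exact" if (min(n1, n2) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return GroupComparison("mann_whitney", float(res.statistic), float(res.pvalue), n1, n2)
    raise ValueError(f"unknown test: {test!r}")
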