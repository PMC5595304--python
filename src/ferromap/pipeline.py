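"""End-to-end runs: echo stack -> iron map -> hot-spot clusters, and
slide -> detection -> resolution-matched clusters -> survey.

Each run is deterministic given its configuration and inputs; the report
echoes the exact configuration used so a run can be reproduced from its
outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import fit_calibration, apply_calibration
from .clusters import HIGH_IRON_BAND, cluster_summary, find_clusters, stratify
from .histology import (
    MIN_OBJECT_AREA_UM2,
    DEFAULT_SCALE_FACTOR,
    count_cells_in_clusters,
    detect_positive,
    downsample_mask,
    filter_objects,
    match_clusters,
    segment_lesions,
    survey_lesions,
)
from . import io as fio
from .relaxometry import fit_map

__all__ = ["RunConfig", "RunReport", "run_mri_pipeline", "run_histology_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every field has a safe default."""

    # inputs
    stack_path: str | None = None
    calibration_path: str | None = None  # curve JSON or (concentration, r2star) CSV
    slide_path: str | None = None
    out_dir: str = "."
    # relaxometry
    noise_floor: float = 0.0
    # stratification / clustering
    band: tuple[float, float] = HIGH_IRON_BAND
    connectivity: int = 8
    min_pixels: int = 1
    # histology
    min_object_area_um2: float = MIN_OBJECT_AREA_UM2
    scale_factor: int = DEFAULT_SCALE_FACTOR
    cluster_threshold: float = 0.0
    counterstain: str = "neutral_red"
    min_lesion_area_um2: float = 500.0
    run_survey: bool = True
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass
class RunReport:
    """Outputs of a pipeline run plus the configuration that produced it."""

    config: RunConfig
    version: str = __version__
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format=fio.FLOAT_FORMAT)
        (out / "report.json").write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config": json.loads(self.config.to_json()),
                    "summary": self.summary,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _load_curve(path: str) -> "fio.CalibrationCurve":
    p = Path(path)
    if p.suffix.lower() == ".json":
        return fio.load_calibration(p)
    df = pd.read_csv(p)
    cols = {c.lower(): c for c in df.columns}
    try:
        conc = df[cols["concentration"]].to_numpy(dtype=float)
        r2s = df[cols["r2star"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise KeyError(f"calibration CSV {p} needs 'concentration' and 'r2star' columns") from exc
    return fit_calibration(conc, r2s)


def run_mri_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """EchoSeries -> RelaxationMap -> IronMap -> StratifiedMask -> ClusterSet."""
    if config.stack_path is None or config.calibration_path is None:
        raise ValueError("MRI pipeline needs stack_path and calibration_path")
    series = fio.load_echo_series(config.stack_path)
    curve = _load_curve(config.calibration_path)
    rmap = fit_map(series, noise_floor=config.noise_floor)
    iron = apply_calibration(rmap, curve)
    strat = stratify(iron, *config.band)
    cs = find_clusters(strat, connectivity=config.connectivity, min_pixels=config.min_pixels)
    n, mean_area, _ = cluster_summary(cs)

    report = RunReport(config=config)
    report.tables["clusters"] = cs.to_frame()
    report.summary = {
        "n_clusters": n,
        "mean_cluster_area_mm2": mean_area,
        "n_valid_pixels": int(rmap.valid.sum()),
        "calibration": {"slope": curve.slope, "intercept": curve.intercept},
        "band": list(config.band),
    }
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.save_relaxation_map(out / "relaxation_map.tif", rmap)
        fio.save_iron_map(out / "iron_map.tif", iron)
        fio.save_cluster_set(out / "clusters.csv", cs, out / "cluster_labels.tif")
        report.write(out)
    return report


def run_histology_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Slide -> detection -> size filter -> downsample -> clusters -> survey."""
    if config.slide_path is None:
        raise ValueError("histology pipeline needs slide_path")
    slide = fio.load_slide(config.slide_path)
    dm = filter_objects(detect_positive(slide), min_area=config.min_object_area_um2)
    mcm = downsample_mask(dm, scale_factor=config.scale_factor)
    cs = match_clusters(mcm, threshold=config.cluster_threshold)
    cells = count_cells_in_clusters(dm, cs, config.scale_factor)

    report = RunReport(config=config)
    cluster_df = cs.to_frame()
    cluster_df["cells"] = [cells[c.id] for c in cs.clusters]
    report.tables["hlm_clusters"] = cluster_df
    report.summary = {
        "n_hlm_objects": len(dm.objects),
        "n_clusters": len(cs),
        "total_cells_in_clusters": int(sum(cells.values())),
    }
    if config.run_survey:
        ls = segment_lesions(
            slide,
            counterstain=config.counterstain,
            min_lesion_area_um2=config.min_lesion_area_um2,
        )
        survey, percent = survey_lesions(ls, dm, mcm)
        flat = survey.copy()
        flat["cluster_areas_mm2"] = flat["cluster_areas_mm2"].map(
            lambda v: ";".join(fio.FLOAT_FORMAT % a for a in v)
        )
        flat["cells_per_cluster"] = flat["cells_per_cluster"].map(
            lambda v: ";".join(str(c) for c in v)
        )
        report.tables["lesion_survey"] = flat
        report.summary["n_lesions"] = ls.n_lesions
        report.summary["iron_positive_percent"] = percent
    if write:
        report.write(config.out_dir)
    return report
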