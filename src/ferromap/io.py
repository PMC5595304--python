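"""File formats: multi-page TIFF stacks with JSON sidecars, CSV tables.

Conventions: an image written to ``foo.tif`` carries its metadata (echo
times in ms, pixel size in mm, slide scale in um/px, ...) in ``foo.json``
next to it. Float maps are 32-bit TIFF; tables are CSV with fixed column
order and 6-significant-digit floats so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve, IronMap
from .clusters import Cluster, ClusterSet
from .relaxometry import EchoSeries, RelaxationMap
from .synthetic import HistologySlide

__all__ = [
    "sidecar_path",
    "save_echo_series",
    "load_echo_series",
    "save_relaxation_map",
    "load_relaxation_map",
    "save_iron_map",
    "load_iron_map",
    "save_cluster_set",
    "load_cluster_set",
    "save_slide",
    "load_slide",
    "save_calibration",
    "load_calibration",
]

FLOAT_FORMAT = "%.6g"


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: str | Path, required: tuple[str, ...] = ()) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar metadata file: {sc}")
    meta = json.loads(sc.read_text())
    for key in required:
        if key not in meta:
            raise KeyError(f"sidecar {sc} is missing required field {key!r}")
    return meta


def save_echo_series(path: str | Path, series: EchoSeries) -> None:
    tifffile.imwrite(path, series.stack.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {"echo_times_ms": series.echo_times.tolist(), "pixel_size_mm": series.pixel_size},
    )


def load_echo_series(path: str | Path) -> EchoSeries:
    meta = _read_sidecar(path, required=("echo_times_ms", "pixel_size_mm"))
    stack = tifffile.imread(path)
    return EchoSeries(
        stack=np.asarray(stack, dtype=float),
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        pixel_size=float(meta["pixel_size_mm"]),
    )


_RMAP_PAGES = ("s0", "t2star", "r2star", "fit_r2", "valid", "flags")


def save_relaxation_map(path: str | Path, rmap: RelaxationMap) -> None:
    pages = np.stack(
        [np.asarray(getattr(rmap, name), dtype=np.float32) for name in _RMAP_PAGES]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_sidecar(path, {"pages": list(_RMAP_PAGES), "pixel_area_mm2": rmap.pixel_area})


def load_relaxation_map(path: str | Path) -> RelaxationMap:
    meta = _read_sidecar(path, required=("pages", "pixel_area_mm2"))
    pages = tifffile.imread(path)
    data = {name: np.asarray(pages[i], dtype=float) for i, name in enumerate(meta["pages"])}
    return RelaxationMap(
        s0=data["s0"],
        t2star=data["t2star"],
        r2star=data["r2star"],
        fit_r2=data["fit_r2"],
        valid=data["valid"].astype(bool),
        pixel_area=float(meta["pixel_area_mm2"]),
        flags=data["flags"].astype(np.uint8),
    )


def save_iron_map(path: str | Path, iron: IronMap) -> None:
    pages = np.stack(
        [iron.concentration.astype(np.float32), iron.valid.astype(np.float32)]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_sidecar(
        path,
        {"pixel_area_mm2": iron.pixel_area, "clip_range": list(iron.clip_range)},
    )


def load_iron_map(path: str | Path) -> IronMap:
    meta = _read_sidecar(path, required=("pixel_area_mm2", "clip_range"))
    pages = tifffile.imread(path)
    lo, hi = meta["clip_range"]
    return IronMap(
        # float32 storage can nudge values past the clip bounds; restore them
        concentration=np.clip(np.asarray(pages[0], dtype=float), lo, hi),
        valid=np.asarray(pages[1]).astype(bool),
        pixel_area=float(meta["pixel_area_mm2"]),
        clip_range=tuple(meta["clip_range"]),
    )


def save_cluster_set(csv_path: str | Path, cs: ClusterSet, labels_path: str | Path | None = None) -> None:
    cs.to_frame().to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    _write_sidecar(
        csv_path, {"connectivity": cs.connectivity, "pixel_area_mm2": cs.pixel_area}
    )
    if labels_path is not None:
        tifffile.imwrite(labels_path, cs.labels.astype(np.int32))


def load_cluster_set(csv_path: str | Path, labels_path: str | Path | None = None) -> ClusterSet:
    meta = _read_sidecar(csv_path, required=("connectivity", "pixel_area_mm2"))
    df = pd.read_csv(csv_path)
    clusters = [
        Cluster(
            id=int(r["id"]),
            pixel_count=int(r["pixels"]),
            area_mm2=float(r["area_mm2"]),
            centroid_row=float(r["centroid_row"]),
            centroid_col=float(r["centroid_col"]),
        )
        for _, r in df.iterrows()
    ]
    if labels_path is not None and Path(labels_path).exists():
        labels = np.asarray(tifffile.imread(labels_path), dtype=np.int32)
    else:
        labels = np.zeros((0, 0), dtype=np.int32)
    return ClusterSet(
        labels=labels,
        clusters=clusters,
        connectivity=int(meta["connectivity"]),
        pixel_area=float(meta["pixel_area_mm2"]),
    )


def save_slide(path: str | Path, slide: HistologySlide) -> None:
    iio.imwrite(path, slide.rgb)
    _write_sidecar(path, {"scale_um_per_px": slide.scale, "stain": slide.stain})


def load_slide(path: str | Path) -> HistologySlide:
    meta = _read_sidecar(path, required=("scale_um_per_px",))
    rgb = np.asarray(iio.imread(path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:  # drop alpha
        rgb = rgb[..., :3]
    return HistologySlide(
        rgb=rgb, scale=float(meta["scale_um_per_px"]), stain=meta.get("stain", "prussian_blue")
    )


def save_calibration(path: str | Path, curve: CalibrationCurve) -> None:
    Path(path).write_text(curve.to_json())


def load_calibration(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_json(Path(path).read_text())
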