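"""File-format plumbing: NIfTI-1 rasters, JSON contours/reports, YAML config.

Arrays are held in memory as (slice, row, col[, tsl]) and written to NIfTI
as (col, row, slice[, tsl]) with pixel spacing and slice thickness in the
header zooms.  The spin-lock schedule has no native NIfTI field, so it lives
in a JSON sidecar next to the 4-D volume.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .chords import ContourPair
from .phantom import PhantomConfig, TissueParams, TSLSeries


def _affine(pixel_spacing: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def _to_nifti_order(arr: np.ndarray) -> np.ndarray:
    # (slice, row, col, ...) -> (col, row, slice, ...)
    return np.moveaxis(arr, [0, 1, 2], [2, 1, 0])


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    return np.moveaxis(arr, [2, 1, 0], [0, 1, 2])


def save_volume(path: str | Path, volume: np.ndarray, pixel_spacing: float,
                slice_thickness: float, dtype=np.float32) -> None:
    img = nib.Nifti1Image(
        _to_nifti_order(np.asarray(volume)).astype(dtype),
        _affine(pixel_spacing, slice_thickness),
    )
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return _from_nifti_order(np.asarray(img.dataobj))


def save_series(path: str | Path, series: TSLSeries) -> None:
    """4-D NIfTI plus a JSON sidecar carrying TSL and spin-lock amplitude."""
    path = Path(path)
    save_volume(path, series.data, series.pixel_spacing,
                series.slice_thickness)
    sidecar = {
        "tsl_ms": list(series.tsl_ms),
        "spin_lock_amplitude_hz": series.spin_lock_amplitude_hz,
        "pixel_spacing_mm": series.pixel_spacing,
        "slice_thickness_mm": series.slice_thickness,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_series(path: str | Path) -> TSLSeries:
    path = Path(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} (field tsl_ms is required)")
    meta = json.loads(sidecar_path.read_text())
    for key in ("tsl_ms", "pixel_spacing_mm", "slice_thickness_mm"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar_path} missing field {key!r}")
    return TSLSeries(
        data=np.asarray(load_volume(path), dtype=float),
        tsl_ms=tuple(meta["tsl_ms"]),
        spin_lock_amplitude_hz=meta.get("spin_lock_amplitude_hz", float("nan")),
        pixel_spacing=meta["pixel_spacing_mm"],
        slice_thickness=meta["slice_thickness_mm"],
    )


def save_contours(path: str | Path, contours: list[ContourPair]) -> None:
    payload = [
        {
            "slice_index": c.slice_index,
            "pixel_spacing_mm": c.pixel_spacing,
            "epicardium": np.asarray(c.epicardium).tolist(),
            "endocardium": np.asarray(c.endocardium).tolist(),
        }
        for c in contours
    ]
    Path(path).write_text(json.dumps(payload))


def load_contours(path: str | Path) -> list[ContourPair]:
    payload = json.loads(Path(path).read_text())
    return [
        ContourPair(
            slice_index=item["slice_index"],
            epicardium=np.asarray(item["epicardium"]),
            endocardium=np.asarray(item["endocardium"]),
            pixel_spacing=item["pixel_spacing_mm"],
        )
        for item in payload
    ]


def config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tissue_params"] = {
        name: {"t1rho": p["t1rho"], "s0": p["s0"]}
        for name, p in d["tissue_params"].items()
    }
    for key in ("matrix", "tsl_ms", "infarct_transmural_profile"):
        d[key] = list(d[key])
    for key in ("apical_extent", "infarct_profile_edges"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "tissue_params" in d:
        d["tissue_params"] = {
            name: TissueParams(**p) for name, p in d["tissue_params"].items()
        }
    for key in ("matrix", "tsl_ms", "infarct_transmural_profile",
                "apical_extent", "infarct_profile_edges"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def save_config(path: str | Path, config: PhantomConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path: str | Path) -> PhantomConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def save_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
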