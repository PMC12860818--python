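"""NIfTI readers/writers and YAML run configuration.

Dynamic volumes are stored as 4D NIfTI-1 with a JSON sidecar carrying what the
NIfTI header cannot (frame times, tube voltage, intensity unit).  Label maps
and masks are 3D NIfTI.  Voxel indexing is 0-based internally; world
coordinates live in the NIfTI affine (diagonal spacing here).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .exceptions import FormatError, InvalidInputError
from .types import UNIT_HU, DynamicVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_labels",
    "save_study",
    "RunConfig",
    "load_config",
]

log = logging.getLogger("fractalperf")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: DynamicVolume, path) -> Path:
    """Write a 4D volume as NIfTI plus a JSON sidecar (frame times, kV, unit)."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), path)
    sidecar = {
        "frame_times_s": volume.frame_times_s.tolist(),
        "unit": volume.unit,
        "kv": volume.kv,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path) -> DynamicVolume:
    """Read a 4D NIfTI volume; spacing from the header, metadata from sidecar."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupted header / not a NIfTI
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D dynamic volume, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta["frame_times_s"], dtype=np.float64)
        unit = meta.get("unit", UNIT_HU)
        kv = int(meta.get("kv", 80))
    else:
        warnings.warn(
            f"no sidecar {sidecar.name}; assuming 1 s frames, HU, 80 kV",
            stacklevel=2,
        )
        times = np.arange(data.shape[3], dtype=np.float64)
        unit, kv = UNIT_HU, 80
    return DynamicVolume(data=data, spacing_mm=spacing, frame_times_s=times,
                         unit=unit, kv=kv)


def write_mask(mask: np.ndarray, spacing_mm, path) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)
    return path


def write_labels(labels: np.ndarray, spacing_mm, path) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), path)
    return path


def read_mask(path) -> np.ndarray:
    try:
        img = nib.load(Path(path))
        return np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc


def save_study(study, out_dir) -> dict:
    """Write a phantom study (volume, labels, masks, ground truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = study.volume.spacing_mm
    paths = {
        "volume": write_volume(study.volume, out / "dynamic.nii.gz"),
        "labels": write_labels(study.labels, sp, out / "aha_labels.nii.gz"),
        "myocardium": write_mask(study.myocardium_mask, sp, out / "myocardium.nii.gz"),
        "aif": write_mask(study.aif_mask, sp, out / "aif_roi.nii.gz"),
    }
    if study.de_mask is not None:
        paths["delayed_enhancement"] = write_mask(
            study.de_mask, sp, out / "delayed_enhancement.nii.gz"
        )
    truth = {
        "segment_mbf": {str(k): v for k, v in study.true_segment_mbf.items()},
        "territory_class": study.true_territory_class,
        "remote_flow": study.true_remote_flow,
        "seed": study.config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    import pandas as pd

    pd.DataFrame(
        {
            "segment": list(study.true_segment_mbf),
            "true_mbf_ml_100ml_min": list(study.true_segment_mbf.values()),
        }
    ).to_csv(out / "truth_segments.csv", index=False)
    paths["truth"] = out / "truth.json"
    return paths


class RunConfig(BaseModel):
    """Schema-validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "fractalperf_out"
    log_level: str = "INFO"
    phantom: dict = {}
    denoise: dict = {}
    conversion: dict = {}
    fractal: dict = {}          # eps_max, kernel, intensity_gain, neighborhood ...
    perfusion: dict = {}        # smooth_window, upslope_lag
    cutoffs: dict = {}
    aha: dict = {}              # margin_mm, de_overlap_threshold, territory_map
    stratification: dict = {}   # {"preset": "published"} or {"boundaries": [b1, b2]}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: config must be a YAML mapping")
    return RunConfig(**raw)
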