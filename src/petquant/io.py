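"""File formats: NIfTI images with JSON frame-timing sidecars, JSON records
and CSV tables.

Images are NIfTI-1, RAS+ with an isotropic mm affine, voxel data float32.
A 4-D image carries its frame schedule in ``<name>.json`` next to the
image (keys ``frame_start_min``, ``frame_duration_min``); a 3-D image
without a sidecar is accepted as a single static frame.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dosimetry import ClockTime, ConversionFactor, DoseRecord
from .image import DynamicImage
from .kinetics import TAC
from .quantify import BiodistSample
from .schedule import FrameSchedule

__all__ = [
    "read_image",
    "write_image",
    "read_masks",
    "write_masks",
    "read_dose_record",
    "write_dose_record",
    "read_conversion_factor",
    "write_conversion_factor",
    "read_tac",
    "write_tac",
    "read_biodist",
    "write_biodist",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_image(path, img: DynamicImage) -> Path:
    """Write a (dynamic) image as NIfTI-1 + JSON timing sidecar."""
    path = Path(path)
    affine = np.diag([img.voxel_size] * 3 + [1.0])
    data = img.data if img.n_frames > 1 else img.data[..., 0]
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    if img.schedule is not None:
        sidecar = {
            "frame_start_min": img.schedule.start.tolist(),
            "frame_duration_min": img.schedule.duration.tolist(),
            "units": "kBq/ml",
            "decay_corrected": img.decay_corrected,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path) -> DynamicImage:
    """Read a NIfTI image; 4-D images require the timing sidecar."""
    path = Path(path)
    nii = nib.load(path)
    data = np.asanyarray(nii.dataobj, dtype=np.float32)
    voxel = float(nii.header.get_zooms()[0])
    sidecar_path = _sidecar_path(path)
    schedule = None
    decay_corrected = True
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        schedule = FrameSchedule(
            start=np.asarray(meta["frame_start_min"], dtype=float),
            duration=np.asarray(meta["frame_duration_min"], dtype=float),
        )
        decay_corrected = bool(meta.get("decay_corrected", True))
    elif data.ndim == 4:
        raise ValueError(f"4-D image {path} is missing its timing sidecar {sidecar_path.name}")
    return DynamicImage(
        data=data, voxel_size=voxel, schedule=schedule, decay_corrected=decay_corrected
    )


def write_masks(path, masks: dict[str, np.ndarray], voxel_size: float) -> Path:
    """Write organ masks as one labelled NIfTI plus a JSON organ map."""
    path = Path(path)
    labels = np.zeros(next(iter(masks.values())).shape, dtype=np.int16)
    mapping = {}
    for i, (name, m) in enumerate(masks.items(), start=1):
        labels[np.asarray(m, dtype=bool)] = i
        mapping[name] = i
    nib.save(nib.Nifti1Image(labels, np.diag([voxel_size] * 3 + [1.0])), path)
    _sidecar_path(path).write_text(json.dumps({"labels": mapping}, indent=1))
    return path


def read_masks(path) -> dict[str, np.ndarray]:
    path = Path(path)
    labels = np.asanyarray(nib.load(path).dataobj)
    mapping = json.loads(_sidecar_path(path).read_text())["labels"]
    return {name: labels == i for name, i in mapping.items()}


def write_dose_record(path, rec: DoseRecord) -> Path:
    path = Path(path)
    d = dataclasses.asdict(rec)
    for k in ("initial_time", "injection_time", "scan_time"):
        d[k] = str(getattr(rec, k))
    path.write_text(json.dumps(d, indent=1))
    return path


def read_dose_record(path) -> DoseRecord:
    d = json.loads(Path(path).read_text())
    for k in ("initial_time", "injection_time", "scan_time"):
        d[k] = ClockTime.parse(d[k].replace(":", "."))
    return DoseRecord(**d)


def write_conversion_factor(path, cf: ConversionFactor) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(cf), indent=1))
    return path


def read_conversion_factor(path) -> ConversionFactor:
    return ConversionFactor(**json.loads(Path(path).read_text()))


def write_tac(path, tac: TAC) -> Path:
    """TAC as CSV with columns t_mid_min, value_kBq_ml[, duration_min]."""
    path = Path(path)
    cols = {"t_mid_min": tac.t, "value_kBq_ml": tac.value}
    if tac.duration is not None:
        cols["duration_min"] = tac.duration
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_tac(path, decay_corrected: bool = True) -> TAC:
    df = pd.read_csv(path)
    return TAC(
        t=df["t_mid_min"].to_numpy(),
        value=df["value_kBq_ml"].to_numpy(),
        duration=df["duration_min"].to_numpy() if "duration_min" in df else None,
        decay_corrected=decay_corrected,
    )


def write_biodist(path, samples: list[BiodistSample]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "organ": s.organ,
                "wet_weight_g": s.wet_weight,
                "counts_bq": s.counts,
                "count_time": str(s.count_time),
            }
            for s in samples
        ]
    ).to_csv(path, index=False)
    return path


def read_biodist(path) -> list[BiodistSample]:
    df = pd.read_csv(path)
    return [
        BiodistSample(
            organ=r.organ,
            wet_weight=r.wet_weight_g,
            counts=r.counts_bq,
            count_time=ClockTime.parse(str(r.count_time).replace(":", ".")),
        )
        for r in df.itertuples()
    ]
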