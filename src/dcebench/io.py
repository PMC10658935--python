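"""Readers/writers and run configuration.

Volumes and masks travel as NIfTI-1; the cohort manifest is a CSV with one
row per lesion; per-case metadata (VOI, timepoints, labels) sits in a JSON
sidecar.  Arrays are stored with spatial axes first (NIfTI convention) and
transposed back to the package's ``(slice, row, col)`` order on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError
from .types import (
    DCECase,
    EnhancementType,
    KineticClass,
    KineticClassName,
    LesionSpec,
    LesionVOI,
    Pathology,
    SegmentationMask,
)

#: Effective-diameter bin labels. Edges follow the half-open convention
#: (0,5), [5,10), [10,15), [15,20), [20, inf).
SIZE_BIN_LABELS = ("<5", "5 to 9", "10 to 14", "15 to 19", ">20")
_SIZE_BIN_EDGES = (5.0, 10.0, 15.0, 20.0)


def size_bin(effective_diameter_mm: float) -> str:
    """Map an effective diameter (mm) to its reporting bin."""
    d = float(effective_diameter_mm)
    if d <= 0:
        raise ValueError(f"effective diameter must be > 0, got {d}")
    for edge, label in zip(_SIZE_BIN_EDGES, SIZE_BIN_LABELS):
        if d < edge:
            return label
    return SIZE_BIN_LABELS[-1]


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    # spatial axes on disk are (slice, row, col) in storage order
    return np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])


def write_case(case: DCECase, out_dir: str | Path) -> dict[str, str]:
    """Write one case (4D series, truth mask, metadata) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = case.case_id
    series_path = out_dir / f"{stem}_series.nii.gz"
    mask_path = out_dir / f"{stem}_mask.nii.gz"
    meta_path = out_dir / f"{stem}_meta.json"

    # (time, slice, row, col) -> (slice, row, col, time): spatial axes first
    nib.save(
        nib.Nifti1Image(
            np.asarray(case.series, np.float32).transpose(1, 2, 3, 0),
            _affine(case.spacing_mm),
        ),
        series_path,
    )
    nib.save(
        nib.Nifti1Image(
            case.truth_mask.astype(np.uint8), _affine(case.spacing_mm)
        ),
        mask_path,
    )
    spec = case.spec
    meta = {
        "case_id": case.case_id,
        "timepoints_s": list(case.timepoints_s),
        "spacing_mm": list(case.spacing_mm),
        "voi": {
            "row_range": list(case.voi.row_range),
            "col_range": list(case.voi.col_range),
            "first_slice": int(case.voi.first_slice),
            "last_slice": int(case.voi.last_slice),
        },
        "spec": None
        if spec is None
        else {
            "enhancement_type": spec.enhancement_type.value,
            "pathology": spec.pathology.value,
            "effective_diameter_mm": spec.effective_diameter_mm,
            "kinetic_name": spec.kinetic.name.value,
            "peak_enhancement": spec.kinetic.peak_enhancement,
            "time_to_peak_s": spec.kinetic.time_to_peak_s,
            "seed": spec.seed,
            "morphology": None if spec.morphology is None else spec.morphology.value,
        },
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return {
        "series": str(series_path),
        "mask": str(mask_path),
        "meta": str(meta_path),
    }


def read_case(paths: dict[str, str]) -> DCECase:
    """Load a case written by :func:`write_case`, with integrity checks."""
    series_img = nib.load(paths["series"])
    mask_img = nib.load(paths["mask"])
    meta = json.loads(Path(paths["meta"]).read_text())

    series = np.asarray(series_img.dataobj, np.float32).transpose(3, 0, 1, 2)
    mask = np.asarray(mask_img.dataobj).astype(bool)
    if series.shape[1:] != mask.shape:
        raise IntegrityError(
            f"series spatial shape {series.shape[1:]} != mask shape {mask.shape}"
        )
    sp_series = tuple(round(float(z), 6) for z in series_img.header.get_zooms()[:3])
    sp_mask = tuple(round(float(z), 6) for z in mask_img.header.get_zooms()[:3])
    if sp_series != sp_mask:
        raise IntegrityError(f"spacing mismatch: series {sp_series} vs mask {sp_mask}")

    v = meta["voi"]
    voi = LesionVOI(
        row_range=tuple(v["row_range"]),
        col_range=tuple(v["col_range"]),
        first_slice=v["first_slice"],
        last_slice=v["last_slice"],
    )
    spec = None
    if meta.get("spec"):
        s = meta["spec"]
        spec = LesionSpec(
            enhancement_type=EnhancementType(s["enhancement_type"]),
            pathology=Pathology(s["pathology"]),
            effective_diameter_mm=s["effective_diameter_mm"],
            kinetic=KineticClass(
                KineticClassName(s["kinetic_name"]),
                peak_enhancement=s["peak_enhancement"],
                time_to_peak_s=s["time_to_peak_s"],
            ),
            seed=s["seed"],
            morphology=None if s.get("morphology") is None else EnhancementType(s["morphology"]),
        )
    return DCECase(
        case_id=meta["case_id"],
        series=series,
        spacing_mm=sp_series,
        timepoints_s=tuple(meta["timepoints_s"]),
        truth_mask=mask,
        voi=voi,
        spec=spec,
    )


def write_mask(
    mask: SegmentationMask, path: str | Path
) -> str:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm)),
        path,
    )
    return str(path)


def read_mask(path: str | Path) -> SegmentationMask:
    img = nib.load(path)
    data = np.asarray(img.dataobj).astype(bool)
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return SegmentationMask.from_array(data, spacing)


# ---------------------------------------------------------------------------
# Manifest


def manifest_from_cases(cases_paths: list[tuple[DCECase, dict[str, str]]]) -> pd.DataFrame:
    rows = []
    for case, paths in cases_paths:
        spec = case.spec
        rows.append(
            {
                "case_id": case.case_id,
                "pathology": spec.pathology.value if spec else "",
                "enhancement_type": spec.enhancement_type.value if spec else "",
                "effective_diameter_mm": spec.effective_diameter_mm if spec else np.nan,
                "size_bin": size_bin(spec.effective_diameter_mm) if spec else "",
                "kinetic_class": spec.kinetic.name.value if spec else "",
                "series_path": paths["series"],
                "mask_path": paths["mask"],
                "meta_path": paths["meta"],
            }
        )
    df = pd.DataFrame(rows)
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise IntegrityError(f"duplicate case_ids in manifest: {dupes}")
    labelled = df[df["size_bin"] != ""]
    mismatch = [
        cid
        for cid, d, b in zip(
            labelled["case_id"],
            labelled["effective_diameter_mm"],
            labelled["size_bin"],
        )
        if size_bin(d) != b
    ]
    if mismatch:
        raise IntegrityError(f"size_bin inconsistent with diameter for {mismatch}")


def write_manifest(df: pd.DataFrame, path: str | Path) -> str:
    validate_manifest(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return str(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_manifest(df)
    return df


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Experiment-wide configuration shared by the CLI stages."""

    seed: int = 0
    n_cases: int = 60
    k_folds: int = 5
    epochs_2d: int = 30
    epochs_3d: int = 20
    arch_2d: dict = field(default_factory=dict)
    arch_3d: dict = field(default_factory=dict)
    input_size: int = 64
    threshold_2d: float = 0.25
    threshold_3d: float = 0.23
    threshold_grid: tuple[float, ...] = tuple(
        round(0.14 + 0.01 * i, 2) for i in range(17)
    )
    timepoints: tuple[int, ...] = (1, 2)
    out_dir: str = "runs"
    train_on_truth: bool = False  # False: FCM masks are the training labels

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if not all(0.0 < t < 1.0 for t in self.threshold_grid):
            raise ConfigurationError("threshold grid values must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("threshold_grid", "timepoints"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
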