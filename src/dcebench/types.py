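"""Domain types for the DCE-MRI lesion-segmentation benchmark.

Axis conventions, fixed once for the whole package:

* volumes are indexed ``(slice, row, col)``, 0-based;
* a 4D series is indexed ``(time, slice, row, col)``;
* VOI slice ranges are inclusive, in-plane ranges are half-open;
* spacings are millimetres in ``(slice, row, col)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import GeometryError, IntegrityError


class EnhancementType(str, Enum):
    MASS = "mass"
    NONMASS = "nonmass"
    UNKNOWN = "unknown"


class Pathology(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class KineticClassName(str, Enum):
    PERSISTENT = "persistent"
    PLATEAU = "plateau"
    WASHOUT = "washout"


@dataclass(frozen=True)
class KineticClass:
    """Shape of a lesion's contrast-uptake curve.

    Parameters
    ----------
    name:
        One of ``persistent`` (uptake keeps rising over the acquisition
        window), ``plateau`` (rises then holds) or ``washout`` (rises then
        falls before the last timepoint).
    peak_enhancement:
        Peak relative enhancement (S_peak - S_0)/S_0, dimensionless, >= 0.
    time_to_peak_s:
        Time at which the curve peaks, seconds, > 0.
    """

    name: KineticClassName
    peak_enhancement: float = 1.0
    time_to_peak_s: float = 150.0

    def __post_init__(self) -> None:
        if self.peak_enhancement < 0:
            raise ValueError("peak_enhancement must be >= 0")
        if self.time_to_peak_s <= 0:
            raise ValueError("time_to_peak_s must be > 0")


@dataclass(frozen=True)
class LesionVOI:
    """Operator bounding box: in-plane rectangle plus first/last lesion slices.

    ``row_range``/``col_range`` are half-open ``(start, stop)`` index pairs;
    ``first_slice``/``last_slice`` are inclusive.
    """

    row_range: tuple[int, int]
    col_range: tuple[int, int]
    first_slice: int
    last_slice: int

    def __post_init__(self) -> None:
        if self.first_slice > self.last_slice:
            raise GeometryError(
                f"first_slice {self.first_slice} > last_slice {self.last_slice}"
            )
        for lo, hi in (self.row_range, self.col_range):
            if lo >= hi:
                raise GeometryError(f"empty in-plane range ({lo}, {hi})")

    @property
    def n_slices(self) -> int:
        return self.last_slice - self.first_slice + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return (
            self.n_slices,
            self.row_range[1] - self.row_range[0],
            self.col_range[1] - self.col_range[0],
        )

    def slicer(self) -> tuple[slice, slice, slice]:
        """Numpy index expression selecting the VOI from a (slice,row,col) volume."""
        return (
            slice(self.first_slice, self.last_slice + 1),
            slice(*self.row_range),
            slice(*self.col_range),
        )

    def check_within(self, volume_shape: Sequence[int]) -> None:
        ns, nr, nc = volume_shape
        if not (0 <= self.first_slice and self.last_slice < ns):
            raise GeometryError("VOI slice range outside volume")
        if not (0 <= self.row_range[0] and self.row_range[1] <= nr):
            raise GeometryError("VOI row range outside volume")
        if not (0 <= self.col_range[0] and self.col_range[1] <= nc):
            raise GeometryError("VOI col range outside volume")


@dataclass(frozen=True)
class LesionSpec:
    """Recipe for one synthetic lesion.

    ``morphology`` is the shape actually rendered; it defaults to
    ``enhancement_type`` and only differs for lesions whose radiological
    label is ``unknown`` (which are still drawn as mass or nonmass).
    """

    enhancement_type: EnhancementType
    pathology: Pathology
    effective_diameter_mm: float
    kinetic: KineticClass
    center: tuple[int, int, int] | None = None
    seed: int = 0
    morphology: EnhancementType | None = None

    def __post_init__(self) -> None:
        if self.effective_diameter_mm <= 0:
            raise ValueError("effective_diameter_mm must be > 0")

    @property
    def shape_kind(self) -> EnhancementType:
        if self.morphology is not None:
            return self.morphology
        return self.enhancement_type


@dataclass
class DCECase:
    """One lesion's 4D DCE-MRI series with truth mask and operator VOI."""

    case_id: str
    series: np.ndarray  # (time, slice, row, col) float32
    spacing_mm: tuple[float, float, float]  # (slice, row, col)
    timepoints_s: tuple[float, ...]
    truth_mask: np.ndarray  # (slice, row, col) bool
    voi: LesionVOI
    spec: LesionSpec | None = None

    def __post_init__(self) -> None:
        if self.series.ndim != 4:
            raise IntegrityError("series must be 4D (time, slice, row, col)")
        if self.series.shape[1:] != self.truth_mask.shape:
            raise IntegrityError(
                f"mask shape {self.truth_mask.shape} != series spatial shape "
                f"{self.series.shape[1:]}"
            )
        if len(self.timepoints_s) != self.series.shape[0]:
            raise IntegrityError("timepoints_s length != number of volumes")
        self.voi.check_within(self.truth_mask.shape)

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]


@dataclass
class SegmentationMask:
    """Binary 3D mask aligned to a VOI grid, possibly flagged as failed (empty)."""

    data: np.ndarray  # (slice, row, col) bool
    spacing_mm: tuple[float, float, float]
    failed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise IntegrityError("mask must be 3D")
        if self.failed and self.data.any():
            raise IntegrityError("failed mask must be empty")

    @classmethod
    def from_array(
        cls, data: np.ndarray, spacing_mm: tuple[float, float, float]
    ) -> "SegmentationMask":
        data = np.asarray(data).astype(bool)
        return cls(data=data, spacing_mm=spacing_mm, failed=not data.any())


@dataclass
class ProbabilityMap:
    """Per-voxel lesion probabilities in [0, 1] emitted by a network."""

    data: np.ndarray
    model_id: str = ""
    lesion_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.size and (d.min() < -1e-9 or d.max() > 1 + 1e-9):
            raise ValueError("probability values must lie in [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)


@dataclass
class MetricRecord:
    """Per-lesion agreement metrics for one (method, reference, timepoint) arm."""

    lesion_id: str
    method: str
    reference: str
    timepoint: int
    dsc: float
    median_hd_mm: float | None
    center_dsc: float | None
    center_hd_mm: float | None
    failed: bool
    pathology: str = ""
    enhancement_type: str = ""
    size_bin: str = ""

    def __post_init__(self) -> None:
        if self.failed and (self.dsc != 0.0 or self.median_hd_mm is not None):
            raise IntegrityError("failed record requires dsc=0 and undefined HD")


@dataclass
class ThresholdCalibration:
    """Result of sweeping binarization thresholds against reference masks."""

    grid: tuple[float, ...]
    mean_dsc: tuple[float, ...]
    selected: float

    def __post_init__(self) -> None:
        if self.selected not in self.grid:
            raise ValueError("selected threshold must belong to the grid")


@dataclass
class FoldPlan:
    """Lesion -> fold assignment for stratified k-fold cross-validation."""

    assignment: dict[str, int]
    k: int
    seed: int
    stratum_report: dict[str, dict[int, int]] = field(default_factory=dict)

    def fold_of(self, lesion_id: str) -> int:
        return self.assignment[lesion_id]

    def lesions_in_fold(self, fold: int) -> list[str]:
        return sorted(l for l, f in self.assignment.items() if f == fold)
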