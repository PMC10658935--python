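"""Segmentation agreement metrics.

Volume Dice similarity coefficient; per-slice symmetric Hausdorff distance
over 4-connectivity boundary pixels (Euclidean, in millimetres, honouring
anisotropic in-plane spacing) aggregated as a per-lesion median; center-slice
metrics; effective diameter 2*sqrt(A/pi); and the failed-segmentation
policy: an all-empty prediction scores DSC 0 and is excluded from HD
statistics because no boundary exists to measure against.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import IntegrityError
from .types import LesionVOI, MetricRecord, SegmentationMask


def _as_bool(a) -> np.ndarray:
    return np.asarray(a).astype(bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly by convention (DSC 1.0); this case never
    arises for reference masks, which are non-empty by construction.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise IntegrityError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_pixels(mask2d: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the 4-connectivity inner boundary."""
    mask2d = _as_bool(mask2d)
    if not mask2d.any():
        return np.empty((0, 2), dtype=int)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndimage.binary_erosion(mask2d, structure=structure, border_value=0)
    return np.argwhere(mask2d & ~interior)


def hausdorff_slice(a2d, b2d, spacing_inplane: tuple[float, float]) -> float | None:
    """Symmetric Hausdorff distance between two 2D masks, in mm.

    max(h(A,B), h(B,A)) with h the directed max-min distance over boundary
    pixels.  Exactly one empty mask -> undefined (None); both empty -> 0.
    """
    a2d, b2d = _as_bool(a2d), _as_bool(b2d)
    if a2d.shape != b2d.shape:
        raise IntegrityError(f"shape mismatch {a2d.shape} vs {b2d.shape}")
    ea, eb = not a2d.any(), not b2d.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return None
    pa = boundary_pixels(a2d) * np.asarray(spacing_inplane, dtype=float)
    pb = boundary_pixels(b2d) * np.asarray(spacing_inplane, dtype=float)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def lesion_median_hd(
    pred: SegmentationMask | np.ndarray,
    ref: SegmentationMask | np.ndarray,
    spacing_mm: tuple[float, float, float] | None = None,
) -> float | None:
    """Median over per-slice HDs, using slices where both masks are non-empty.

    Returns None (lesion excluded from HD statistics) when no slice has both
    masks non-empty — in particular for failed, all-empty predictions.
    """
    if isinstance(pred, SegmentationMask):
        spacing_mm = spacing_mm or pred.spacing_mm
        pred = pred.data
    if isinstance(ref, SegmentationMask):
        spacing_mm = spacing_mm or ref.spacing_mm
        ref = ref.data
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise IntegrityError(f"grid mismatch {pred.shape} vs {ref.shape}")
    hds = []
    for z in range(pred.shape[0]):
        if pred[z].any() and ref[z].any():
            hds.append(hausdorff_slice(pred[z], ref[z], spacing_mm[1:]))
    if not hds:
        return None
    return float(np.median(hds))


def center_slice_index(voi: LesionVOI) -> int:
    """Center slice of the VOI, lower-middle for even slice counts."""
    return (voi.first_slice + voi.last_slice) // 2


def effective_diameter(
    center_slice_mask: np.ndarray, spacing_inplane: tuple[float, float]
) -> float:
    """2*sqrt(A/pi) with A the lesion area in the center slice, mm^2."""
    m = _as_bool(center_slice_mask)
    n = int(m.sum())
    if n == 0:
        raise ValueError("effective diameter undefined for an empty slice")
    area = n * spacing_inplane[0] * spacing_inplane[1]
    return float(2.0 * np.sqrt(area / np.pi))


def evaluate_lesion(
    pred: SegmentationMask,
    ref: SegmentationMask,
    voi: LesionVOI,
    lesion_id: str = "",
    method: str = "",
    reference: str = "",
    timepoint: int = 0,
    strata: dict[str, str] | None = None,
) -> MetricRecord:
    """Per-lesion metric record: volume DSC, median HD, center-slice DSC/HD.

    ``pred`` and ``ref`` live on the VOI grid; the center slice is indexed
    relative to that grid.
    """
    if pred.data.shape != ref.data.shape:
        raise IntegrityError(
            f"prediction grid {pred.data.shape} != reference grid {ref.data.shape}"
        )
    spacing = ref.spacing_mm
    failed = pred.failed or not pred.data.any()
    vol_dsc = 0.0 if failed else dice(pred.data, ref.data)
    med_hd = None if failed else lesion_median_hd(pred.data, ref.data, spacing)

    cz = center_slice_index(voi) - voi.first_slice
    cz = int(np.clip(cz, 0, ref.data.shape[0] - 1))
    if failed:
        c_dsc, c_hd = 0.0, None
    else:
        c_dsc = dice(pred.data[cz], ref.data[cz])
        c_hd = hausdorff_slice(pred.data[cz], ref.data[cz], spacing[1:])
    strata = strata or {}
    return MetricRecord(
        lesion_id=lesion_id,
        method=method,
        reference=reference,
        timepoint=timepoint,
        dsc=float(vol_dsc),
        median_hd_mm=med_hd,
        center_dsc=float(c_dsc),
        center_hd_mm=c_hd,
        failed=bool(failed),
        pathology=strata.get("pathology", ""),
        enhancement_type=strata.get("enhancement_type", ""),
        size_bin=strata.get("size_bin", ""),
    )
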