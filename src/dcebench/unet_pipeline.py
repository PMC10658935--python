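"""2D and 3D U-Net segmentation arms.

Preprocessing, training-set assembly, probability-map inference, quasi-3D
stacking, threshold calibration and back-resizing to the original VOI grid.

Conventions:

* network inputs are postcontrast-minus-precontrast subtraction images
  cropped to the operator VOI and resized in-plane (range-preservingly) to a
  square model size; slice count is never resampled;
* 2D training excludes each lesion's top and bottom VOI slices (these are
  kept at test time); lesions with fewer than three slices keep all slices;
* probability maps are binarized with ``p > threshold`` (default 0.25 for
  the quasi-3D arm, 0.23 for the 3D arm); an all-empty result is flagged
  failed rather than raised;
* back-resizing interpolates the probability map to the original in-plane
  dimensions first and thresholds second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, IntegrityError
from .nn import UNet, UNetConfig
from .synthetic import subtraction_image
from .types import DCECase, LesionVOI, ProbabilityMap, SegmentationMask, ThresholdCalibration

logger = logging.getLogger(__name__)

#: Default binarization thresholds for the two arms.
THRESHOLD_2D = 0.25
THRESHOLD_3D = 0.23

#: Default calibration sweep: 0.14 to 0.30 in steps of 0.01.
DEFAULT_THRESHOLD_GRID = tuple(round(0.14 + 0.01 * i, 2) for i in range(17))


@dataclass
class SliceSample:
    """One resized 2D training slice with its aligned binary target.

    ``norm_lo``/``norm_hi`` record the lesion's whole-VOI subtraction range;
    network inputs are min-max scaled with these shared bounds so that
    lesion-free margin slices are not amplified to full range.
    """

    image: np.ndarray
    target: np.ndarray
    lesion_id: str
    slice_index: int
    norm_lo: float = 0.0
    norm_hi: float = 1.0


@dataclass
class VolumeSample:
    """One resized (in-plane only) 3D training volume with target."""

    image: np.ndarray  # (N, S, S)
    target: np.ndarray
    lesion_id: str


@dataclass
class TrainedUNet:
    model: UNet
    loss_log: list[float] = field(default_factory=list)
    model_id: str = ""


def resize_preserve_range(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear in-plane resize that preserves the exact (min, max) range."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape == tuple(out_shape):
        return img.copy()
    out = _sk_resize(
        img, out_shape, order=1, preserve_range=True, anti_aliasing=False
    )
    lo, hi = img.min(), img.max()
    olo, ohi = out.min(), out.max()
    if ohi > olo:
        out = lo + (out - olo) * (hi - lo) / (ohi - olo)
    else:
        out = np.full(out_shape, lo)
    return out


def _resize_mask(mask: np.ndarray, out_shape) -> np.ndarray:
    return _sk_resize(
        mask.astype(float), out_shape, order=0, preserve_range=True,
        anti_aliasing=False,
    ) > 0.5


def _voi_subtraction(case: DCECase, voi: LesionVOI, timepoint: int) -> np.ndarray:
    sub = subtraction_image(case, timepoint)
    return sub[voi.slicer()]


def make_2d_training_set(
    cases: list[DCECase],
    reference_masks: dict[str, SegmentationMask],
    timepoint: int,
    size: int = 256,
) -> list[SliceSample]:
    """Slice samples for 2D training: all VOI slices except top and bottom.

    Lesions with fewer than three VOI slices keep all their slices (strict
    exclusion would discard the lesion entirely); a flag is logged.
    """
    samples: list[SliceSample] = []
    for case in cases:
        ref = reference_masks[case.case_id]
        voi = case.voi
        if ref.data.shape != voi.shape:
            raise IntegrityError(
                f"{case.case_id}: reference mask grid {ref.data.shape} "
                f"!= VOI grid {voi.shape}"
            )
        sub = _voi_subtraction(case, voi, timepoint)
        lo, hi = float(sub.min()), float(sub.max())
        n = voi.n_slices
        if n >= 3:
            kept = range(1, n - 1)
        else:
            logger.warning(
                "%s has %d VOI slices; keeping all slices in training",
                case.case_id, n,
            )
            kept = range(n)
        for z in kept:
            samples.append(
                SliceSample(
                    image=resize_preserve_range(sub[z], (size, size)),
                    target=_resize_mask(ref.data[z], (size, size)),
                    lesion_id=case.case_id,
                    slice_index=z,
                    norm_lo=lo,
                    norm_hi=hi,
                )
            )
    return samples


def make_3d_training_set(
    cases: list[DCECase],
    reference_masks: dict[str, SegmentationMask],
    timepoint: int,
    size: int = 256,
) -> list[VolumeSample]:
    """Volume samples for 3D training: in-plane resize only, all slices kept."""
    samples: list[VolumeSample] = []
    for case in cases:
        ref = reference_masks[case.case_id]
        voi = case.voi
        if ref.data.shape != voi.shape:
            raise IntegrityError(f"{case.case_id}: reference/VOI grid mismatch")
        sub = _voi_subtraction(case, voi, timepoint)
        image = np.stack(
            [resize_preserve_range(sub[z], (size, size)) for z in range(voi.n_slices)]
        )
        target = np.stack(
            [_resize_mask(ref.data[z], (size, size)) for z in range(voi.n_slices)]
        )
        samples.append(VolumeSample(image=image, target=target, lesion_id=case.case_id))
    return samples


def _normalize(img: np.ndarray, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Min-max scale a network input to [0, 1]; constant inputs map to 0.

    When ``lo``/``hi`` are given (the per-VOI range), they are used instead
    of the input's own range, and values are clipped into [0, 1].
    """
    if lo is None or hi is None:
        lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def train_unet(
    samples: list,
    arch: UNetConfig,
    epochs: int,
    seed: int = 0,
    batch_size: int = 8,
) -> TrainedUNet:
    """Train a U-Net with Adam on binary cross-entropy.

    2D samples are batched (default 8 slices); 3D volumes run one per step
    because their slice counts differ.  The loss log holds the mean training
    BCE per epoch.  Fully deterministic given (samples, arch, epochs, seed).
    """
    if not samples:
        raise ConfigurationError("empty training set")
    if epochs < 1:
        raise ConfigurationError("epochs must be >= 1")
    is_3d = isinstance(samples[0], VolumeSample)
    if is_3d != (arch.ndim == 3):
        raise ConfigurationError("sample rank does not match architecture ndim")
    model = UNet(arch, seed=seed)
    opt = model.make_optimizer()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A41]))
    log: list[float] = []
    lr0 = opt.lr
    for _epoch in range(epochs):
        # cosine decay to lr0/10 stabilizes late training
        frac = _epoch / max(epochs - 1, 1)
        opt.lr = lr0 * (0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac)))
        order = rng.permutation(len(samples))
        losses = []
        if is_3d:
            for idx in order:
                s = samples[idx]
                x = _normalize(s.image)[None, None]  # (1,1,N,S,S)
                t = s.target[None, None].astype(np.float32)
                losses.append(model.train_step(x, t, opt))
        else:
            for start in range(0, len(order), batch_size):
                chunk = order[start : start + batch_size]
                x = np.stack(
                    [_normalize(samples[i].image, samples[i].norm_lo,
                                samples[i].norm_hi)
                     for i in chunk]
                )[:, None]
                t = np.stack([samples[i].target for i in chunk])[:, None].astype(
                    np.float32
                )
                losses.append(model.train_step(x, t, opt))
        log.append(float(np.mean(losses)))
    model.trained = True
    return TrainedUNet(model=model, loss_log=log, model_id=f"unet{arch.ndim}d-s{seed}")


def predict_slices(
    trained: TrainedUNet,
    case: DCECase,
    voi: LesionVOI | None = None,
    timepoint: int = 2,
    size: int = 256,
    batch_size: int = 8,
) -> list[ProbabilityMap]:
    """One probability map per VOI slice (top and bottom slices included)."""
    voi = voi or case.voi
    model = trained.model
    sub = _voi_subtraction(case, voi, timepoint)
    lo, hi = float(sub.min()), float(sub.max())
    imgs = np.stack(
        [_normalize(resize_preserve_range(sub[z], (size, size)), lo, hi)
         for z in range(voi.n_slices)]
    )
    probs = []
    for start in range(0, len(imgs), batch_size):
        p = model.predict_proba(imgs[start : start + batch_size, None])
        probs.append(p[:, 0])
    prob = np.concatenate(probs)
    return [
        ProbabilityMap(prob[z], model_id=trained.model_id, lesion_id=case.case_id)
        for z in range(voi.n_slices)
    ]


def _check_threshold(threshold: float) -> None:
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")


def binarize(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Probability-to-mask rule used everywhere: voxel on iff p > threshold."""
    _check_threshold(threshold)
    return np.asarray(prob) > threshold


def assemble_quasi3d(
    prob_slices: list[ProbabilityMap],
    threshold: float = THRESHOLD_2D,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SegmentationMask:
    """Stack thresholded 2D slice predictions into a quasi-3D volume."""
    _check_threshold(threshold)
    vol = np.stack([binarize(p.data, threshold) for p in prob_slices])
    return SegmentationMask.from_array(vol, spacing_mm)


def predict_3d(
    trained: TrainedUNet,
    case: DCECase,
    voi: LesionVOI | None = None,
    timepoint: int = 2,
    threshold: float = THRESHOLD_3D,
    size: int = 256,
) -> SegmentationMask:
    """3D U-Net probability volume thresholded into a binary mask."""
    _check_threshold(threshold)
    voi = voi or case.voi
    prob = predict_3d_proba(trained, case, voi, timepoint, size)
    return SegmentationMask.from_array(
        binarize(prob.data, threshold), case.spacing_mm
    )


def predict_3d_proba(
    trained: TrainedUNet,
    case: DCECase,
    voi: LesionVOI | None = None,
    timepoint: int = 2,
    size: int = 256,
) -> ProbabilityMap:
    voi = voi or case.voi
    sub = _voi_subtraction(case, voi, timepoint)
    img = np.stack(
        [resize_preserve_range(sub[z], (size, size)) for z in range(voi.n_slices)]
    )
    x = _normalize(img)[None, None]
    p = trained.model.predict_proba(x)[0, 0]
    return ProbabilityMap(p, model_id=trained.model_id, lesion_id=case.case_id)


def calibrate_threshold(
    prob_maps: list[np.ndarray],
    reference_masks: list[np.ndarray],
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> ThresholdCalibration:
    """Pick the grid threshold maximizing mean DSC; ties go to the smallest.

    ``prob_maps`` and ``reference_masks`` are matched (probability, binary
    reference) pairs on a common grid per pair.
    """
    from .metrics import dice

    if not prob_maps or len(prob_maps) != len(reference_masks):
        raise ConfigurationError("need >=1 matched (probability, reference) pair")
    grid = tuple(sorted(grid))
    means = []
    for thr in grid:
        _check_threshold(thr)
        means.append(
            float(
                np.mean(
                    [dice(binarize(p, thr), r)
                     for p, r in zip(prob_maps, reference_masks)]
                )
            )
        )
    best = int(np.argmax(means))  # argmax returns the first (smallest) maximizer
    return ThresholdCalibration(grid=grid, mean_dsc=tuple(means), selected=grid[best])


def resize_prediction_to_voi(
    prediction: np.ndarray,
    voi_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    threshold: float | None = None,
) -> SegmentationMask:
    """Bring a model-grid prediction back to the original VOI grid.

    Probability volumes (``threshold`` given) are linearly interpolated
    in-plane and thresholded after interpolation; binary volumes
    (``threshold`` None) are resized nearest-neighbour.
    """
    pred = np.asarray(prediction)
    if pred.ndim != 3:
        raise IntegrityError("prediction must be a 3D (slice, row, col) array")
    if pred.shape[0] != voi_shape[0]:
        raise IntegrityError(
            f"prediction has {pred.shape[0]} slices but VOI records {voi_shape[0]}"
        )
    target_inplane = voi_shape[1:]
    out = np.empty(voi_shape, dtype=bool)
    for z in range(pred.shape[0]):
        if threshold is not None:
            _check_threshold(threshold)
            plane = _sk_resize(
                pred[z].astype(np.float64), target_inplane, order=1,
                preserve_range=True, anti_aliasing=False,
            )
            out[z] = plane > threshold
        else:
            out[z] = _resize_mask(pred[z], target_inplane)
    return SegmentationMask.from_array(out, spacing_mm)
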