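"""Fuzzy c-means contrast-uptake segmentation.

Each VOI voxel is described by its relative-enhancement vector, one entry
per postcontrast timepoint: ``(S_t - S_0) / max(S_0, eps)``.  Standard FCM
alternating updates cluster these vectors (default c=2: lesion vs
background), minimizing

    J = sum_k sum_i u_ik^m ||x_k - v_i||^2,    sum_i u_ik = 1,

and the cluster whose centroid has the highest mean enhancement is taken as
lesion.  A voxel enters the binary mask when its lesion membership exceeds
0.5; the largest 3D connected component is kept and in-plane holes are
filled.  An all-empty result is returned flagged as failed rather than
raised, mirroring how failed segmentations are handled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError
from .types import DCECase, LesionVOI, SegmentationMask


@dataclass
class FCMState:
    """Memberships, centroids and objective trace of one FCM run."""

    memberships: np.ndarray  # (n_voxels, c)
    centroids: np.ndarray  # (c, n_features)
    fuzziness: float
    objective: float
    objective_trace: list[float]
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class FCMConfig:
    c: int = 2
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    epsilon: float = 1.0  # intensity-unit guard for the S_0 division
    seed: int = 0
    membership_cutoff: float = 0.5


def extract_features(
    case: DCECase, voi: LesionVOI | None = None, epsilon: float = 1.0
) -> np.ndarray:
    """Per-voxel relative-enhancement vectors over the VOI.

    Returns an array of shape ``(n_voi_voxels, n_postcontrast)`` in VOI
    raster order (slice-major); only slices in ``[first_slice, last_slice]``
    contribute.
    """
    voi = voi or case.voi
    voi.check_within(case.truth_mask.shape)
    if case.n_timepoints < 3:
        raise DegenerateDataError("need >=2 postcontrast timepoints")
    sub = case.series[(slice(None),) + voi.slicer()]  # (time, ns, nr, nc)
    s0 = sub[0].astype(np.float64)
    denom = np.maximum(s0, epsilon)
    feats = (sub[1:].astype(np.float64) - s0) / denom  # (T-1, ns, nr, nc)
    return feats.reshape(feats.shape[0], -1).T.copy()


def _init_centroids(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: spread initial centroids across the data."""
    n = x.shape[0]
    centroids = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - np.array(centroids)[None]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        centroids.append(x[rng.choice(n, p=probs)])
    return np.array(centroids)


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    d2 = ((x[:, None, :] - v[None]) ** 2).sum(-1)  # (n, c)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():  # voxel sits exactly on a centroid
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


def fcm_iterate(
    features: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> FCMState:
    """Run FCM alternating updates to convergence.

    Converged when the largest membership change between iterations falls
    below ``tol``; the objective J is non-increasing along the trace.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    if np.unique(x, axis=0).shape[0] < c:
        raise DegenerateDataError(
            f"need at least {c} distinct feature vectors for {c} clusters"
        )
    rng = np.random.default_rng(seed)
    v = _init_centroids(x, c, rng)
    u = _memberships(x, v, m)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        v = (um.T @ x) / um.sum(axis=0)[:, None]
        u_new = _memberships(x, v, m)
        d2 = ((x[:, None, :] - v[None]) ** 2).sum(-1)
        trace.append(float((u_new**m * d2).sum()))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < tol:
            converged = True
            break
    return FCMState(
        memberships=u,
        centroids=v,
        fuzziness=m,
        objective=trace[-1],
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def _postprocess(mask3d: np.ndarray) -> np.ndarray:
    """Largest 26-connected component, then per-slice hole filling."""
    if not mask3d.any():
        return mask3d
    labels, n = ndimage.label(mask3d, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask3d = labels == (int(np.argmax(sizes)) + 1)
    out = np.zeros_like(mask3d)
    for z in range(mask3d.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask3d[z])
    return out


def segment_fcm(
    case: DCECase, voi: LesionVOI | None = None, config: FCMConfig | None = None
) -> SegmentationMask:
    """FCM lesion segmentation inside the operator VOI.

    The output mask lives on the VOI grid ``(n_slices, n_rows, n_cols)``.
    The lesion cluster is identified by centroid mean enhancement (never by
    cluster index), so relabelling clusters cannot change the result.
    """
    voi = voi or case.voi
    config = config or FCMConfig()
    feats = extract_features(case, voi, epsilon=config.epsilon)
    try:
        state = fcm_iterate(
            feats,
            c=config.c,
            m=config.m,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
        )
    except DegenerateDataError:
        # nothing enhances distinguishably inside the VOI -> failed mask
        empty = np.zeros(voi.shape, dtype=bool)
        return SegmentationMask(empty, case.spacing_mm, failed=True)
    lesion_cluster = int(np.argmax(state.centroids.mean(axis=1)))
    hard = state.memberships[:, lesion_cluster] > config.membership_cutoff
    mask3d = _postprocess(hard.reshape(voi.shape))
    return SegmentationMask.from_array(mask3d, case.spacing_mm)
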