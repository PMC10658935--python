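"""Synthetic DCE-MRI lesion phantom generator.

Emulates the structure a breast DCE-MRI segmentation benchmark needs without
patient data: mass vs nonmass enhancement morphology, benign/malignant
contrast-uptake kinetics, a realistic effective-diameter distribution, and
first/second postcontrast subtraction contrast levels.

A phantom is a 4D series (one precontrast plus >=2 postcontrast volumes) in
which voxels inside a binary truth mask follow ``baseline * (1 + e(t))`` for a
class-specific relative-enhancement curve ``e``, background parenchyma carries
a weaker, spatially smooth enhancement, and Gaussian noise is added per
timepoint.  Everything is a pure function of (spec, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidProtocolError
from .types import (
    DCECase,
    EnhancementType,
    KineticClass,
    KineticClassName,
    LesionSpec,
    LesionVOI,
    Pathology,
)

# Fraction of peak enhancement lost between the peak and the end of the
# acquisition window for washout curves.
WASHOUT_FRACTION = 0.25

#: Default kinetic class per pathology.  Benign lesions enhance slowly and
#: persistently; malignant lesions enhance fast with late mild washout.  The
#: defaults keep second-postcontrast enhancement above first-postcontrast for
#: both classes so timepoint-ordering experiments are well posed.
DEFAULT_KINETICS: dict[Pathology, KineticClass] = {
    Pathology.BENIGN: KineticClass(
        KineticClassName.PERSISTENT, peak_enhancement=0.8, time_to_peak_s=150.0
    ),
    Pathology.MALIGNANT: KineticClass(
        KineticClassName.WASHOUT, peak_enhancement=1.2, time_to_peak_s=120.0
    ),
}

#: Joint (enhancement type, pathology) cohort composition observed in a large
#: clinical series of 994 breast lesions.
DEFAULT_COMPOSITION: dict[tuple[str, str], float] = {
    ("mass", "benign"): 170 / 994,
    ("mass", "malignant"): 517 / 994,
    ("nonmass", "benign"): 49 / 994,
    ("nonmass", "malignant"): 175 / 994,
    ("unknown", "benign"): 51 / 994,
    ("unknown", "malignant"): 32 / 994,
}

#: Effective-diameter bin frequencies from the same series (bins in mm:
#: <5, 5-9, 10-14, 15-19, >20) and the sampling range used within each bin.
DEFAULT_SIZE_BINS: tuple[tuple[float, tuple[float, float]], ...] = (
    (64 / 994, (3.0, 5.0)),
    (344 / 994, (5.0, 10.0)),
    (252 / 994, (10.0, 15.0)),
    (125 / 994, (15.0, 20.0)),
    (209 / 994, (20.0, 26.0)),
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition + simulation parameters for one cohort.

    Spacing and timing defaults sit inside routine breast DCE-MRI protocol
    ranges (in-plane 0.5-1.0 mm, slice 1-3.5 mm, temporal resolution
    60-75 s).  Noise and background levels are simulation conventions.
    """

    volume_shape: tuple[int, int, int] = (18, 64, 64)  # (slice, row, col)
    spacing_mm: tuple[float, float, float] = (3.0, 0.8, 0.8)
    timepoints_s: tuple[float, ...] = (0.0, 75.0, 150.0)
    baseline_intensity: float = 500.0
    noise_sigma_frac: float = 0.05  # Gaussian sigma as fraction of baseline
    background_enhancement_frac: float = 0.2  # fraction of lesion peak
    background_texture_frac: float = 0.5  # spatial modulation of the above
    voi_margin_inplane: int = 3  # voxels beyond mask bounding box
    voi_margin_slices: int = 1


def enhancement_curve(
    kinetic: KineticClass, timepoints_s: tuple[float, ...] | list[float]
) -> np.ndarray:
    """Relative enhancement (S_t - S_0)/S_0 sampled at the acquisition times.

    The precontrast value (t=0) is exactly 0.  Persistent curves rise
    concavely through the whole window; plateau curves rise linearly to the
    peak time then hold; washout curves rise to the peak then decline
    linearly, losing ``WASHOUT_FRACTION`` of the peak per full window length.
    """
    t = np.asarray(timepoints_s, dtype=float)
    if t.size < 3:
        raise InvalidProtocolError(
            "DCE protocol needs >=3 timepoints (1 precontrast + >=2 postcontrast)"
        )
    if t[0] != 0:
        raise InvalidProtocolError("first timepoint must be the precontrast t=0")
    if np.any(np.diff(t) <= 0):
        raise InvalidProtocolError("timepoints must be strictly increasing")

    peak = kinetic.peak_enhancement
    tp = kinetic.time_to_peak_s
    t_end = t[-1]
    if kinetic.name == KineticClassName.PERSISTENT:
        e = peak * (t / t_end) ** 0.7
    elif kinetic.name == KineticClassName.PLATEAU:
        e = peak * np.minimum(t / tp, 1.0)
    elif kinetic.name == KineticClassName.WASHOUT:
        rise = peak * t / tp
        fall = peak * (1.0 - WASHOUT_FRACTION * (t - tp) / t_end)
        e = np.where(t <= tp, rise, fall)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown kinetic class {kinetic.name}")
    e[0] = 0.0
    return np.maximum(e, 0.0)


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Zero-mean unit-max-abs smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def _threshold_by_area(field: np.ndarray, center_slice: int, n_pixels: int) -> float:
    """Threshold level whose superlevel set has ``n_pixels`` on the center slice."""
    plane = np.sort(field[center_slice].ravel())[::-1]
    n_pixels = min(max(n_pixels, 1), plane.size)
    return plane[n_pixels - 1]


def _ellipsoid_field(
    shape, center_vox, radii_mm, spacing_mm, rng, irregularity=0.12
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        *(np.arange(n, dtype=float) for n in shape), indexing="ij"
    )
    coords = (zz, yy, xx)
    q = np.zeros(shape, dtype=float)
    for ax in range(3):
        q += (((coords[ax] - center_vox[ax]) * spacing_mm[ax]) / radii_mm[ax]) ** 2
    f = 1.0 - q
    if irregularity > 0:
        f = f + irregularity * _smooth_noise(rng, shape, sigma_vox=(1.0, 2.5, 2.5))
        f = ndimage.gaussian_filter(f, sigma=(0.0, 0.6, 0.6))
    return f


def _check_fits(diameter_mm: float, shape, spacing_mm, margin_vox: int = 4) -> None:
    inplane_extent = min(shape[1] * spacing_mm[1], shape[2] * spacing_mm[2])
    if diameter_mm + 2 * margin_vox * max(spacing_mm[1:]) > inplane_extent:
        raise GeometryError(
            f"lesion diameter {diameter_mm} mm does not fit the "
            f"{shape} volume at spacing {spacing_mm}"
        )


def generate_lesion_shape(
    spec: LesionSpec,
    spacing_mm: tuple[float, float, float],
    volume_shape: tuple[int, int, int],
) -> np.ndarray:
    """Binary 3D lesion mask whose center-slice effective diameter matches the spec.

    Mass lesions are single connected, smoothly irregular ellipsoidal blobs;
    nonmass lesions are unions of 3-8 disjoint small blobs (diffuse, scattered
    enhancement) with the same total center-slice area.  The threshold is set
    by exact pixel-count matching on the center slice, so
    ``2*sqrt(A/pi)`` of the realized mask reproduces
    ``spec.effective_diameter_mm`` to within one in-plane voxel.
    """
    d = spec.effective_diameter_mm
    _check_fits(d, volume_shape, spacing_mm)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5A]))
    pixel_area = spacing_mm[1] * spacing_mm[2]
    target_pixels = max(1, int(round(np.pi * (d / 2.0) ** 2 / pixel_area)))
    center = spec.center or tuple(s // 2 for s in volume_shape)

    if spec.shape_kind == EnhancementType.NONMASS:
        return _nonmass_shape(d, center, target_pixels, spacing_mm, volume_shape, rng)
    return _mass_shape(d, center, target_pixels, spacing_mm, volume_shape, rng)


def _mass_shape(d, center, target_pixels, spacing_mm, volume_shape, rng):
    r = d / 2.0
    # mild anisotropy; z radius capped so thin-slice lesions stay plausible
    radii = (
        max(r * rng.uniform(0.7, 1.0), 0.6 * spacing_mm[0]),
        r * rng.uniform(0.85, 1.15),
        r * rng.uniform(0.85, 1.15),
    )
    f = _ellipsoid_field(volume_shape, center, radii, spacing_mm, rng)
    cs = center[0]
    for _ in range(3):
        thr = _threshold_by_area(f, cs, target_pixels)
        mask = f >= thr
        labels, n = ndimage.label(mask)
        if n > 1:  # keep the blob containing the nominal center
            keep = labels[center] if mask[center] else np.argmax(
                np.bincount(labels[labels > 0])
            )
            mask = labels == keep
        support = np.nonzero(mask.any(axis=(1, 2)))[0]
        new_cs = (support[0] + support[-1]) // 2
        if new_cs == cs:
            break
        cs = new_cs
    return mask


def _nonmass_shape(d, center, target_pixels, spacing_mm, volume_shape, rng):
    n_blobs = int(rng.integers(3, 9))
    # split the target center-slice area across blobs
    w = rng.dirichlet(np.full(n_blobs, 4.0))
    areas = np.maximum(np.round(w * target_pixels).astype(int), 1)
    areas[0] += target_pixels - areas.sum()
    areas[0] = max(areas[0], 1)
    pixel_area = spacing_mm[1] * spacing_mm[2]
    radii_mm = np.sqrt(areas * pixel_area / np.pi)

    env_r = max(d, radii_mm.max() * 2.5 + 2 * max(spacing_mm[1:]))
    centers = _place_disjoint(
        n_blobs, radii_mm, env_r, center, spacing_mm, volume_shape, rng
    )
    mask = np.zeros(volume_shape, dtype=bool)
    for (cy, cx), r_mm, area in zip(centers, radii_mm, areas):
        zr = max(r_mm * rng.uniform(0.8, 1.5), 0.55 * spacing_mm[0])
        f = _ellipsoid_field(
            volume_shape,
            (center[0], cy, cx),
            (zr, r_mm * 1.3, r_mm * 1.3),
            spacing_mm,
            rng,
            irregularity=0.05,
        )
        thr = _threshold_by_area(f, center[0], int(area))
        mask |= f >= thr
    return mask


def _place_disjoint(n, radii_mm, env_r, center, spacing_mm, volume_shape, rng):
    """In-plane blob centers, pairwise separated so blobs stay disconnected."""
    sy, sx = spacing_mm[1], spacing_mm[2]
    lim_y = (radii_mm.max() / sy + 4, volume_shape[1] - radii_mm.max() / sy - 4)
    lim_x = (radii_mm.max() / sx + 4, volume_shape[2] - radii_mm.max() / sx - 4)
    gap_mm = 1.6 * max(sy, sx)
    for _ in range(400):
        props = []
        ok = True
        for i in range(n):
            for _ in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = env_r / 2.0 * np.sqrt(rng.uniform())
                cy = center[1] + rad * np.sin(ang) / sy
                cx = center[2] + rad * np.cos(ang) / sx
                cy = float(np.clip(cy, *lim_y))
                cx = float(np.clip(cx, *lim_x))
                if all(
                    np.hypot((cy - py) * sy, (cx - px) * sx)
                    > 1.4 * (radii_mm[i] + radii_mm[j]) + gap_mm
                    for j, (py, px) in enumerate(props)
                ):
                    props.append((cy, cx))
                    break
            else:
                ok = False
                break
        if ok:
            return props
        env_r *= 1.15  # relax the envelope if packing failed
    raise GeometryError("could not place disjoint nonmass blobs in the volume")


def voi_from_mask(
    mask: np.ndarray,
    margin_inplane: int,
    margin_slices: int,
) -> LesionVOI:
    """Operator-style bounding box: mask support plus a safety margin."""
    if not mask.any():
        raise GeometryError("cannot build a VOI around an empty mask")
    zs, ys, xs = np.nonzero(mask)
    ns, nr, nc = mask.shape
    return LesionVOI(
        row_range=(
            int(max(ys.min() - margin_inplane, 0)),
            int(min(ys.max() + 1 + margin_inplane, nr)),
        ),
        col_range=(
            int(max(xs.min() - margin_inplane, 0)),
            int(min(xs.max() + 1 + margin_inplane, nc)),
        ),
        first_slice=int(max(zs.min() - margin_slices, 0)),
        last_slice=int(min(zs.max() + margin_slices, ns - 1)),
    )


def generate_dce_case(
    spec: LesionSpec,
    protocol: ProtocolConfig | None = None,
    seed: int | None = None,
    case_id: str = "case",
) -> DCECase:
    """Simulate one lesion's 4D DCE series, truth mask and VOI.

    Lesion voxels follow ``baseline * (1 + e(t))``; background voxels carry a
    smooth parenchymal enhancement of amplitude
    ``background_enhancement_frac * peak``; Gaussian noise with sigma
    ``noise_sigma_frac * baseline`` is added independently per timepoint.
    """
    protocol = protocol or ProtocolConfig()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0E]))

    mask = generate_lesion_shape(
        replace(spec, seed=seed), protocol.spacing_mm, protocol.volume_shape
    )
    curve = enhancement_curve(spec.kinetic, protocol.timepoints_s)
    # background uptake follows a persistent-type temporal profile
    bg_curve = enhancement_curve(
        KineticClass(KineticClassName.PERSISTENT, peak_enhancement=1.0),
        protocol.timepoints_s,
    )
    bg_amp = protocol.background_enhancement_frac * spec.kinetic.peak_enhancement
    texture = _smooth_noise(rng, protocol.volume_shape, sigma_vox=(1.5, 6.0, 6.0))
    bg_field = bg_amp * np.clip(
        1.0 + protocol.background_texture_frac * texture, 0.0, 2.0
    ) / (1.0 + protocol.background_texture_frac)

    base = protocol.baseline_intensity
    series = np.empty((len(protocol.timepoints_s), *protocol.volume_shape), np.float32)
    m = mask.astype(float)
    for ti in range(len(protocol.timepoints_s)):
        enh = curve[ti] * m + bg_curve[ti] / bg_curve[-1] * bg_field * (1.0 - m)
        vol = base * (1.0 + enh)
        if protocol.noise_sigma_frac > 0:
            vol = vol + rng.normal(
                0.0, protocol.noise_sigma_frac * base, protocol.volume_shape
            )
        series[ti] = vol.astype(np.float32)

    voi = voi_from_mask(
        mask, protocol.voi_margin_inplane, protocol.voi_margin_slices
    )
    return DCECase(
        case_id=case_id,
        series=series,
        spacing_mm=protocol.spacing_mm,
        timepoints_s=protocol.timepoints_s,
        truth_mask=mask,
        voi=voi,
        spec=spec,
    )


def subtraction_image(case: DCECase, post_index: int) -> np.ndarray:
    """Postcontrast-minus-precontrast volume, the standard U-Net input."""
    if not 1 <= post_index < case.n_timepoints:
        raise IndexError(
            f"post_index must be in [1, {case.n_timepoints - 1}], got {post_index}"
        )
    return case.series[post_index] - case.series[0]


# ---------------------------------------------------------------------------
# Cohort-level sampling


def _largest_remainder(proportions: list[float], n: int) -> list[int]:
    raw = [p * n for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder first
    for i in order[:short]:
        counts[i] += 1
    return counts


def sample_specs(
    n: int,
    seed: int,
    composition: dict[tuple[str, str], float] | None = None,
    size_bins: tuple[tuple[float, tuple[float, float]], ...] = DEFAULT_SIZE_BINS,
    kinetics: dict[Pathology, KineticClass] | None = None,
) -> list[LesionSpec]:
    """Draw ``n`` lesion specs matching a (type, pathology) composition table.

    Stratum counts are apportioned by largest remainder, so each realized
    stratum is within one case of ``n * proportion``.  Lesions labelled
    ``unknown`` are morphologically mass or nonmass with equal probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    composition = composition or DEFAULT_COMPOSITION
    total = sum(composition.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"composition proportions sum to {total}, expected 1")
    kinetics = kinetics or DEFAULT_KINETICS
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0C0]))

    strata = sorted(composition.items())
    counts = _largest_remainder([p for _, p in strata], n)
    bin_p = np.array([p for p, _ in size_bins])
    bin_p = bin_p / bin_p.sum()

    specs: list[LesionSpec] = []
    for ((etype, path), _), cnt in zip(strata, counts):
        for _ in range(cnt):
            b = rng.choice(len(size_bins), p=bin_p)
            lo, hi = size_bins[b][1]
            diameter = float(rng.uniform(lo, hi))
            if etype == "unknown":
                morph = (
                    EnhancementType.MASS
                    if rng.uniform() < 0.5
                    else EnhancementType.NONMASS
                )
            else:
                morph = None
            specs.append(
                LesionSpec(
                    enhancement_type=EnhancementType(etype),
                    pathology=Pathology(path),
                    effective_diameter_mm=diameter,
                    kinetic=kinetics[Pathology(path)],
                    seed=int(rng.integers(0, 2**31 - 1)),
                    center=None,
                    morphology=morph,
                )
            )
    # deterministic shuffle so strata are interleaved in the manifest
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def generate_cases(
    specs: list[LesionSpec],
    protocol: ProtocolConfig | None = None,
    id_prefix: str = "les",
) -> list[DCECase]:
    """Render every spec into an in-memory :class:`DCECase`."""
    protocol = protocol or ProtocolConfig()
    width = max(3, len(str(len(specs))))
    return [
        generate_dce_case(spec, protocol, case_id=f"{id_prefix}{i:0{width}d}")
        for i, spec in enumerate(specs)
    ]


def generate_cohort(
    n: int,
    out_dir,
    seed: int,
    composition: dict[tuple[str, str], float] | None = None,
    protocol: ProtocolConfig | None = None,
    size_bins: tuple[tuple[float, tuple[float, float]], ...] = DEFAULT_SIZE_BINS,
):
    """Simulate ``n`` cases, write them as NIfTI under ``out_dir``, return the manifest."""
    from . import io as io_mod  # local import: io depends only on types

    protocol = protocol or ProtocolConfig()
    specs = sample_specs(n, seed, composition=composition, size_bins=size_bins)
    cases = generate_cases(specs, protocol)
    pairs = [(case, io_mod.write_case(case, out_dir)) for case in cases]
    manifest = io_mod.manifest_from_cases(pairs)
    io_mod.write_manifest(manifest, f"{out_dir}/manifest.csv")
    return manifest
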