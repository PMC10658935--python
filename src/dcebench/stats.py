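"""Cross-validation fold construction and the comparison harness.

Implements stratified by-lesion k-fold assignment (pathology x enhancement
type x size bin), exact/approximate Wilcoxon signed-rank and Mann-Whitney U
tests, Bonferroni correction, median summaries with bootstrap confidence
intervals, and the four benchmark comparison designs:

* A — quasi-3D vs 3D volumetric segmentation against the FCM surrogate
  reference (paired, 2 corrections: DSC and HD);
* B — FCM vs quasi-3D vs 3D center-slice segmentation against the
  center-slice truth reference (3 pairwise paired tests per metric);
* C — first vs second postcontrast input per U-Net arm and lesion type
  (paired, 4 corrections per metric);
* D — mass vs nonmass lesions per U-Net arm and input timepoint
  (unpaired, 4 corrections per metric).

Lesions whose prediction failed (all-empty mask) keep DSC = 0 in DSC tests
but are excluded from HD tests, and their ids are reported.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DegenerateTestError,
    EmptySummaryError,
)
from .types import FoldPlan, MetricRecord

# ---------------------------------------------------------------------------
# Fold construction

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_U_MAX_PRODUCT = 400


def stratified_folds(
    manifest: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Assign lesions to k folds, balanced within each stratum.

    Strata are (pathology, enhancement_type, size_bin).  Within a stratum the
    lesions are shuffled (seeded) and dealt round-robin starting from the
    fold with the fewest lesions so far, so per-stratum fold counts differ by
    at most one and overall fold sizes stay close.  Assignment is by lesion:
    every slice of a lesion inherits its lesion's fold.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    n = len(manifest)
    if k > n:
        raise ConfigurationError(f"k={k} folds but only {n} lesions")
    rng = np.random.default_rng(seed)
    strata_cols = ["pathology", "enhancement_type", "size_bin"]
    work = manifest[["case_id"] + strata_cols].copy()
    work["_stratum"] = work[strata_cols].astype(str).agg("|".join, axis=1)

    assignment: dict[str, int] = {}
    fold_totals = np.zeros(k, dtype=int)
    report: dict[str, dict[int, int]] = {}
    groups = sorted(
        work.groupby("_stratum"), key=lambda kv: (-len(kv[1]), kv[0])
    )
    for stratum, grp in groups:
        ids = list(grp["case_id"])
        rng.shuffle(ids)
        start = int(np.argmin(fold_totals))
        counts: dict[int, int] = {}
        for i, lesion_id in enumerate(ids):
            f = (start + i) % k
            assignment[lesion_id] = f
            fold_totals[f] += 1
            counts[f] = counts.get(f, 0) + 1
        report[stratum] = counts
    return FoldPlan(assignment=assignment, k=k, seed=seed, stratum_report=report)


# ---------------------------------------------------------------------------
# Rank tests


def _signed_rank_exact_p(double_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p for W+ by dynamic programming over sign assignments.

    ``double_ranks`` are the (tie-averaged) ranks multiplied by two so they
    are integers; the distribution of the doubled W+ over all 2^n equally
    likely sign patterns is built by convolution.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w_plus_doubled + 1].sum()
    p_ge = counts[w_plus_doubled:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped and tied absolute differences receive
    averaged ranks.  For n <= 25 retained pairs the null distribution of W+
    is enumerated exactly; above that a normal approximation with tie and
    continuity corrections is used.  ``method`` forces one code path
    ("exact" / "approx"); the default switches on sample size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    use_exact = n <= EXACT_SIGNED_RANK_MAX_N if method == "auto" else method == "exact"
    if use_exact:
        double_ranks = np.round(ranks * 2).astype(int)
        w2 = int(round(w_plus * 2))
        return _signed_rank_exact_p(double_ranks, w2)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise DegenerateTestError("zero variance in signed-rank statistic")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _u_exact_distribution(n: int, m: int) -> np.ndarray:
    """Null counts of the Mann-Whitney U statistic for sample sizes (n, m).

    U has the distribution of the inversion count of a random binary word
    with n ones and m zeros; the DP places symbols left to right, a zero
    after ``a`` ones adding ``a`` inversions.
    """
    max_u = n * m
    dp = np.zeros((n + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for _pos in range(n + m):
        new = np.zeros_like(dp)
        for a in range(n + 1):
            row = dp[a]
            if a < n:  # place a one
                new[a + 1] += row
            if a:  # place a zero after `a` ones
                new[a, a:] += row[: max_u + 1 - a]
            else:
                new[0] += row
        dp = new
    return dp[n]


def mann_whitney_u(x, y, method: str = "auto") -> float:
    """Two-sided Mann-Whitney U p-value for two independent samples.

    Exact enumeration (inversion counting) when there are no ties and
    ``n*m <= 400``; otherwise a normal approximation with tie and continuity
    corrections.  Identical samples yield p = 1.  ``method`` forces one code
    path ("exact" / "approx"); exact is never used in the presence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x
    has_ties = np.unique(combined).size < combined.size
    use_exact = (
        n * m <= EXACT_U_MAX_PRODUCT if method == "auto" else method == "exact"
    ) and not has_ties
    if use_exact:
        counts = _u_exact_distribution(n, m)
        counts = counts / counts.sum()
        u_lo = int(round(min(u_x, u_y)))
        return float(min(1.0, 2.0 * counts[: u_lo + 1].sum()))
    mean = n * m / 2.0
    nn = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nn * (nn - 1))
    var = n * m / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u_x - mean - 0.5 * np.sign(u_x - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni-corrected p-value min(1, raw_p * m)."""
    if not 0.0 <= raw_p <= 1.0:
        raise ValueError(f"raw p-value {raw_p} outside [0, 1]")
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return min(1.0, raw_p * m)


# ---------------------------------------------------------------------------
# Summaries


def summarize(
    values, n_boot: int = 2000, seed: int = 0
) -> dict[str, float | int]:
    """Min/max/median with a percentile-bootstrap 95% CI on the median.

    ``None``/NaN entries (undefined HDs) are dropped and counted.
    """
    arr = np.asarray(
        [v for v in values if v is not None and np.isfinite(v)], dtype=float
    )
    n_excluded = len(list(values)) - arr.size
    if arr.size == 0:
        raise EmptySummaryError("no defined values to summarize")
    rng = np.random.default_rng(seed)
    boots = np.median(
        arr[rng.integers(0, arr.size, size=(n_boot, arr.size))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n": int(arr.size),
        "n_excluded": int(n_excluded),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "median": float(np.median(arr)),
        "ci95_low": float(lo),
        "ci95_high": float(hi),
    }


# ---------------------------------------------------------------------------
# Comparison designs


@dataclass
class ComparisonResult:
    comparison: str  # A | B | C | D
    metric: str  # DSC | HD
    label: str  # human-readable description of the pair of groups
    groups: tuple[str, str]
    raw_p: float
    corrected_p: float
    n: int
    direction: str  # which group is better by median, or "inconclusive"
    excluded: tuple[str, ...] = ()

    def to_row(self) -> dict:
        row = asdict(self)
        row["groups"] = " vs ".join(self.groups)
        row["excluded"] = ";".join(self.excluded)
        return row


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def _paired(df_a: pd.DataFrame, df_b: pd.DataFrame, col: str):
    merged = df_a[["lesion_id", col, "failed"]].merge(
        df_b[["lesion_id", col, "failed"]],
        on="lesion_id",
        suffixes=("_a", "_b"),
    )
    return merged


def _run_test(
    comparison: str,
    metric: str,
    label: str,
    groups: tuple[str, str],
    x: np.ndarray,
    y: np.ndarray,
    m: int,
    paired: bool,
    higher_better: bool,
    excluded: tuple[str, ...] = (),
) -> ComparisonResult:
    try:
        raw = wilcoxon_signed_rank(x, y) if paired else mann_whitney_u(x, y)
    except DegenerateTestError:
        return ComparisonResult(
            comparison, metric, label, groups, float("nan"), float("nan"),
            len(x), "inconclusive", excluded,
        )
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if med_x == med_y:
        direction = "tie"
    else:
        better_first = (med_x > med_y) == higher_better
        direction = groups[0] if better_first else groups[1]
    return ComparisonResult(
        comparison, metric, label, groups, raw, bonferroni(raw, m),
        len(x), direction, excluded,
    )


def _dsc_hd_pair_tests(
    comparison, label, groups, df_a, df_b, m, dsc_col="dsc", hd_col="median_hd_mm"
) -> list[ComparisonResult]:
    out = []
    pd_dsc = _paired(df_a, df_b, dsc_col)
    out.append(
        _run_test(
            comparison, "DSC", label, groups,
            pd_dsc[f"{dsc_col}_a"].to_numpy(), pd_dsc[f"{dsc_col}_b"].to_numpy(),
            m, paired=True, higher_better=True,
        )
    )
    pd_hd = _paired(df_a, df_b, hd_col)
    ok = pd_hd[f"{hd_col}_a"].notna() & pd_hd[f"{hd_col}_b"].notna()
    excluded = tuple(pd_hd.loc[~ok, "lesion_id"])
    pd_hd = pd_hd[ok]
    if len(pd_hd):
        out.append(
            _run_test(
                comparison, "HD", label, groups,
                pd_hd[f"{hd_col}_a"].to_numpy(), pd_hd[f"{hd_col}_b"].to_numpy(),
                m, paired=True, higher_better=False, excluded=excluded,
            )
        )
    return out


def comparison_a(records: pd.DataFrame, timepoint: int = 2) -> list[ComparisonResult]:
    """Quasi-3D vs 3D volumetric segmentation against the FCM reference."""
    sel = records[(records.reference == "fcm") & (records.timepoint == timepoint)]
    q = sel[sel.method == "quasi3d"]
    v = sel[sel.method == "unet3d"]
    if q.empty or v.empty:
        raise ConfigurationError("comparison A needs quasi3d and unet3d vs fcm tables")
    return _dsc_hd_pair_tests("A", "quasi-3D vs 3D (volume, FCM ref)",
                              ("quasi3d", "unet3d"), q, v, m=2)


def comparison_b(records: pd.DataFrame, timepoint: int = 2) -> list[ComparisonResult]:
    """FCM vs quasi-3D vs 3D on center slices against the truth reference."""
    sel = records[(records.reference == "truth") & (records.timepoint == timepoint)]
    tables = {meth: sel[sel.method == meth] for meth in ("fcm", "quasi3d", "unet3d")}
    missing = [k for k, t in tables.items() if t.empty]
    if missing:
        raise ConfigurationError(f"comparison B missing methods: {missing}")
    out: list[ComparisonResult] = []
    pairs = [("fcm", "quasi3d"), ("quasi3d", "unet3d"), ("fcm", "unet3d")]
    for a, b in pairs:
        out += _dsc_hd_pair_tests(
            "B", f"{a} vs {b} (center slice, truth ref)", (a, b),
            tables[a], tables[b], m=3,
            dsc_col="center_dsc", hd_col="center_hd_mm",
        )
    return out


def comparison_c(records: pd.DataFrame) -> list[ComparisonResult]:
    """First vs second postcontrast input, per U-Net arm and lesion type."""
    sel = records[records.reference == "fcm"]
    out: list[ComparisonResult] = []
    for method in ("quasi3d", "unet3d"):
        for etype in ("mass", "nonmass"):
            t1 = sel[(sel.method == method) & (sel.timepoint == 1)
                     & (sel.enhancement_type == etype)]
            t2 = sel[(sel.method == method) & (sel.timepoint == 2)
                     & (sel.enhancement_type == etype)]
            if t1.empty or t2.empty:
                continue
            out += _dsc_hd_pair_tests(
                "C", f"{method} {etype}: tp1 vs tp2", ("tp1", "tp2"),
                t1, t2, m=4,
            )
    if not out:
        raise ConfigurationError("comparison C found no matching tables")
    return out


def comparison_d(records: pd.DataFrame) -> list[ComparisonResult]:
    """Mass vs nonmass lesions, per U-Net arm and input timepoint (unpaired)."""
    sel = records[records.reference == "fcm"]
    out: list[ComparisonResult] = []
    for method in ("quasi3d", "unet3d"):
        for tp in (1, 2):
            sub = sel[(sel.method == method) & (sel.timepoint == tp)]
            mass = sub[sub.enhancement_type == "mass"]
            nonmass = sub[sub.enhancement_type == "nonmass"]
            if mass.empty or nonmass.empty:
                continue
            label = f"{method} tp{tp}: mass vs nonmass"
            out.append(
                _run_test(
                    "D", "DSC", label, ("mass", "nonmass"),
                    mass["dsc"].to_numpy(), nonmass["dsc"].to_numpy(),
                    m=4, paired=False, higher_better=True,
                )
            )
            hx = mass["median_hd_mm"].dropna().to_numpy()
            hy = nonmass["median_hd_mm"].dropna().to_numpy()
            excluded = tuple(
                sub.loc[sub["median_hd_mm"].isna(), "lesion_id"]
            )
            if hx.size and hy.size:
                out.append(
                    _run_test(
                        "D", "HD", label, ("mass", "nonmass"), hx, hy,
                        m=4, paired=False, higher_better=False, excluded=excluded,
                    )
                )
    if not out:
        raise ConfigurationError("comparison D found no matching tables")
    return out


def run_comparison(design: str, records: pd.DataFrame) -> list[ComparisonResult]:
    """Dispatch one of the four comparison designs on a metric table."""
    design = design.upper()
    dispatch = {
        "A": comparison_a,
        "B": comparison_b,
        "C": comparison_c,
        "D": comparison_d,
    }
    if design not in dispatch:
        raise ConfigurationError(f"unknown comparison design {design!r}")
    return dispatch[design](records)
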