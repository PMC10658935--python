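"""End-to-end experiment orchestration.

``run_experiment`` chains: cohort simulation -> FCM surrogate reference ->
stratified by-lesion cross-validation -> 2D (quasi-3D) and 3D U-Net training
and prediction at the requested subtraction timepoints -> per-lesion metrics
against the FCM reference (volumes) and the synthetic-truth reference
(center slices) -> comparison designs A-D.

All stages are pure functions of (plan, seed); the run log records the
config hash and every stage seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcm as fcm_mod
from . import metrics as metrics_mod
from . import stats as stats_mod
from . import unet_pipeline as up
from .errors import DependencyError
from .nn import UNetConfig
from .synthetic import ProtocolConfig, generate_cases, sample_specs
from .io import size_bin
from .types import DCECase, FoldPlan, SegmentationMask

logger = logging.getLogger(__name__)


@dataclass
class ExperimentPlan:
    """Everything needed to reproduce one benchmark run."""

    n_cases: int = 60
    seed: int = 0
    k_folds: int = 2  # folds actually trained; every lesion is tested once
    arms: tuple[str, ...] = ("quasi3d", "unet3d")
    timepoints: tuple[int, ...] = (1, 2)
    comparisons: tuple[str, ...] = ("A", "B", "C", "D")
    input_size: int = 64
    arch_2d: UNetConfig = field(
        default_factory=lambda: UNetConfig(ndim=2, base_filters=16, levels=3)
    )
    arch_3d: UNetConfig = field(
        default_factory=lambda: UNetConfig(ndim=3, base_filters=8, levels=2)
    )
    epochs_2d: int = 12
    epochs_3d: int = 7
    threshold_2d: float = up.THRESHOLD_2D
    threshold_3d: float = up.THRESHOLD_3D
    train_on_truth: bool = False  # False: FCM masks are the training labels
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    out_dir: str | None = None

    def validate(self) -> None:
        need = {
            "A": {("quasi3d", 2), ("unet3d", 2)},
            "B": {("quasi3d", 2), ("unet3d", 2)},
            "C": {(a, t) for a in ("quasi3d", "unet3d") for t in (1, 2)},
            "D": {(a, t) for a in ("quasi3d", "unet3d") for t in (1, 2)},
        }
        have = {(a, t) for a in self.arms for t in self.timepoints}
        for comp in self.comparisons:
            missing = need.get(comp.upper(), set()) - have
            if missing:
                raise DependencyError(
                    f"comparison {comp} needs arms/timepoints {sorted(missing)}"
                )


@dataclass
class ExperimentResult:
    manifest: pd.DataFrame
    fold_plan: FoldPlan
    records: pd.DataFrame
    comparisons: dict[str, list[stats_mod.ComparisonResult]]
    summaries: pd.DataFrame
    masks: dict[tuple[str, int], dict[str, SegmentationMask]]
    fcm_masks: dict[str, SegmentationMask]
    cases: list[DCECase]


def build_manifest(cases: list[DCECase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        s = c.spec
        rows.append(
            {
                "case_id": c.case_id,
                "pathology": s.pathology.value,
                "enhancement_type": s.enhancement_type.value,
                "effective_diameter_mm": s.effective_diameter_mm,
                "size_bin": size_bin(s.effective_diameter_mm),
                "kinetic_class": s.kinetic.name.value,
            }
        )
    return pd.DataFrame(rows)


def fcm_reference(cases: list[DCECase], seed: int = 0) -> dict[str, SegmentationMask]:
    """FCM surrogate reference masks on each case's VOI grid."""
    cfg = fcm_mod.FCMConfig(seed=seed)
    return {c.case_id: fcm_mod.segment_fcm(c, config=cfg) for c in cases}


def truth_on_voi(case: DCECase) -> SegmentationMask:
    return SegmentationMask.from_array(
        case.truth_mask[case.voi.slicer()], case.spacing_mm
    )


def _train_fold_2d(plan, train_cases, labels, timepoint, fold, base_seed):
    samples = up.make_2d_training_set(
        train_cases, labels, timepoint, size=plan.input_size
    )
    return up.train_unet(
        samples, plan.arch_2d, plan.epochs_2d,
        seed=base_seed + 101 * fold + 11 * timepoint,
    )


def _train_fold_3d(plan, train_cases, labels, timepoint, fold, base_seed):
    samples = up.make_3d_training_set(
        train_cases, labels, timepoint, size=plan.input_size
    )
    return up.train_unet(
        samples, plan.arch_3d, plan.epochs_3d,
        seed=base_seed + 211 * fold + 13 * timepoint,
    )


def cross_validated_masks(
    plan: ExperimentPlan,
    cases: list[DCECase],
    labels: dict[str, SegmentationMask],
    fold_plan: FoldPlan,
    arm: str,
    timepoint: int,
) -> dict[str, SegmentationMask]:
    """Held-out predictions on the original VOI grid for every lesion."""
    by_id = {c.case_id: c for c in cases}
    out: dict[str, SegmentationMask] = {}
    for fold in range(fold_plan.k):
        test_ids = [i for i in fold_plan.assignment if fold_plan.assignment[i] == fold]
        train_cases = [
            by_id[i] for i in sorted(fold_plan.assignment) if fold_plan.assignment[i] != fold
        ]
        t0 = time.time()
        if arm == "quasi3d":
            trained = _train_fold_2d(plan, train_cases, labels, timepoint, fold, plan.seed)
        elif arm == "unet3d":
            trained = _train_fold_3d(plan, train_cases, labels, timepoint, fold, plan.seed)
        else:
            raise DependencyError(f"unknown arm {arm!r}")
        logger.info(
            "%s tp%d fold %d: trained in %.1fs (final BCE %.4f)",
            arm, timepoint, fold, time.time() - t0, trained.loss_log[-1],
        )
        for lesion_id in sorted(test_ids):
            case = by_id[lesion_id]
            if arm == "quasi3d":
                maps = up.predict_slices(
                    trained, case, timepoint=timepoint, size=plan.input_size
                )
                prob = np.stack([m.data for m in maps])
                mask = up.resize_prediction_to_voi(
                    prob, case.voi.shape, case.spacing_mm,
                    threshold=plan.threshold_2d,
                )
            else:
                pm = up.predict_3d_proba(
                    trained, case, timepoint=timepoint, size=plan.input_size
                )
                mask = up.resize_prediction_to_voi(
                    pm.data, case.voi.shape, case.spacing_mm,
                    threshold=plan.threshold_3d,
                )
            out[lesion_id] = mask
    return out


def evaluate_arm(
    cases: list[DCECase],
    preds: dict[str, SegmentationMask],
    refs: dict[str, SegmentationMask],
    manifest: pd.DataFrame,
    method: str,
    reference: str,
    timepoint: int,
) -> list[metrics_mod.MetricRecord]:
    strata_by_id = manifest.set_index("case_id")[
        ["pathology", "enhancement_type", "size_bin"]
    ].to_dict("index")
    records = []
    for case in cases:
        records.append(
            metrics_mod.evaluate_lesion(
                preds[case.case_id],
                refs[case.case_id],
                case.voi,
                lesion_id=case.case_id,
                method=method,
                reference=reference,
                timepoint=timepoint,
                strata=strata_by_id[case.case_id],
            )
        )
    return records


def plan_hash(plan: ExperimentPlan) -> str:
    import dataclasses
    import hashlib

    payload = json.dumps(dataclasses.asdict(plan), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_experiment(plan: ExperimentPlan) -> ExperimentResult:
    plan.validate()
    logger.info(
        "experiment seed=%d n=%d config=%s", plan.seed, plan.n_cases, plan_hash(plan)
    )

    specs = sample_specs(plan.n_cases, plan.seed)
    cases = generate_cases(specs, plan.protocol)
    manifest = build_manifest(cases)
    fold_plan = stats_mod.stratified_folds(manifest, k=plan.k_folds, seed=plan.seed)
    fcm_masks = fcm_reference(cases, seed=plan.seed)
    truth_masks = {c.case_id: truth_on_voi(c) for c in cases}
    labels = truth_masks if plan.train_on_truth else fcm_masks

    masks: dict[tuple[str, int], dict[str, SegmentationMask]] = {}
    all_records: list[metrics_mod.MetricRecord] = []
    for arm in plan.arms:
        for tp in plan.timepoints:
            masks[(arm, tp)] = cross_validated_masks(
                plan, cases, labels, fold_plan, arm, tp
            )
            all_records += evaluate_arm(
                cases, masks[(arm, tp)], fcm_masks, manifest, arm, "fcm", tp
            )
            all_records += evaluate_arm(
                cases, masks[(arm, tp)], truth_masks, manifest, arm, "truth", tp
            )
    # the FCM arm itself, against truth (center-slice comparison B)
    last_tp = max(plan.timepoints)
    all_records += evaluate_arm(
        cases, fcm_masks, truth_masks, manifest, "fcm", "truth", last_tp
    )
    records = stats_mod.records_to_frame(all_records)

    comparisons: dict[str, list[stats_mod.ComparisonResult]] = {}
    for comp in plan.comparisons:
        comparisons[comp.upper()] = stats_mod.run_comparison(comp, records)

    summary_rows = []
    for (method, reference, tp), grp in records.groupby(
        ["method", "reference", "timepoint"]
    ):
        for metric, col in (("DSC", "dsc"), ("HD", "median_hd_mm")):
            try:
                s = stats_mod.summarize(list(grp[col]), seed=plan.seed)
            except stats_mod.EmptySummaryError:
                continue
            summary_rows.append(
                {"method": method, "reference": reference, "timepoint": tp,
                 "metric": metric, **s}
            )
    summaries = pd.DataFrame(summary_rows)

    result = ExperimentResult(
        manifest=manifest,
        fold_plan=fold_plan,
        records=records,
        comparisons=comparisons,
        summaries=summaries,
        masks=masks,
        fcm_masks=fcm_masks,
        cases=cases,
    )
    if plan.out_dir:
        write_report(result, plan)
    return result


def write_report(result: ExperimentResult, plan: ExperimentPlan) -> None:
    out = Path(plan.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.manifest.to_csv(out / "manifest.csv", index=False)
    result.records.to_csv(out / "metrics.csv", index=False)
    result.summaries.to_csv(out / "summaries.csv", index=False)
    (out / "fold_plan.json").write_text(
        json.dumps(
            {"k": result.fold_plan.k, "seed": result.fold_plan.seed,
             "assignment": result.fold_plan.assignment,
             "strata": {k: {str(f): c for f, c in v.items()}
                        for k, v in result.fold_plan.stratum_report.items()}},
            indent=1,
        )
    )
    comp_rows = [
        r.to_row() for results in result.comparisons.values() for r in results
    ]
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
    lines = ["# Benchmark report", ""]
    for comp, results in sorted(result.comparisons.items()):
        lines.append(f"## Comparison {comp}")
        for r in results:
            p = "nan" if np.isnan(r.raw_p) else f"{r.raw_p:.4g}"
            pc = "nan" if np.isnan(r.corrected_p) else f"{r.corrected_p:.4g}"
            lines.append(
                f"- {r.label} [{r.metric}]: better={r.direction}, "
                f"raw p={p}, corrected p={pc}, n={r.n}"
            )
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
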