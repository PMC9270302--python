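"""End-to-end cohort analysis: score, classify, and run the study statistics.

``score_cohort`` builds the per-vessel table (QVP terms and index, tertile,
qualitative pattern, post-PCI QFR and the suboptimal-PCI flag);
``analyze_cohort`` computes the cohort-level results: pattern-wise
summaries, ROC of the QVP index against suboptimal PCI (low index predicts
the event), suboptimal rates by QVP tertile, Pearson correlation between
QVP index and post-PCI QFR, inter-rater agreement between the strict and
lenient classifier presets, group comparisons, and standardized regression
of post-PCI QFR on pattern indicators and on the QVP index.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .errors import DegenerateLabelsError, QfrPullbackError
from .metrics import QvpIndexExtractor, Thresholds
from .patterns import (
    DIFFUSE,
    FOCAL,
    LENIENT_PRESET,
    PATTERNS,
    STRICT_PRESET,
    QualitativePatternClassifier,
    classify_pattern,
)
from .simulate import SyntheticVessel
from .stats import (
    DIRECTION_LOW,
    cohens_kappa,
    group_tests,
    pearson_r,
    roc_optimal_cutoff,
    standardized_beta,
)

log = logging.getLogger(__name__)

TERTILE_ORDER = ("lowest", "intermediate", "highest")


def score_cohort(
    vessels: Sequence[SyntheticVessel],
    thresholds: Thresholds | None = None,
    extractor: QvpIndexExtractor | None = None,
    classifier: QualitativePatternClassifier | None = None,
) -> pd.DataFrame:
    """Per-vessel table combining the quantitative and qualitative methods
    with the simulated PCI outcome."""
    th = thresholds or Thresholds()
    ext = extractor or QvpIndexExtractor(thresholds=th)
    clf = (classifier or QualitativePatternClassifier()).fit()
    traces = [v.trace_pre for v in vessels]
    df = ext.fit(traces).transform(traces)
    df.insert(0, "patient_id", [v.patient_id for v in vessels])
    df["pattern"] = clf.predict(traces)
    df["true_pattern"] = [v.true_pattern for v in vessels]
    df["post_qfr"] = [v.post_qfr for v in vessels]
    df["suboptimal"] = df["post_qfr"] <= th.suboptimal_post_qfr
    return df


def classify_cohort(
    vessels: Sequence[SyntheticVessel],
    classifier: QualitativePatternClassifier | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Qualitative classification table plus the per-event companion table."""
    clf = (classifier or QualitativePatternClassifier()).fit()
    rows, events = [], []
    for v in vessels:
        evs = clf.detect(v.trace_pre)
        rows.append(
            {
                "vessel_id": v.vessel_id,
                "pattern": classify_pattern(evs),
                "n_focal_drops": sum(1 for e in evs if e.kind == "focal"),
                "n_diffuse_segments": sum(1 for e in evs if e.kind == "diffuse"),
            }
        )
        for e in evs:
            events.append(
                {
                    "vessel_id": v.vessel_id,
                    "start_mm": e.start_mm,
                    "end_mm": e.end_mm,
                    "magnitude": e.magnitude,
                    "kind": e.kind,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(events)


def _pattern_summary(df: pd.DataFrame) -> dict:
    out = {}
    for p in PATTERNS:
        sub = df[df["pattern"] == p]
        out[p] = {
            "n": int(len(sub)),
            "mean_qvp": float(sub["qvp_index"].mean()) if len(sub) else None,
            "mean_post_qfr": float(sub["post_qfr"].mean()) if len(sub) else None,
            "suboptimal_rate": float(sub["suboptimal"].mean()) if len(sub) else None,
        }
    return out


def _tertile_summary(df: pd.DataFrame) -> dict:
    out = {}
    for t in TERTILE_ORDER:
        sub = df[df["qvp_tertile"] == t]
        out[t] = {
            "n": int(len(sub)),
            "suboptimal_rate": float(sub["suboptimal"].mean()) if len(sub) else None,
            "median_post_qfr": float(sub["post_qfr"].median()) if len(sub) else None,
        }
    return out


def analyze_cohort(
    vessels: Sequence[SyntheticVessel],
    thresholds: Thresholds | None = None,
    seed: int = 0,
    n_resamples: int = 100_000,
) -> dict:
    """Full statistical report for a simulated cohort, as a JSON-ready dict."""
    th = thresholds or Thresholds()
    df = score_cohort(vessels, thresholds=th)
    report: dict = {
        "n_vessels": int(len(df)),
        "n_patients": int(df["patient_id"].nunique()),
        "seed": int(seed),
        "thresholds": {
            "focal_pred_cutoff": th.focal_pred_cutoff,
            "diffuse_pred_cutoff": th.diffuse_pred_cutoff,
            "suboptimal_qvp_cutoff": th.suboptimal_qvp_cutoff,
            "tertile_bounds": list(th.tertile_bounds),
            "suboptimal_post_qfr": th.suboptimal_post_qfr,
        },
        "by_pattern": _pattern_summary(df),
        "by_tertile": _tertile_summary(df),
        "suboptimal_rate": float(df["suboptimal"].mean()),
        "mean_qvp": float(df["qvp_index"].mean()),
        "median_pre_qfr": float(df["distal_qfr"].median()),
        "median_post_qfr": float(df["post_qfr"].median()),
    }

    r, ci = pearson_r(df["qvp_index"], df["post_qfr"])
    report["pearson_qvp_post_qfr"] = {"r": r, "ci95": list(ci)}

    try:
        roc = roc_optimal_cutoff(
            df["qvp_index"].to_numpy(), df["suboptimal"].to_numpy(), DIRECTION_LOW
        )
        report["roc_suboptimal"] = {
            "auc": roc.auc,
            "optimal_cutoff": round(roc.optimal_cutoff, 2),
            "sensitivity": roc.sensitivity_at_optimum,
            "specificity": roc.specificity_at_optimum,
        }
    except DegenerateLabelsError as exc:
        log.warning("ROC analysis skipped: %s", exc)
        report["roc_suboptimal"] = None

    traces = [v.trace_pre for v in vessels]
    strict = QualitativePatternClassifier(**STRICT_PRESET).fit().predict(traces)
    lenient = QualitativePatternClassifier(**LENIENT_PRESET).fit().predict(traces)
    kappa, kci = cohens_kappa(strict, lenient)
    report["kappa_strict_vs_lenient"] = {"kappa": kappa, "ci95": list(kci)}

    try:
        gt = group_tests(
            continuous={"qvp_index": df["qvp_index"].to_numpy(),
                        "post_qfr": df["post_qfr"].to_numpy()},
            categorical={"suboptimal": df["suboptimal"].to_numpy()},
            groups=df["pattern"].to_numpy(),
            n_resamples=n_resamples,
            seed=seed,
        )
        report["group_tests"] = [
            {"name": g.name, "p_raw": g.p_raw, "p_bonferroni": g.p_bonferroni}
            for g in gt
        ]
    except QfrPullbackError as exc:
        log.warning("group comparisons skipped: %s", exc)
        report["group_tests"] = None

    try:
        X = pd.DataFrame(
            {
                "focal": (df["pattern"] == FOCAL).astype(float),
                "diffuse": (df["pattern"] == DIFFUSE).astype(float),
            }
        )
        betas = standardized_beta(df["post_qfr"], X, cluster=df["patient_id"])
        report["std_beta_pattern"] = [
            {"predictor": b.predictor, "beta": b.beta, "ci95": [b.ci_low, b.ci_high],
             "p": b.p_value}
            for b in betas
        ]
    except QfrPullbackError as exc:
        log.warning("pattern regression skipped: %s", exc)
        report["std_beta_pattern"] = None

    try:
        betas_qvp = standardized_beta(
            df["post_qfr"], pd.DataFrame({"qvp_index": df["qvp_index"]}),
            cluster=df["patient_id"],
        )
        b = betas_qvp[0]
        report["std_beta_qvp"] = {
            "beta": b.beta, "ci95": [b.ci_low, b.ci_high], "p": b.p_value
        }
    except QfrPullbackError as exc:
        log.warning("QVP regression skipped: %s", exc)
        report["std_beta_qvp"] = None
    return report
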