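"""Shapley feature attribution and the rescued-embryo analysis.

Attributions are exact TreeSHAP values computed natively by XGBoost
(``pred_contribs`` prediction mode) in margin (log-odds) space, so the
efficiency axiom holds exactly: per sample, attributions plus the base
value sum to the model's margin output.

A *rescued* embryo is one the without-cohort classifier gets wrong and the
with-cohort classifier gets right at the operating threshold; comparing the
cohort features of rescued embryos against the mean over all cohorts of the
erroneously predicted label shows which sibling properties drive the
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost
from scipy import stats

from .data_model import Cohort
from .features import COHORT_FEATURE_NAMES, encode_cohort
from .modeling import PairedImplantationResults

__all__ = [
    "ImportanceReport",
    "RescueReport",
    "RescueComparison",
    "shapley_importance",
    "identify_rescued",
    "rescue_feature_comparison",
    "plot_importance",
]


@dataclass
class ImportanceReport:
    """Per-feature Shapley attribution summary for one fitted model."""

    features: list[str]
    attributions: pd.DataFrame  # per-sample, per-feature, margin space
    base_value: float
    margin_output: np.ndarray

    @property
    def mean_abs(self) -> pd.Series:
        return self.attributions.abs().mean(axis=0).sort_values(ascending=False)

    @property
    def ranking(self) -> list[str]:
        return list(self.mean_abs.index)

    def top(self, k: int = 10) -> pd.Series:
        return self.mean_abs.head(k)

    def local_accuracy_error(self) -> float:
        """Max |sum(attributions) + base - margin| over all samples."""
        recon = self.attributions.sum(axis=1).to_numpy() + self.base_value
        return float(np.max(np.abs(recon - self.margin_output)))

    def to_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "mean_abs_attribution": {k: float(v) for k, v in self.mean_abs.items()},
            "base_value": self.base_value,
            "local_accuracy_error": self.local_accuracy_error(),
        }


def shapley_importance(model, features: pd.DataFrame) -> ImportanceReport:
    """Exact tree-path Shapley attributions for every sample and feature.

    ``model`` is a fitted XGBoost classifier trained on exactly the columns
    of ``features``; ranking is by mean absolute attribution.
    """
    booster = model.get_booster()
    trained = booster.feature_names
    if trained is not None and list(features.columns) != list(trained):
        raise ValueError(
            f"feature columns {list(features.columns)} do not match the "
            f"model's training columns {list(trained)}"
        )
    dm = xgboost.DMatrix(features)
    contribs = booster.predict(dm, pred_contribs=True)
    margin = booster.predict(dm, output_margin=True)
    attributions = pd.DataFrame(contribs[:, :-1], columns=list(features.columns))
    base = float(contribs[0, -1])
    return ImportanceReport(
        features=list(features.columns),
        attributions=attributions,
        base_value=base,
        margin_output=np.asarray(margin, dtype=float),
    )


@dataclass
class RescueReport:
    """Embryos partitioned by which classifier arm got them right."""

    threshold: float
    positive_rescued: list[str]  # implanted, corrected by the cohort arm
    negative_rescued: list[str]  # non-implanted, corrected by the cohort arm
    both_correct: list[str]
    both_wrong: list[str]
    broken: list[str]  # correct without cohort, wrong with it
    scores: pd.DataFrame

    @property
    def n_positive_rescued(self) -> int:
        return len(self.positive_rescued)

    @property
    def n_negative_rescued(self) -> int:
        return len(self.negative_rescued)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_positive_rescued": self.n_positive_rescued,
            "n_negative_rescued": self.n_negative_rescued,
            "n_both_correct": len(self.both_correct),
            "n_both_wrong": len(self.both_wrong),
            "n_broken": len(self.broken),
            "positive_rescued": self.positive_rescued,
            "negative_rescued": self.negative_rescued,
        }


def identify_rescued(
    paired: PairedImplantationResults,
    labels: Optional[Sequence[int]] = None,
    threshold: float = 0.5,
) -> RescueReport:
    """Partition matched test embryos by per-arm correctness at a threshold.

    Rescued embryos are wrong in the without-cohort arm and right in the
    with-cohort arm; they are split by true label (positive-rescued were
    implanted, negative-rescued were not).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    scores = paired.scores
    y = np.asarray(scores["label"] if labels is None else labels, dtype=int)
    pred_wo = (scores["score_without"].to_numpy() >= threshold).astype(int)
    pred_wi = (scores["score_with"].to_numpy() >= threshold).astype(int)
    ok_wo = pred_wo == y
    ok_wi = pred_wi == y
    ids = scores["embryo_id"].to_numpy()
    rescued = ~ok_wo & ok_wi
    return RescueReport(
        threshold=threshold,
        positive_rescued=list(ids[rescued & (y == 1)]),
        negative_rescued=list(ids[rescued & (y == 0)]),
        both_correct=list(ids[ok_wo & ok_wi]),
        both_wrong=list(ids[~ok_wo & ~ok_wi]),
        broken=list(ids[ok_wo & ~ok_wi]),
        scores=scores,
    )


@dataclass
class RescueComparison:
    """Rescued embryos' cohort feature vs the erroneous-label reference."""

    feature: str
    direction: str  # "positive_rescued" or "negative_rescued"
    rescued_values: np.ndarray
    reference_values: np.ndarray
    reference_mean: float
    statistic: Optional[float]
    p_value: Optional[float]

    def to_dict(self) -> dict:
        empty = len(self.rescued_values) == 0
        return {
            "feature": self.feature,
            "direction": self.direction,
            "n_rescued": len(self.rescued_values),
            "rescued_mean": None if empty else float(np.mean(self.rescued_values)),
            "rescued_sd": (
                None
                if len(self.rescued_values) < 2
                else float(np.std(self.rescued_values, ddof=1))
            ),
            "reference_mean": self.reference_mean,
            "reference_sd": float(np.std(self.reference_values, ddof=1)),
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def _cohort_property(cohort: Cohort, feature: str) -> Optional[float]:
    """Cohort-level value of a sibling-derived feature, excluding all
    transferred embryos (the convention of the label-wise comparisons)."""
    siblings = [e for e in cohort.embryos if not e.transferred]
    if feature == "cohort_size":
        return float(cohort.size)
    if not siblings:
        return None
    if feature == "frac_blastulation":
        return sum(e.blastulated for e in siblings) / len(siblings)
    if feature == "frac_hatched":
        return sum(
            1 for e in siblings if e.gardner is not None and e.gardner.expansion >= 5
        ) / len(siblings)
    raise ValueError(f"unsupported cohort feature {feature!r}")


def rescue_feature_comparison(
    rescued: RescueReport,
    cohorts: Sequence[Cohort],
    feature: str,
    direction: str = "positive_rescued",
) -> RescueComparison:
    """Compare a cohort feature of rescued embryos to the reference mean.

    Positive-rescued embryos (implanted, but predicted negative without the
    cohort) are compared against the mean of the feature over all *negative*
    cohorts in the full dataset, by Wilcoxon signed-rank on the differences
    from that reference mean; symmetrically for negative-rescued embryos.
    A single rescued embryo is reported without a test; an empty direction
    yields an empty comparison.
    """
    if direction not in ("positive_rescued", "negative_rescued"):
        raise ValueError(f"unknown direction {direction!r}")
    rescued_ids = set(getattr(rescued, direction))
    reference_label = "negative" if direction == "positive_rescued" else "positive"

    by_embryo: dict[str, Cohort] = {
        e.embryo_id: c for c in cohorts for e in c.embryos
    }
    rescued_values = []
    for eid in sorted(rescued_ids):
        cohort = by_embryo[eid]
        rescued_values.append(float(encode_cohort(cohort, eid)[feature]))
    reference_values = [
        v
        for c in cohorts
        if c.label == reference_label
        for v in [_cohort_property(c, feature)]
        if v is not None
    ]
    rescued_arr = np.asarray(rescued_values)
    reference_arr = np.asarray(reference_values)
    ref_mean = float(np.mean(reference_arr))

    statistic = p_value = None
    if len(rescued_arr) > 1:
        d = rescued_arr - ref_mean
        if np.all(d == 0):
            statistic, p_value = 0.0, 1.0
        else:
            s, p = stats.wilcoxon(d, alternative="two-sided")
            statistic, p_value = float(s), float(p)
    return RescueComparison(
        feature=feature,
        direction=direction,
        rescued_values=rescued_arr,
        reference_values=reference_arr,
        reference_mean=ref_mean,
        statistic=statistic,
        p_value=p_value,
    )


def plot_importance(report: ImportanceReport, path: str, k: int = 10) -> None:
    """Horizontal bar plot of the top-k mean absolute attributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = report.top(k)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1))
    ax.barh(top.index, top.to_numpy(), color="#4878a8")
    ax.set_xlabel("mean |Shapley attribution| (log-odds)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
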