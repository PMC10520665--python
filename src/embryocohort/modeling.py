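"""Paired implantation classifiers without vs with sibling-cohort features.

The central object is :class:`PairedImplantationModel`: built from a list of
cohorts and a base feature-block set, its :meth:`~PairedImplantationModel.fit`
trains two gradient-boosted tree classifiers under an identical protocol —
one on the base blocks only, one with the 16 sibling-cohort features added —
on a label-stratified cohort-level 80/20 split, and returns a
:class:`PairedImplantationResults` carrying matched test scores, both ROC
curves and AUCs, and the Wilcoxon signed-rank comparison of the matched
score pairs.  :meth:`~PairedImplantationModel.replicate` repeats the whole
procedure over independent repartitions.

Splitting is always at the cycle level so no cohort straddles train and
test.  Hyperparameters are tuned per arm by cross-validated AUC over a grid
on the six XGBoost dimensions: number of trees, minimum split loss (gamma),
maximum depth, instance subsample ratio, per-tree column subsample ratio,
and minimum child weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .data_model import Cohort
from .features import FeatureMatrix, assemble

__all__ = [
    "DEFAULT_GRID",
    "SplitSpec",
    "split_cohorts",
    "train_classifier",
    "select_features",
    "roc_auc",
    "PairedImplantationModel",
    "PairedImplantationResults",
    "ReplicationResults",
    "paired_evaluation",
    "replicate",
]

#: Small documented default grid over the six tuned hyperparameter
#: dimensions (single-valued dimensions are still part of the search space).
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "gamma": [0.0],
    "max_depth": [2, 3],
    "subsample": [1.0],
    "colsample_bytree": [0.8],
    "min_child_weight": [1, 5],
}


@dataclass(frozen=True)
class SplitSpec:
    """Cohort-level train/test partition (disjoint, label-stratified)."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int


def split_cohorts(
    cohorts: Sequence[Cohort], test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Label-stratified cohort-level split; no cycle straddles the sets."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    by_label: dict[str, list[str]] = {"positive": [], "negative": []}
    for c in cohorts:
        by_label[c.label].append(c.cycle_id)
    for lab, ids in by_label.items():
        if len(ids) < 5:
            raise ValueError(f"need at least 5 {lab} cohorts, found {len(ids)}")
    rng = np.random.default_rng(seed)
    test: list[str] = []
    train: list[str] = []
    for ids in by_label.values():
        ids = sorted(ids)
        rng.shuffle(ids)
        n_test = int(round(test_fraction * len(ids)))
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return SplitSpec(frozenset(train), frozenset(test), seed)


def _make_estimator(seed: int) -> XGBClassifier:
    return XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        eval_metric="logloss",
        n_jobs=1,
        random_state=seed,
    )


def train_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    tuning_grid: Optional[Mapping[str, list]] = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> GridSearchCV:
    """Grid-tuned XGBoost binary classifier (CV-AUC criterion).

    Returns the fitted :class:`GridSearchCV`; ``.best_estimator_`` exposes
    probability scores in [0, 1] via ``predict_proba``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    grid = dict(DEFAULT_GRID if tuning_grid is None else tuning_grid)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        _make_estimator(seed), grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True
    )
    gs.fit(X, y)
    return gs


def select_features(
    X: pd.DataFrame, y: np.ndarray, k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Keep the top-``k`` columns by extremely-randomised-trees importance.

    Identity when the matrix already has at most ``k`` columns.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[1] <= k:
        return X
    forest = ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    forest.fit(X, np.asarray(y))
    order = np.argsort(forest.feature_importances_, kind="stable")[::-1][:k]
    keep = [X.columns[i] for i in sorted(order)]  # preserve column order
    return X[keep]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """ROC-AUC (rank statistic; ties count one-half) plus the curve points."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, points


def _wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank; identical vectors give p = 1."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    return float(stat), float(p)


@dataclass
class PairedImplantationResults:
    """Matched evaluation of the without- vs with-cohort classifier pair."""

    base_blocks: tuple[str, ...]
    split: SplitSpec
    scores: pd.DataFrame  # embryo_id, cycle_id, label, score_without, score_with
    auc_without: float
    auc_with: float
    roc_without: pd.DataFrame
    roc_with: pd.DataFrame
    wilcoxon_statistic: float
    wilcoxon_p: float
    best_params: dict[str, dict]
    selected_features: dict[str, list[str]]
    models: dict[str, object] = field(repr=False, default_factory=dict)
    feature_matrices: dict[str, FeatureMatrix] = field(repr=False, default_factory=dict)

    @property
    def delta_auc(self) -> float:
        return self.auc_with - self.auc_without

    def summary(self) -> str:
        lines = [
            "Paired implantation model (without vs with cohort features)",
            "=" * 60,
            f"base blocks:        {', '.join(self.base_blocks)}",
            f"test embryos:       {len(self.scores)} "
            f"({int(self.scores['label'].sum())} positive)",
            f"AUC without cohort: {self.auc_without:.3f}",
            f"AUC with cohort:    {self.auc_with:.3f}",
            f"delta AUC:          {self.delta_auc:+.3f}",
            f"Wilcoxon signed-rank on matched scores: "
            f"W={self.wilcoxon_statistic:.1f}, p={self.wilcoxon_p:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "base_blocks": list(self.base_blocks),
            "n_test": len(self.scores),
            "auc_without": self.auc_without,
            "auc_with": self.auc_with,
            "delta_auc": self.delta_auc,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_p": self.wilcoxon_p,
            "best_params": self.best_params,
            "selected_features": self.selected_features,
        }


@dataclass
class ReplicationResults:
    """Per-replicate AUC pairs over independent repartitions."""

    base_blocks: tuple[str, ...]
    auc_pairs: pd.DataFrame  # replicate, seed, auc_without, auc_with
    wilcoxon_statistic: float
    wilcoxon_p: float

    @property
    def mean_auc_without(self) -> float:
        return float(self.auc_pairs["auc_without"].mean())

    @property
    def mean_auc_with(self) -> float:
        return float(self.auc_pairs["auc_with"].mean())

    @property
    def mean_delta_auc(self) -> float:
        return self.mean_auc_with - self.mean_auc_without

    def summary(self) -> str:
        p = self.auc_pairs
        wins = int((p["auc_with"] > p["auc_without"]).sum())
        lines = [
            f"Replication over {len(p)} independent repartitions",
            "=" * 60,
            f"base blocks:          {', '.join(self.base_blocks)}",
            f"AUC without cohort:   {p['auc_without'].mean():.3f} "
            f"({p['auc_without'].std(ddof=1):.3f})",
            f"AUC with cohort:      {p['auc_with'].mean():.3f} "
            f"({p['auc_with'].std(ddof=1):.3f})",
            f"mean delta AUC:       {self.mean_delta_auc:+.3f} "
            f"(with-cohort wins {wins}/{len(p)})",
            f"Wilcoxon signed-rank on AUC pairs: "
            f"W={self.wilcoxon_statistic:.1f}, p={self.wilcoxon_p:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.auc_pairs
        return {
            "base_blocks": list(self.base_blocks),
            "n_replicates": len(p),
            "auc_without_mean": float(p["auc_without"].mean()),
            "auc_without_sd": float(p["auc_without"].std(ddof=1)),
            "auc_with_mean": float(p["auc_with"].mean()),
            "auc_with_sd": float(p["auc_with"].std(ddof=1)),
            "mean_delta_auc": self.mean_delta_auc,
            "with_wins": int((p["auc_with"] > p["auc_without"]).sum()),
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_p": self.wilcoxon_p,
            "auc_pairs": p.to_dict(orient="list"),
        }


class PairedImplantationModel:
    """Paired without/with-cohort implantation model over a cohort dataset.

    Parameters
    ----------
    cohorts
        Validated cohorts (labels derive from the transferred embryos).
    base_blocks
        Embryo-level feature blocks for the without-cohort arm; the
        with-cohort arm adds the sibling-derived ``cohort`` block.
    tuning_grid
        XGBoost hyperparameter grid (defaults to :data:`DEFAULT_GRID`).
    select_k
        When set, per-arm feature selection to ``select_k`` columns by
        extra-trees importance, fitted on the training rows.
    """

    def __init__(
        self,
        cohorts: Sequence[Cohort],
        base_blocks: Iterable[str],
        tuning_grid: Optional[Mapping[str, list]] = None,
        test_fraction: float = 0.2,
        cv_folds: int = 5,
        select_k: Optional[int] = None,
        morphology_encoding: str = "onehot",
    ) -> None:
        self.cohorts = list(cohorts)
        self.base_blocks = tuple(base_blocks)
        if not self.base_blocks:
            raise ValueError("base_blocks must be nonempty")
        self.tuning_grid = tuning_grid
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        self.select_k = select_k
        self.morphology_encoding = morphology_encoding

    def _assemble_arms(self) -> tuple[FeatureMatrix, FeatureMatrix]:
        without = assemble(
            self.cohorts, self.base_blocks, morphology_encoding=self.morphology_encoding
        )
        with_blocks = tuple(self.base_blocks) + ("cohort",)
        with_ = assemble(
            self.cohorts, with_blocks, morphology_encoding=self.morphology_encoding
        )
        if without.embryo_ids != with_.embryo_ids:
            raise AssertionError("arms are not row-aligned")  # cohort block never drops rows
        return without, with_

    def fit(self, seed: int = 0, split: Optional[SplitSpec] = None) -> PairedImplantationResults:
        """Train both arms on one stratified split and evaluate on its test set."""
        without, with_ = self._assemble_arms()
        if split is None:
            split = split_cohorts(self.cohorts, self.test_fraction, seed)

        cycle = np.array(without.cycle_ids)
        train_mask = np.isin(cycle, sorted(split.train_ids))
        test_mask = np.isin(cycle, sorted(split.test_ids))

        arm_out: dict[str, dict] = {}
        for arm, fm in (("without", without), ("with", with_)):
            X_train, X_test = fm.X[train_mask], fm.X[test_mask]
            y_train = fm.y[train_mask]
            if self.select_k is not None:
                X_train = select_features(X_train, y_train, k=self.select_k, seed=seed)
                X_test = X_test[X_train.columns]
            gs = train_classifier(
                X_train, y_train, self.tuning_grid, self.cv_folds, seed=seed
            )
            arm_out[arm] = {
                "model": gs.best_estimator_,
                "params": gs.best_params_,
                "features": list(X_train.columns),
                "scores": gs.best_estimator_.predict_proba(X_test)[:, 1],
            }

        y_test = without.y[test_mask]
        scores = pd.DataFrame(
            {
                "embryo_id": np.array(without.embryo_ids)[test_mask],
                "cycle_id": cycle[test_mask],
                "label": y_test,
                "score_without": arm_out["without"]["scores"],
                "score_with": arm_out["with"]["scores"],
            }
        ).reset_index(drop=True)
        auc_wo, roc_wo = roc_auc(scores["score_without"], y_test)
        auc_wi, roc_wi = roc_auc(scores["score_with"], y_test)
        w_stat, w_p = _wilcoxon_paired(
            scores["score_with"].to_numpy(), scores["score_without"].to_numpy()
        )
        return PairedImplantationResults(
            base_blocks=self.base_blocks,
            split=split,
            scores=scores,
            auc_without=auc_wo,
            auc_with=auc_wi,
            roc_without=roc_wo,
            roc_with=roc_wi,
            wilcoxon_statistic=w_stat,
            wilcoxon_p=w_p,
            best_params={a: d["params"] for a, d in arm_out.items()},
            selected_features={a: d["features"] for a, d in arm_out.items()},
            models={a: d["model"] for a, d in arm_out.items()},
            feature_matrices={"without": without, "with": with_},
        )

    def replicate(
        self, n_replicates: int = 10, seed: int = 0, seeds: Optional[Sequence[int]] = None
    ) -> ReplicationResults:
        """Repeat fit/evaluate over independent repartitions of the cohorts."""
        if seeds is None:
            if n_replicates < 2:
                raise ValueError("n_replicates must be >= 2")
            rng = np.random.default_rng(seed)
            seeds = [int(s) for s in rng.integers(0, 2**31, size=n_replicates)]
        rows = []
        for r, s in enumerate(seeds):
            res = self.fit(seed=s)
            rows.append(
                {
                    "replicate": r,
                    "seed": s,
                    "auc_without": res.auc_without,
                    "auc_with": res.auc_with,
                }
            )
        pairs = pd.DataFrame(rows)
        w_stat, w_p = _wilcoxon_paired(
            pairs["auc_with"].to_numpy(), pairs["auc_without"].to_numpy()
        )
        return ReplicationResults(self.base_blocks, pairs, w_stat, w_p)


def paired_evaluation(
    cohorts: Sequence[Cohort],
    base_blocks: Iterable[str],
    seed: int = 0,
    **model_kwargs,
) -> PairedImplantationResults:
    """One-split paired evaluation (functional form of the model object)."""
    return PairedImplantationModel(cohorts, base_blocks, **model_kwargs).fit(seed=seed)


def replicate(
    cohorts: Sequence[Cohort],
    base_blocks: Iterable[str],
    n_replicates: int = 10,
    seed: int = 0,
    seeds: Optional[Sequence[int]] = None,
    **model_kwargs,
) -> ReplicationResults:
    """Replicated paired evaluation over independent repartitions."""
    model = PairedImplantationModel(cohorts, base_blocks, **model_kwargs)
    return model.replicate(n_replicates=n_replicates, seed=seed, seeds=seeds)
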