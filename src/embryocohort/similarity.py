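"""Intra- vs inter-cohort similarity statistics and cohort comparisons.

Sibling embryos (same IVF cycle) are expected to develop more alike than
random non-sibling pairs; these analyses quantify that with absolute
differences of single timing features, normalised multivariate profile
distances, a Gardner-matched triplet design that controls for morphological
quality, and positive- vs negative-cohort property comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CORE_EVENTS, Cohort
from .features import (
    KINETIC_FEATURE_NAMES,
    KINETIC_INTERVALS,
    complete_annotations,
    encode_kinetics,
)

__all__ = [
    "SimilarityReport",
    "TripletReport",
    "CohortComparison",
    "pairwise_differences",
    "fit_normalizer",
    "profile_distance",
    "triplet_analysis",
    "cohort_compare",
]

INTERVAL_FEATURES = [f"{b}-{a}" for b, a in KINETIC_INTERVALS]
EVENT_FEATURES = list(CORE_EVENTS)


@dataclass
class SimilarityReport:
    """Sibling vs non-sibling absolute-difference samples for one feature."""

    feature: str
    sibling_values: np.ndarray
    nonsibling_values: np.ndarray
    statistic: float
    p_value: float

    @property
    def sibling_mean(self) -> float:
        return float(np.mean(self.sibling_values))

    @property
    def sibling_sd(self) -> float:
        return float(np.std(self.sibling_values, ddof=1))

    @property
    def nonsibling_mean(self) -> float:
        return float(np.mean(self.nonsibling_values))

    @property
    def nonsibling_sd(self) -> float:
        return float(np.std(self.nonsibling_values, ddof=1))

    @property
    def n_pairs(self) -> tuple[int, int]:
        return (len(self.sibling_values), len(self.nonsibling_values))

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "sibling_mean": self.sibling_mean,
            "sibling_sd": self.sibling_sd,
            "nonsibling_mean": self.nonsibling_mean,
            "nonsibling_sd": self.nonsibling_sd,
            "n_sibling_pairs": len(self.sibling_values),
            "n_nonsibling_pairs": len(self.nonsibling_values),
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


@dataclass
class TripletReport:
    """Gardner-matched ordered-triplet comparison of profile distances."""

    n_triplets: int
    sibling_distances: np.ndarray
    nonsibling_distances: np.ndarray
    statistic: Optional[float]
    p_value: Optional[float]

    def to_dict(self) -> dict:
        empty = self.n_triplets == 0
        return {
            "n_triplets": self.n_triplets,
            "sibling_mean": None if empty else float(np.mean(self.sibling_distances)),
            "nonsibling_mean": None if empty else float(np.mean(self.nonsibling_distances)),
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def _feature_value(embryo, feature: str) -> Optional[float]:
    mk = embryo.morphokinetics
    if "-" in feature:
        b, a = feature.split("-")
        if b in mk and a in mk:
            return mk[b] - mk[a]
        return None
    return mk.get(feature)


def pairwise_differences(
    cohorts: Sequence[Cohort],
    feature: str,
    n_nonsibling_pairs: Optional[int] = None,
    seed: int = 0,
) -> SimilarityReport:
    """Compare |Δfeature| over all sibling pairs vs random non-sibling pairs.

    ``feature`` is an event name (``"t3"``) or a consecutive interval
    (``"t3-t2"``).  The non-sibling sample is drawn uniformly over
    cross-cohort pairs with a seed; by default it matches the sibling-pair
    count.  Two-sided Mann-Whitney U compares the samples.
    """
    values: list[tuple[int, float]] = []  # (cohort index, feature value)
    for ci, cohort in enumerate(cohorts):
        for e in cohort.embryos:
            v = _feature_value(e, feature)
            if v is not None:
                values.append((ci, v))
    cohort_ids = {ci for ci, _ in values}
    if len(cohort_ids) < 2:
        raise ValueError("need the feature observed in at least 2 cohorts")

    by_cohort: dict[int, list[float]] = {}
    for ci, v in values:
        by_cohort.setdefault(ci, []).append(v)

    sibling = np.array(
        [
            abs(vs[i] - vs[j])
            for vs in by_cohort.values()
            for i in range(len(vs))
            for j in range(i + 1, len(vs))
        ]
    )
    if sibling.size == 0:
        raise ValueError("no within-cohort pair has the feature observed twice")

    n_pairs = len(sibling) if n_nonsibling_pairs is None else int(n_nonsibling_pairs)
    rng = np.random.default_rng(seed)
    ci_arr = np.array([ci for ci, _ in values])
    v_arr = np.array([v for _, v in values])
    nonsibling = np.empty(n_pairs)
    for k in range(n_pairs):
        while True:
            i, j = rng.integers(0, len(values), size=2)
            if ci_arr[i] != ci_arr[j]:
                break
        nonsibling[k] = abs(v_arr[i] - v_arr[j])

    stat, p = stats.mannwhitneyu(sibling, nonsibling, alternative="two-sided")
    return SimilarityReport(feature, sibling, nonsibling, float(stat), float(p))


def fit_normalizer(vectors: pd.DataFrame) -> pd.DataFrame:
    """Per-feature min/max bounds fitted once on the full analysis set."""
    return pd.DataFrame({"min": vectors.min(axis=0), "max": vectors.max(axis=0)})


def profile_distance(
    a: pd.Series,
    b: pd.Series,
    normalizer: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
) -> float:
    """Euclidean distance between min-max-normalised kinetic profiles.

    ``features`` selects the sub-vector (e.g. the five intervals or the six
    event times); default is every feature in the normaliser.  A zero-range
    feature contributes 0 with a warning.
    """
    names = list(normalizer.index if features is None else features)
    lo = normalizer.loc[names, "min"].to_numpy()
    hi = normalizer.loc[names, "max"].to_numpy()
    span = hi - lo
    degenerate = span <= 0
    if degenerate.any():
        warnings.warn(
            f"zero-range features contribute 0 to distance: "
            f"{[n for n, d in zip(names, degenerate) if d]}"
        )
        span = np.where(degenerate, 1.0, span)
    av = (a[names].to_numpy() - lo) / span
    bv = (b[names].to_numpy() - lo) / span
    diff = np.where(degenerate, 0.0, av - bv)
    return float(np.sqrt((diff**2).sum()))


def triplet_analysis(
    cohorts: Sequence[Cohort],
    max_triplets: int = 1_000_000,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
) -> TripletReport:
    """Sibling vs non-sibling profile distances at matched Gardner scores.

    Enumerates every ordered triplet (X1, X2, Y1) with X1, X2 siblings,
    Y1 from a different cohort, and all three embryos sharing the exact
    three-part Gardner score; compares d(X1, X2) against d(X2, Y1) by
    two-sided Mann-Whitney U.  Above ``max_triplets`` a seeded uniform
    subsample is used.  No qualifying triplet yields an empty report.
    """
    completed, log = complete_annotations(cohorts)
    usable = []  # (cohort index, gardner tuple, kinetic vector)
    for ci, cohort in enumerate(completed):
        for e in cohort.embryos:
            if e.gardner is None or e.embryo_id in log.excluded:
                continue
            if not all(ev in e.morphokinetics for ev in CORE_EVENTS):
                continue
            usable.append((ci, e.gardner.as_tuple(), encode_kinetics(e)))
    if features is None:
        features = INTERVAL_FEATURES
    if not usable:
        return TripletReport(0, np.array([]), np.array([]), None, None)

    vectors = pd.DataFrame([v for _, _, v in usable])
    normalizer = fit_normalizer(vectors)

    groups: dict[tuple, list[int]] = {}
    for idx, (_, g, _) in enumerate(usable):
        groups.setdefault(g, []).append(idx)

    triplets: list[tuple[int, int, int]] = []
    for members in groups.values():
        by_cohort: dict[int, list[int]] = {}
        for idx in members:
            by_cohort.setdefault(usable[idx][0], []).append(idx)
        for ci, sibs in by_cohort.items():
            if len(sibs) < 2:
                continue
            others = [idx for cj, lst in by_cohort.items() if cj != ci for idx in lst]
            if not others:
                continue
            for x1 in sibs:
                for x2 in sibs:
                    if x1 == x2:
                        continue
                    for y1 in others:
                        triplets.append((x1, x2, y1))

    if not triplets:
        return TripletReport(0, np.array([]), np.array([]), None, None)
    if len(triplets) > max_triplets:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(triplets), size=max_triplets, replace=False)
        triplets = [triplets[i] for i in sorted(keep)]

    # vectorised equivalent of profile_distance over all triplets
    names = list(features)
    lo = normalizer.loc[names, "min"].to_numpy()
    hi = normalizer.loc[names, "max"].to_numpy()
    span = np.where(hi > lo, hi - lo, 1.0)
    V = (vectors[names].to_numpy() - lo) / span
    V[:, hi <= lo] = 0.0
    t = np.asarray(triplets)
    sib = np.sqrt(((V[t[:, 0]] - V[t[:, 1]]) ** 2).sum(axis=1))
    non = np.sqrt(((V[t[:, 1]] - V[t[:, 2]]) ** 2).sum(axis=1))
    stat, p = stats.mannwhitneyu(sib, non, alternative="two-sided")
    return TripletReport(len(triplets), sib, non, float(stat), float(p))


@dataclass
class CohortComparison:
    """Positive- vs negative-cohort distribution of one cohort property."""

    property: str
    positive_values: np.ndarray
    negative_values: np.ndarray
    statistic: Optional[float]
    p_value: Optional[float]
    category_fractions: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "property": self.property,
            "positive_mean": float(np.mean(self.positive_values)),
            "positive_sd": float(np.std(self.positive_values, ddof=1)),
            "negative_mean": float(np.mean(self.negative_values)),
            "negative_sd": float(np.std(self.negative_values, ddof=1)),
            "n_positive": len(self.positive_values),
            "n_negative": len(self.negative_values),
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.category_fractions is not None:
            d["category_fractions"] = self.category_fractions.to_dict()
        return d


_GARDNER_ORDINAL = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}


def cohort_compare(cohorts: Sequence[Cohort], property: str) -> CohortComparison:
    """Compare one sibling-derived cohort property across outcome labels.

    Scalar properties (``cohort_size``, ``frac_blastulation``,
    ``frac_hatched``) yield per-cohort samples.  Gardner parts
    (``gardner_expansion``, ``gardner_icm``, ``gardner_te``) pool sibling
    scores (ordinal-coded, A=4..D=1) by label and additionally report
    per-category sibling fractions.  Siblings exclude all transferred
    embryos.  Two-sided Mann-Whitney U across labels.
    """
    labels = {c.label for c in cohorts}
    if labels != {"positive", "negative"}:
        raise ValueError("need both positive and negative cohorts")

    scalar = {"cohort_size", "frac_blastulation", "frac_hatched"}
    gardner_parts = {"gardner_expansion", "gardner_icm", "gardner_te"}
    if property not in scalar | gardner_parts:
        raise ValueError(f"unknown property {property!r}")

    if property in scalar:
        samples = {"positive": [], "negative": []}
        for c in cohorts:
            siblings = [e for e in c.embryos if not e.transferred]
            if property == "cohort_size":
                v = float(c.size)
            elif not siblings:
                continue
            elif property == "frac_blastulation":
                v = sum(e.blastulated for e in siblings) / len(siblings)
            else:
                v = sum(
                    1 for e in siblings if e.gardner is not None and e.gardner.expansion >= 5
                ) / len(siblings)
            samples[c.label].append(v)
        pos, neg = np.array(samples["positive"]), np.array(samples["negative"])
        stat, p = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        return CohortComparison(property, pos, neg, float(stat), float(p))

    part = property.removeprefix("gardner_")
    pooled = {"positive": [], "negative": []}
    counts = {"positive": {}, "negative": {}}
    n_sib = {"positive": 0, "negative": 0}
    for c in cohorts:
        for e in c.embryos:
            if e.transferred:
                continue
            n_sib[c.label] += 1
            if e.gardner is None:
                continue
            if part == "expansion":
                v = float(e.gardner.expansion)
                cat = str(e.gardner.expansion)
            else:
                letter = e.gardner.icm if part == "icm" else e.gardner.te
                v = _GARDNER_ORDINAL[letter]
                cat = letter
            pooled[c.label].append(v)
            counts[c.label][cat] = counts[c.label].get(cat, 0) + 1
    pos, neg = np.array(pooled["positive"]), np.array(pooled["negative"])
    stat, p = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    cats = sorted(set(counts["positive"]) | set(counts["negative"]))
    frac = pd.DataFrame(
        {
            lab: [counts[lab].get(c, 0) / max(n_sib[lab], 1) for c in cats]
            for lab in ("positive", "negative")
        },
        index=cats,
    )
    return CohortComparison(property, pos, neg, float(stat), float(p), frac)
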