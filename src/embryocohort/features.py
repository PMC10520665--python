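"""Feature encoders and morphokinetic annotation completion.

Three feature blocks describe the transferred embryo itself (one-hot Gardner
morphology, the 11-entry kinetic vector, oocyte age, optional image-model
confidence score) and one block summarises its non-transferred siblings
(cohort size, sibling blastulation and hatching fractions, and the sibling
Gardner-grade fractions).

Missing event annotations are completed in two stages before kinetic
encoding: expert offset rules between adjacent events, then a 5-nearest-
neighbour mean for embryos still missing exactly one of the six core events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CORE_EVENTS,
    Cohort,
    EmbryoRecord,
    EXPANSION_LABELS,
    GardnerScore,
    ICM_TE_CATEGORIES,
)

__all__ = [
    "MORPHO_FEATURE_NAMES",
    "KINETIC_FEATURE_NAMES",
    "COHORT_FEATURE_NAMES",
    "CompletionLog",
    "FeatureMatrix",
    "complete_annotations",
    "encode_morphology",
    "encode_morphology_ordinal",
    "encode_kinetics",
    "encode_cohort",
    "assemble",
]

#: 6 expansion + 4 ICM + 4 TE one-hot entries = 14.
MORPHO_FEATURE_NAMES = (
    [f"exp_{g}" for g in range(1, 7)]
    + [f"icm_{c}" for c in ICM_TE_CATEGORIES]
    + [f"te_{c}" for c in ICM_TE_CATEGORIES]
)

#: 5 consecutive intervals + 6 absolute event times = 11.
KINETIC_INTERVALS = [("t3", "t2"), ("t4", "t3"), ("t8", "t4"), ("tM", "t8"), ("tSB", "tM")]
KINETIC_FEATURE_NAMES = [f"{b}-{a}" for b, a in KINETIC_INTERVALS] + list(CORE_EVENTS)

#: 1 size + 1 blastulation fraction + 1 hatched fraction + 13 Gardner
#: fractions (5 expansion + 4 ICM + 4 TE) = 16 sibling-derived entries.
COHORT_FEATURE_NAMES = (
    ["cohort_size", "frac_blastulation", "frac_hatched"]
    + [f"frac_exp_{EXPANSION_LABELS[g]}" for g in range(2, 7)]
    + [f"frac_icm_{c}" for c in ICM_TE_CATEGORIES]
    + [f"frac_te_{c}" for c in ICM_TE_CATEGORIES]
)

# Expert completion rules: target event <- (source event, offset in minutes).
# The rules fire only when the source was observed (not itself rule-filled),
# which makes their application order irrelevant.
COMPLETION_RULES = {
    "t2": ("tPNf", 120.0),
    "t4": ("t3", 60.0),
    "t3": ("t4", -60.0),
    "t8": ("t7", 180.0),
    "tM": ("tSB", -360.0),
}


@dataclass
class CompletionLog:
    """Record of every completed annotation and every excluded embryo."""

    entries: list[dict] = field(default_factory=list)
    excluded: set[str] = field(default_factory=set)

    @property
    def n_rule(self) -> int:
        return sum(1 for e in self.entries if e["method"].startswith("rule"))

    @property
    def n_knn(self) -> int:
        return sum(1 for e in self.entries if e["method"] == "5nn")


def complete_annotations(cohorts: Iterable[Cohort]) -> tuple[list[Cohort], CompletionLog]:
    """Two-stage completion of missing core-event annotations.

    Stage 1 applies the expert offset rules (t2 = tPNf + 2 h, t4 = t3 + 1 h,
    t3 = t4 - 1 h, t8 = t7 + 3 h, tM = tSB - 6 h), each firing only when its
    source event was observed.  Stage 2 fills embryos still missing exactly
    one core event with the mean of that event over the five most similar
    fully annotated embryos (Euclidean distance on the min-max-normalised
    events both embryos share).  Embryos missing more than one core event
    after both stages are flagged excluded-from-kinetics.

    Returns a deep copy; the input is untouched.  Idempotent: a second pass
    changes nothing.
    """
    out = [c.copy() for c in cohorts]
    log = CompletionLog()
    embryos = [e for c in out for e in c.embryos]

    # stage 1: offset rules from observed sources only
    for e in embryos:
        observed = dict(e.morphokinetics)
        for target, (source, offset) in COMPLETION_RULES.items():
            if target not in observed and source in observed:
                value = observed[source] + offset
                if value >= 0:
                    e.morphokinetics[target] = value
                    log.entries.append(
                        {
                            "embryo_id": e.embryo_id,
                            "event": target,
                            "method": f"rule:{source}{offset:+g}min",
                            "value": value,
                        }
                    )

    # stage 2: 5-NN mean for a single remaining gap
    need_knn = []
    for e in embryos:
        missing = [ev for ev in CORE_EVENTS if ev not in e.morphokinetics]
        if len(missing) == 1:
            need_knn.append((e, missing[0]))
        elif len(missing) > 1:
            log.excluded.add(e.embryo_id)

    if need_knn:
        complete = [e for e in embryos if all(ev in e.morphokinetics for ev in CORE_EVENTS)]
        if len(complete) < 6:
            raise ValueError(
                f"5-NN completion infeasible: only {len(complete)} fully annotated embryos"
            )
        pool = np.array(
            [[e.morphokinetics[ev] for ev in CORE_EVENTS] for e in complete]
        )
        # min-max bounds over all observed values in the dataset
        lo = np.full(len(CORE_EVENTS), np.inf)
        hi = np.full(len(CORE_EVENTS), -np.inf)
        for e in embryos:
            for k, ev in enumerate(CORE_EVENTS):
                if ev in e.morphokinetics:
                    lo[k] = min(lo[k], e.morphokinetics[ev])
                    hi[k] = max(hi[k], e.morphokinetics[ev])
        span = np.where(hi > lo, hi - lo, 1.0)
        pool_norm = (pool - lo) / span

        for e, target in need_knn:
            k_obs = [k for k, ev in enumerate(CORE_EVENTS) if ev in e.morphokinetics]
            q = np.array(
                [(e.morphokinetics[CORE_EVENTS[k]] - lo[k]) / span[k] for k in k_obs]
            )
            cand_mask = np.array([c.embryo_id != e.embryo_id for c in complete])
            d = np.sqrt(((pool_norm[:, k_obs] - q) ** 2).sum(axis=1))
            d[~cand_mask] = np.inf
            nn = np.argsort(d, kind="stable")[:5]
            t_idx = CORE_EVENTS.index(target)
            value = float(np.mean(pool[nn, t_idx]))
            e.morphokinetics[target] = value
            log.entries.append(
                {
                    "embryo_id": e.embryo_id,
                    "event": target,
                    "method": "5nn",
                    "value": value,
                    "neighbors": [complete[i].embryo_id for i in nn],
                }
            )
    return out, log


def encode_morphology(g: GardnerScore) -> pd.Series:
    """One-hot encode the three Gardner parts into 14 binary entries."""
    v = pd.Series(0.0, index=MORPHO_FEATURE_NAMES)
    v[f"exp_{g.expansion}"] = 1.0
    v[f"icm_{g.icm}"] = 1.0
    v[f"te_{g.te}"] = 1.0
    return v


def encode_morphology_ordinal(g: GardnerScore) -> pd.Series:
    """Ordinal recoding (expansion 1-6; A..D -> 4..1), used for attribution."""
    letter = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}
    return pd.Series(
        {"exp": float(g.expansion), "icm": letter[g.icm], "te": letter[g.te]}
    )


def encode_kinetics(e: EmbryoRecord) -> pd.Series:
    """11-entry kinetic vector: 5 consecutive intervals + 6 event times (min)."""
    missing = [ev for ev in CORE_EVENTS if ev not in e.morphokinetics]
    if missing:
        raise ValueError(
            f"embryo {e.embryo_id} missing events {missing}; complete annotations first"
        )
    t = e.morphokinetics
    values = [t[b] - t[a] for b, a in KINETIC_INTERVALS] + [t[ev] for ev in CORE_EVENTS]
    return pd.Series(values, index=KINETIC_FEATURE_NAMES, dtype=float)


def encode_cohort(cohort: Cohort, transferred_id: str) -> pd.Series:
    """16-entry sibling summary attached to one transferred embryo.

    Siblings are all cohort embryos except the one under evaluation (for a
    double transfer the other transferred embryo counts as a sibling); only
    ``cohort_size`` includes the embryo itself.  Gardner fractions use the
    total sibling count as denominator, so non-blastulating siblings (which
    carry no Gardner score) leave mass out of every block.
    """
    siblings = cohort.siblings_of(transferred_id)
    v = pd.Series(0.0, index=COHORT_FEATURE_NAMES)
    v["cohort_size"] = float(cohort.size)
    if not siblings:
        warnings.warn(
            f"cohort {cohort.cycle_id}: singleton cohort, sibling fractions set to 0"
        )
        return v
    n = len(siblings)
    v["frac_blastulation"] = sum(e.blastulated for e in siblings) / n
    v["frac_hatched"] = (
        sum(1 for e in siblings if e.gardner is not None and e.gardner.expansion >= 5) / n
    )
    for e in siblings:
        if e.gardner is None:
            continue
        if e.gardner.expansion >= 2:
            v[f"frac_exp_{EXPANSION_LABELS[e.gardner.expansion]}"] += 1.0 / n
        v[f"frac_icm_{e.gardner.icm}"] += 1.0 / n
        v[f"frac_te_{e.gardner.te}"] += 1.0 / n
    return v


VALID_BLOCKS = ("morphology", "kinetics", "age", "dl_score", "cohort")


@dataclass
class FeatureMatrix:
    """Named-column numeric matrix over transferred embryos, with labels."""

    X: pd.DataFrame
    y: np.ndarray
    embryo_ids: list[str]
    cycle_ids: list[str]
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.X)


def assemble(
    cohorts: Sequence[Cohort],
    blocks: Iterable[str],
    morphology_encoding: str = "onehot",
    completion_log: Optional[CompletionLog] = None,
) -> FeatureMatrix:
    """Build the feature matrix for all transferred embryos.

    ``blocks`` selects any subset of morphology / kinetics / age / dl_score /
    cohort; column names carry a block prefix.  Embryos lacking a requested
    block (no Gardner score, excluded from kinetics, missing image score)
    are dropped with per-reason counts recorded in ``dropped``.

    Kinetic features are computed on an internally completed copy of the
    dataset; the cohort block always uses the raw annotations so that an
    imputed blastulation time never counts as blastulation.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("at least one feature block is required")
    unknown = [b for b in blocks if b not in VALID_BLOCKS]
    if unknown:
        raise ValueError(f"unknown feature blocks: {unknown}")
    if morphology_encoding not in ("onehot", "ordinal"):
        raise ValueError(f"unknown morphology encoding {morphology_encoding!r}")

    kinetics_by_id: dict[str, EmbryoRecord] = {}
    if "kinetics" in blocks:
        completed, log = complete_annotations(cohorts)
        if completion_log is not None:
            completion_log.entries.extend(log.entries)
            completion_log.excluded.update(log.excluded)
        kinetics_by_id = {
            e.embryo_id: e
            for c in completed
            for e in c.embryos
            if e.embryo_id not in log.excluded
            and all(ev in e.morphokinetics for ev in CORE_EVENTS)
        }

    rows, labels, embryo_ids, cycle_ids = [], [], [], []
    dropped = {"missing_gardner": 0, "excluded_kinetics": 0, "missing_dl_score": 0}
    morph_encode = (
        encode_morphology if morphology_encoding == "onehot" else encode_morphology_ordinal
    )

    for cohort in cohorts:
        for e in cohort.transferred_embryos:
            parts = []
            skip = None
            for block in blocks:
                if block == "morphology":
                    if e.gardner is None:
                        skip = "missing_gardner"
                        break
                    parts.append(morph_encode(e.gardner).add_prefix("morph_"))
                elif block == "kinetics":
                    if e.embryo_id not in kinetics_by_id:
                        skip = "excluded_kinetics"
                        break
                    parts.append(
                        encode_kinetics(kinetics_by_id[e.embryo_id]).add_prefix("kin_")
                    )
                elif block == "age":
                    parts.append(pd.Series({"age": e.oocyte_age}))
                elif block == "dl_score":
                    if e.dl_confidence is None:
                        skip = "missing_dl_score"
                        break
                    parts.append(pd.Series({"dl_score": e.dl_confidence}))
                elif block == "cohort":
                    parts.append(
                        encode_cohort(cohort, e.embryo_id).add_prefix("coh_")
                    )
            if skip is not None:
                dropped[skip] += 1
                continue
            rows.append(pd.concat(parts))
            labels.append(1 if e.implanted else 0)
            embryo_ids.append(e.embryo_id)
            cycle_ids.append(cohort.cycle_id)

    X = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureMatrix(
        X=X,
        y=np.asarray(labels, dtype=int),
        embryo_ids=embryo_ids,
        cycle_ids=cycle_ids,
        dropped={k: v for k, v in dropped.items() if v},
    )
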