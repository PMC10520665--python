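"""End-to-end orchestration: simulate -> featurize -> similarity -> model ->
explain -> rescue, with deterministic per-stage seeding and a self-describing
JSON + Markdown report bundle.

Every stage seed is derived by hashing (global seed, stage name) so any
stage can be re-run in isolation and reproduce its part of the bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .data_model import Cohort, write_dataset
from .features import CompletionLog, assemble
from .modeling import (
    DEFAULT_GRID,
    PairedImplantationModel,
    split_cohorts,
    train_classifier,
)
from .explain import identify_rescued, rescue_feature_comparison, shapley_importance
from .similarity import cohort_compare, pairwise_differences, triplet_analysis
from .simulate import SimulationConfig, generate

__all__ = ["RunConfig", "stage_seed", "run_all", "DEFAULT_MODEL_PAIRS"]

logger = logging.getLogger("embryocohort")

#: Base-block combinations of the six evaluated model pairs (each paired
#: without vs with the sibling-cohort block).
DEFAULT_MODEL_PAIRS: tuple[tuple[str, ...], ...] = (
    ("morphology",),
    ("kinetics",),
    ("kinetics", "morphology", "age"),
    ("dl_score",),
    ("dl_score", "morphology", "age"),
    ("dl_score", "kinetics", "morphology", "age"),
)

#: Consecutive-interval features examined in the pairwise similarity stage.
DEFAULT_SIMILARITY_FEATURES = ("t3-t2", "t4-t3", "t8-t4", "tM-t8", "tSB-tM")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model_pairs: Sequence[Sequence[str]] = DEFAULT_MODEL_PAIRS
    similarity_features: Sequence[str] = DEFAULT_SIMILARITY_FEATURES
    test_fraction: float = 0.2
    replicates: int = 0
    tuning_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    select_k: Optional[int] = 10  # applied to model pairs that include dl_score
    max_triplets: int = 1_000_000
    n_nonsibling_pairs: Optional[int] = None
    subgroup: str = "all"  # all | autologous | donor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subgroup not in ("all", "autologous", "donor"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            sim = SimulationConfig(**sim)
        pairs = d.pop("model_pairs", DEFAULT_MODEL_PAIRS)
        pairs = tuple(tuple(p) for p in pairs)
        return cls(simulation=sim, model_pairs=pairs, **d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_pairs"] = [list(p) for p in self.model_pairs]
        d["similarity_features"] = list(self.similarity_features)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def filter_subgroup(cohorts: Sequence[Cohort], subgroup: str) -> list[Cohort]:
    """Restrict to autologous or donor cycles (``all`` is a no-op)."""
    if subgroup == "all":
        return list(cohorts)
    want_donor = subgroup == "donor"
    return [c for c in cohorts if c.donor_cycle == want_donor]


def _fit_cohort_only(cohorts, grid, seed, test_fraction):
    """Single-arm model on the 16 cohort features alone (for attribution)."""
    fm = assemble(cohorts, ("cohort",))
    split = split_cohorts(cohorts, test_fraction, seed)
    mask = np.isin(np.array(fm.cycle_ids), sorted(split.train_ids))
    gs = train_classifier(fm.X[mask], fm.y[mask], grid, seed=seed)
    return gs.best_estimator_, fm


def run_all(config: RunConfig, out_dir: str) -> dict:
    """Run the full pipeline and write the report bundle under ``out_dir``.

    Artifacts: ``dataset.csv``, ``features.csv``, ``completion_log.json``,
    per-pair ROC point CSVs, and a ``summary.json`` / ``summary.md`` pair
    embedding the configuration hash and global seed.  Deterministic: two
    runs with the same config produce byte-identical JSON.
    """
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    sim_cfg = SimulationConfig(
        **{**asdict(config.simulation), "seed": stage_seed(config.seed, "simulate")}
    )
    cohorts = generate(sim_cfg)
    cohorts = filter_subgroup(cohorts, config.subgroup)
    write_dataset(cohorts, os.path.join(out_dir, "dataset.csv"))
    n_embryos = sum(c.size for c in cohorts)
    n_transferred = sum(len(c.transferred_embryos) for c in cohorts)
    logger.info(
        "simulate: %d cohorts, %d embryos, %d transferred (%s subgroup)",
        len(cohorts), n_embryos, n_transferred, config.subgroup,
    )
    report["stages"]["simulate"] = {
        "n_cohorts": len(cohorts),
        "n_embryos": n_embryos,
        "n_transferred": n_transferred,
        "n_positive_cohorts": sum(c.label == "positive" for c in cohorts),
    }

    # --- featurize ----------------------------------------------------
    log = CompletionLog()
    all_blocks = ("morphology", "kinetics", "age", "dl_score", "cohort")
    fm = assemble(cohorts, all_blocks, completion_log=log)
    fm.X.assign(label=fm.y, embryo_id=fm.embryo_ids).to_csv(
        os.path.join(out_dir, "features.csv"), index=False
    )
    with open(os.path.join(out_dir, "completion_log.json"), "w") as fh:
        json.dump(
            {"entries": log.entries, "excluded": sorted(log.excluded)},
            fh, indent=2, sort_keys=True,
        )
    logger.info(
        "featurize: %d rows, %d rule completions, %d 5-NN completions, "
        "%d embryos excluded from kinetics, dropped=%s",
        len(fm), log.n_rule, log.n_knn, len(log.excluded), fm.dropped,
    )
    report["stages"]["featurize"] = {
        "n_rows": len(fm),
        "n_columns": fm.X.shape[1],
        "n_rule_completions": log.n_rule,
        "n_knn_completions": log.n_knn,
        "n_excluded_kinetics": len(log.excluded),
        "dropped": fm.dropped,
    }

    # --- similarity ---------------------------------------------------
    sim_seed = stage_seed(config.seed, "similarity")
    similarity = {
        feat: pairwise_differences(
            cohorts, feat, n_nonsibling_pairs=config.n_nonsibling_pairs, seed=sim_seed
        ).to_dict()
        for feat in config.similarity_features
    }
    triplets = triplet_analysis(
        cohorts, max_triplets=config.max_triplets, seed=sim_seed
    )
    comparisons = {
        prop: cohort_compare(cohorts, prop).to_dict()
        for prop in (
            "cohort_size", "frac_blastulation",
            "gardner_expansion", "gardner_icm", "gardner_te",
        )
    }
    report["stages"]["similarity"] = {
        "pairwise": similarity,
        "triplets": triplets.to_dict(),
        "cohort_compare": comparisons,
    }

    # --- modeling -----------------------------------------------------
    model_seed = stage_seed(config.seed, "model")
    pair_reports = {}
    main_pair_result = None
    for pair in config.model_pairs:
        pair = tuple(pair)
        name = "+".join(pair)
        select_k = config.select_k if "dl_score" in pair else None
        model = PairedImplantationModel(
            cohorts,
            pair,
            tuning_grid=config.tuning_grid,
            test_fraction=config.test_fraction,
            select_k=select_k,
        )
        res = model.fit(seed=model_seed)
        res.roc_without.to_csv(
            os.path.join(out_dir, f"roc_{name.replace('+', '_')}_without.csv"), index=False
        )
        res.roc_with.to_csv(
            os.path.join(out_dir, f"roc_{name.replace('+', '_')}_with.csv"), index=False
        )
        entry = res.to_dict()
        if config.replicates >= 2:
            entry["replication"] = model.replicate(
                n_replicates=config.replicates, seed=model_seed
            ).to_dict()
        pair_reports[name] = entry
        logger.info(
            "model %s: AUC %.3f -> %.3f (p=%.3g)",
            name, res.auc_without, res.auc_with, res.wilcoxon_p,
        )
        if pair == ("kinetics", "morphology", "age"):
            main_pair_result = res
    report["stages"]["modeling"] = pair_reports

    # --- explain ------------------------------------------------------
    explain_seed = stage_seed(config.seed, "explain")
    cohort_model, cohort_fm = _fit_cohort_only(
        cohorts, config.tuning_grid, explain_seed, config.test_fraction
    )
    importance_cohort = shapley_importance(cohort_model, cohort_fm.X)
    explain_report = {"cohort_only": importance_cohort.to_dict()}
    if main_pair_result is None and config.model_pairs:
        main_pair_result = PairedImplantationModel(
            cohorts,
            tuple(config.model_pairs[0]),
            tuning_grid=config.tuning_grid,
            test_fraction=config.test_fraction,
        ).fit(seed=model_seed)
    if main_pair_result is not None:
        # ordinal morphology recoding for attribution of the main pair
        ordinal_model = PairedImplantationModel(
            cohorts,
            main_pair_result.base_blocks,
            tuning_grid=config.tuning_grid,
            test_fraction=config.test_fraction,
            morphology_encoding="ordinal",
        )
        ordinal_res = ordinal_model.fit(seed=model_seed)
        imp = shapley_importance(
            ordinal_res.models["with"], ordinal_res.feature_matrices["with"].X
        )
        explain_report["main_pair_with_cohort"] = imp.to_dict()
    report["stages"]["explain"] = explain_report

    # --- rescue -------------------------------------------------------
    if main_pair_result is not None:
        rescued = identify_rescued(main_pair_result)
        rescue_report = rescued.to_dict()
        rescue_report["comparisons"] = {}
        for direction in ("positive_rescued", "negative_rescued"):
            for feat in ("frac_blastulation", "cohort_size"):
                cmp_ = rescue_feature_comparison(rescued, cohorts, feat, direction)
                rescue_report["comparisons"][f"{direction}:{feat}"] = cmp_.to_dict()
        report["stages"]["rescue"] = rescue_report
        logger.info(
            "rescue: %d positive-rescued, %d negative-rescued of %d test embryos",
            rescued.n_positive_rescued, rescued.n_negative_rescued, len(rescued.scores),
        )

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown(report, os.path.join(out_dir, "summary.md"))
    return report


def _write_markdown(report: dict, path: str) -> None:
    lines = [
        "# Sibling-cohort implantation analysis report",
        "",
        f"- package version: {report['package_version']}",
        f"- config hash: `{report['config_hash']}`",
        f"- global seed: {report['seed']}",
        "",
    ]
    sim = report["stages"]["simulate"]
    lines += [
        "## Dataset",
        "",
        f"{sim['n_cohorts']} cohorts / {sim['n_embryos']} embryos; "
        f"{sim['n_transferred']} transferred; "
        f"{sim['n_positive_cohorts']} positive cohorts.",
        "",
    ]
    lines += ["## Sibling similarity", ""]
    for feat, rep in report["stages"]["similarity"]["pairwise"].items():
        lines.append(
            f"- |Δ {feat}|: siblings {rep['sibling_mean']:.1f} "
            f"({rep['sibling_sd']:.1f}) vs non-siblings {rep['nonsibling_mean']:.1f} "
            f"({rep['nonsibling_sd']:.1f}) min, p={rep['p_value']:.2g}"
        )
    tri = report["stages"]["similarity"]["triplets"]
    if tri["n_triplets"]:
        lines.append(
            f"- Gardner-matched triplets (n={tri['n_triplets']}): sibling distance "
            f"{tri['sibling_mean']:.3f} vs non-sibling {tri['nonsibling_mean']:.3f}, "
            f"p={tri['p_value']:.2g}"
        )
    lines += ["", "## Model pairs (AUC without -> with cohort features)", ""]
    for name, rep in report["stages"]["modeling"].items():
        lines.append(
            f"- {name}: {rep['auc_without']:.3f} -> {rep['auc_with']:.3f} "
            f"(Δ={rep['delta_auc']:+.3f}, p={rep['wilcoxon_p']:.2g})"
        )
    if "rescue" in report["stages"]:
        r = report["stages"]["rescue"]
        lines += [
            "",
            "## Rescued embryos",
            "",
            f"{r['n_positive_rescued']} positive and {r['n_negative_rescued']} negative "
            f"test embryos were corrected by the cohort features.",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
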