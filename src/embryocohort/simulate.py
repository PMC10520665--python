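"""Seeded generator of synthetic IVF-cycle datasets.

The generator emulates the statistical structure that the downstream
analyses assume, without modelling embryology mechanistically:

* a latent cohort quality ``q_c`` shared by all siblings of a cycle, and a
  per-embryo quality ``e_i = rho * q_c + sqrt(1 - rho^2) * eps_i`` so that
  ``rho`` controls how much sibling embryos resemble each other;
* morphokinetic event times built from a stage mean, a cohort-level random
  effect (siblings drift together), embryo-level noise, and a quality
  coupling (better embryos develop faster), sorted within each embryo to
  keep the developmental order t2 < t3 < t4 < t8 < tM < tSB;
* blastulation, Gardner grades, transfer selection (best Gardner first) and
  implantation all driven by the same latent quality, with an independent
  uterine noise term so that some good embryos fail to implant (the label
  ambiguity of negative outcomes);
* missing-completely-at-random deletion of event annotations at
  configurable per-event rates.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .data_model import (
    CORE_EVENTS,
    Cohort,
    EmbryoRecord,
    GardnerScore,
    ICM_TE_CATEGORIES,
)

__all__ = ["SimulationConfig", "generate", "apply_missingness"]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


#: Stage means in minutes from fertilization (t2 ~ 27 h ... tSB ~ 104 h),
#: consistent with published consensus timings for human preimplantation
#: development under time-lapse culture.
DEFAULT_EVENT_MEANS = {
    "t2": 1620.0,
    "t3": 2190.0,
    "t4": 2280.0,
    "t8": 3360.0,
    "tM": 5160.0,
    "tSB": 6240.0,
}

#: Cohort-level random-effect SDs (minutes); they grow with developmental
#: stage so the sibling-vs-non-sibling gap widens at later events.
DEFAULT_COHORT_EFFECT_SD = {
    "t2": 30.0,
    "t3": 35.0,
    "t4": 40.0,
    "t8": 60.0,
    "tM": 80.0,
    "tSB": 90.0,
}

#: Embryo-level noise SDs (minutes).
DEFAULT_EMBRYO_NOISE_SD = {
    "t2": 60.0,
    "t3": 80.0,
    "t4": 90.0,
    "t8": 150.0,
    "tM": 170.0,
    "tSB": 140.0,
}

#: Minutes of developmental acceleration per unit of embryo quality.
DEFAULT_QUALITY_TIME_SLOPE = {
    "t2": 20.0,
    "t3": 25.0,
    "t4": 30.0,
    "t8": 45.0,
    "tM": 60.0,
    "tSB": 70.0,
}

#: MCAR annotation-deletion rates: 5-10% for cleavage events, 20% for the
#: late events, higher for the auxiliary annotations tPNf and t7.
DEFAULT_MISSINGNESS = {
    "t2": 0.05,
    "t3": 0.05,
    "t4": 0.07,
    "t8": 0.10,
    "tM": 0.20,
    "tSB": 0.20,
    "tPNf": 0.30,
    "t7": 0.30,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    ``within_cohort_corr`` (rho) is the loading of the shared cohort latent
    on embryo quality; rho = 0 makes siblings statistically exchangeable
    with non-siblings.  Intercepts are set so the simulated marginals match
    clinically reported rates: sibling blastulation fraction around 0.45 and
    a positive:negative cohort ratio near 58:42.
    """

    n_cohorts: int = 300
    cohort_size_mean: float = 10.0
    cohort_size_quality_slope: float = 1.0
    cohort_quality_sd: float = 1.0
    within_cohort_corr: float = 0.7
    event_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MEANS))
    cohort_effect_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_EFFECT_SD)
    )
    embryo_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMBRYO_NOISE_SD)
    )
    quality_time_slope: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_TIME_SLOPE)
    )
    blastulation_logit_slope: float = 1.2
    blastulation_intercept: float = 0.1
    implantation_logit_slope: float = 0.8
    implantation_intercept: float = -0.4
    cohort_blastulation_logit_slope: float = 2.0
    age_logit_slope: float = -0.05
    uterine_noise_sd: float = 1.0
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    gardner_missing_rate: float = 0.07
    double_transfer_prob: float = 0.15
    donor_fraction: float = 0.37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts <= 0:
            raise ValueError("n_cohorts must be positive")
        if not 0.0 <= self.within_cohort_corr <= 1.0:
            raise ValueError("within_cohort_corr must be in [0, 1]")
        for name, d in (
            ("cohort_effect_sd", self.cohort_effect_sd),
            ("embryo_noise_sd", self.embryo_noise_sd),
        ):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} entries must be >= 0")
        if self.cohort_quality_sd < 0 or self.uterine_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for ev, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {ev} must be in [0, 1]")
        means = [self.event_means[e] for e in CORE_EVENTS]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("event_means must be strictly increasing in developmental order")
        if not 0.0 <= self.double_transfer_prob <= 1.0:
            raise ValueError("double_transfer_prob must be in [0, 1]")
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ValueError("donor_fraction must be in [0, 1]")


def _draw_gardner(e_i: float, rng: np.random.Generator) -> GardnerScore:
    """Ordinal-threshold a noisy copy of embryo quality into the three parts.

    Blastulating embryos get expansion grades 2-6; hatched (6) is rare.
    """
    x = e_i + rng.normal(0.0, 0.7)
    if x < -0.8:
        expansion = 2
    elif x < 0.2:
        expansion = 3
    elif x < 1.5:
        expansion = 4
    elif x < 2.8:
        expansion = 5
    else:
        expansion = 6

    def _letter(v: float) -> str:
        if v > 1.0:
            return "A"
        if v > 0.0:
            return "B"
        if v > -1.2:
            return "C"
        return "D"

    icm = _letter(e_i + rng.normal(0.0, 0.8))
    te = _letter(e_i + rng.normal(0.0, 0.8))
    return GardnerScore(expansion, icm, te)


def generate(config: SimulationConfig) -> list[Cohort]:
    """Generate a seeded synthetic dataset of validated cohorts."""
    rng = np.random.default_rng(config.seed)
    rho = config.within_cohort_corr
    cohorts: list[Cohort] = []

    for c_idx in range(config.n_cohorts):
        cycle_id = f"C{c_idx:05d}"
        q_c = rng.normal(0.0, config.cohort_quality_sd)
        size = max(2, int(rng.poisson(
            max(0.5, config.cohort_size_mean + config.cohort_size_quality_slope * q_c)
        )))
        donor = bool(rng.random() < config.donor_fraction)
        age_mean = 27.0 if donor else 36.0
        age = float(np.clip(rng.normal(age_mean, 4.0), 18.0, 51.0).round(1))

        e = rho * q_c + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(0.0, 1.0, size)
        u_c = {ev: rng.normal(0.0, config.cohort_effect_sd[ev]) for ev in CORE_EVENTS}

        # raw event times; within-embryo sort enforces developmental order
        times = np.empty((size, len(CORE_EVENTS)))
        for k, ev in enumerate(CORE_EVENTS):
            times[:, k] = (
                config.event_means[ev]
                + u_c[ev]
                - config.quality_time_slope[ev] * e
                + rng.normal(0.0, config.embryo_noise_sd[ev], size)
            )
        times.sort(axis=1)
        times = np.maximum(times, 1.0)

        blast_p = np.array(
            [_sigmoid(config.blastulation_logit_slope * ei + config.blastulation_intercept)
             for ei in e]
        )
        blastulated = rng.random(size) < blast_p

        gardner: list[Optional[GardnerScore]] = [
            _draw_gardner(e[i], rng) if blastulated[i] else None for i in range(size)
        ]

        # transfer selection: best Gardner-ranked blastocyst(s); if the cycle
        # produced none, the top-quality embryo is cultured on and transferred
        if not blastulated.any():
            i_best = int(np.argmax(e))
            blastulated[i_best] = True
            gardner[i_best] = _draw_gardner(e[i_best], rng)
        candidates = [i for i in range(size) if blastulated[i]]
        tie = rng.random(size)
        candidates.sort(key=lambda i: (gardner[i].quality_rank, tie[i]), reverse=True)
        n_transfer = 2 if (len(candidates) >= 2 and rng.random() < config.double_transfer_prob) else 1
        transferred_idx = set(candidates[:n_transfer])

        sib_mask = np.array([i not in transferred_idx for i in range(size)])
        frac_blast_sib = (
            float(blastulated[sib_mask].mean()) if sib_mask.any() else 0.0
        )

        eta_c = rng.normal(0.0, config.uterine_noise_sd)
        logits = [
            config.implantation_logit_slope * e[i]
            + config.cohort_blastulation_logit_slope * (frac_blast_sib - 0.45)
            + config.age_logit_slope * (age - 35.0)
            + config.implantation_intercept
            + eta_c
            for i in sorted(transferred_idx)
        ]
        # a double transfer gets one shared outcome (discordant pairs are
        # excluded from the study population by design)
        outcome = bool(rng.random() < _sigmoid(float(np.mean(logits))))

        embryos: list[EmbryoRecord] = []
        for i in range(size):
            morphokinetics = {"t0": 0.0}
            for k, ev in enumerate(CORE_EVENTS):
                if ev == "tSB" and not blastulated[i]:
                    continue  # blastulation never started: no tSB exists
                morphokinetics[ev] = float(round(times[i, k], 1))
            if "t2" in morphokinetics:
                tpnf = morphokinetics["t2"] - (120.0 + rng.normal(0.0, 20.0))
                morphokinetics["tPNf"] = float(round(max(tpnf, 1.0), 1))
            if "t8" in morphokinetics:
                t7 = morphokinetics["t8"] - (180.0 + rng.normal(0.0, 20.0))
                morphokinetics["t7"] = float(round(max(t7, 1.0), 1))
            g = gardner[i]
            if g is not None and rng.random() < config.gardner_missing_rate:
                g = None  # annotation lost, independent of quality
            embryos.append(
                EmbryoRecord(
                    embryo_id=f"{cycle_id}-E{i:02d}",
                    cycle_id=cycle_id,
                    transferred=i in transferred_idx,
                    implanted=outcome if i in transferred_idx else None,
                    morphokinetics=morphokinetics,
                    gardner=g,
                    oocyte_age=age,
                    dl_confidence=float(_sigmoid(e[i] + rng.normal(0.0, 0.5))),
                    donor_cycle=donor,
                )
            )
        cohorts.append(Cohort(cycle_id, embryos))

    return apply_missingness(cohorts, config.missingness_rates, seed=int(rng.integers(2**31)))


def apply_missingness(
    cohorts: Iterable[Cohort],
    rates: Mapping[str, float],
    seed: int,
) -> list[Cohort]:
    """Delete observed event annotations independently at per-event rates.

    Missingness is completely at random (MCAR).  The input is not modified;
    a deep copy is returned.
    """
    for ev, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate for {ev} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    out = []
    for cohort in cohorts:
        c = cohort.copy()
        for e in c.embryos:
            for ev, r in rates.items():
                if ev in e.morphokinetics and rng.random() < r:
                    del e.morphokinetics[ev]
        out.append(c)
    return out
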