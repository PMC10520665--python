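import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryocohort.data_model import GardnerScore
from embryocohort.features import KINETIC_FEATURE_NAMES, encode_kinetics
from embryocohort.similarity import (
    INTERVAL_FEATURES,
    cohort_compare,
    fit_normalizer,
    pairwise_differences,
    profile_distance,
    triplet_analysis,
)
from conftest import FULL_TIMES, make_cohort


def exact_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (small samples)."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    observed = u_stat(x, y)
    mu = len(x) * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(xs, ys) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestPairwiseDifferences:
    def test_planted_extreme(self):
        c1 = make_cohort("C1", [
            {"transferred": True, "implanted": True,
             "morphokinetics": {"t2": 1000.0, "t3": 1600.0}},
            {"morphokinetics": {"t2": 1100.0, "t3": 1700.0}},
        ])
        c2 = make_cohort("C2", [
            {"transferred": True, "implanted": False,
             "morphokinetics": {"t2": 1000.0, "t3": 2200.0}},
            {"morphokinetics": {"t2": 1100.0, "t3": 2300.0}},
        ])
        rep = pairwise_differences([c1, c2], "t3-t2", seed=0)
        assert rep.sibling_values.max() == 0.0
        assert rep.nonsibling_values.min() > 0.0
        assert rep.sibling_mean < rep.nonsibling_mean

    def test_single_cohort_is_error(self):
        c1 = make_cohort("C1", [
            {"transferred": True, "implanted": True, "morphokinetics": FULL_TIMES},
            {"morphokinetics": FULL_TIMES},
        ])
        with pytest.raises(ValueError):
            pairwise_differences([c1], "t3-t2")

    def test_siblings_closer_on_synthetic_data(self, medium_cohorts):
        """Planted within-cohort correlation: sibling interval differences are
        smaller than non-sibling ones with a decisive rank test."""
        rep = pairwise_differences(medium_cohorts, "t3-t2", seed=1)
        assert rep.sibling_mean < rep.nonsibling_mean
        assert rep.p_value < 0.01

    def test_seeded_nonsibling_sample_reproducible(self, small_cohorts):
        a = pairwise_differences(small_cohorts, "tSB-tM", seed=9)
        b = pairwise_differences(small_cohorts, "tSB-tM", seed=9)
        assert np.array_equal(a.nonsibling_values, b.nonsibling_values)

    def test_rank_test_matches_exact_enumeration(self):
        """The Mann-Whitney p agrees with full permutation enumeration on a
        fixed small sample."""
        x = [1.2, 3.4, 2.2, 5.0, 0.7]
        y = [4.1, 6.3, 5.5, 7.2, 3.9]
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-9)


class TestProfileDistance:
    def _vectors(self):
        rng = np.random.default_rng(3)
        rows = [
            pd.Series(rng.uniform(0, 100, len(KINETIC_FEATURE_NAMES)),
                      index=KINETIC_FEATURE_NAMES)
            for _ in range(6)
        ]
        return rows, fit_normalizer(pd.DataFrame(rows))

    def test_identity(self):
        rows, norm = self._vectors()
        assert profile_distance(rows[0], rows[0], norm) == 0.0

    def test_extreme_corners_sqrt_d(self):
        rows, norm = self._vectors()
        a = pd.Series(norm["min"])
        b = pd.Series(norm["max"])
        d = len(norm)
        assert profile_distance(a, b, norm) == pytest.approx(np.sqrt(d))

    def test_hand_computed_oracle(self):
        names = ["f1", "f2", "f3"]
        norm = pd.DataFrame({"min": [0.0, 0.0, 0.0], "max": [10.0, 5.0, 2.0]},
                            index=names)
        a = pd.Series({"f1": 5.0, "f2": 0.0, "f3": 2.0})
        b = pd.Series({"f1": 10.0, "f2": 5.0, "f3": 1.0})
        expected = np.sqrt(0.5**2 + 1.0**2 + 0.5**2)
        assert profile_distance(a, b, norm) == pytest.approx(expected)

    def test_metric_properties_on_random_triples(self):
        rows, norm = self._vectors()
        for a, b, c in itertools.combinations(rows, 3):
            dab = profile_distance(a, b, norm)
            dba = profile_distance(b, a, norm)
            assert dab == pytest.approx(dba)
            assert dab >= 0
            assert dab <= profile_distance(a, c, norm) + profile_distance(c, b, norm) + 1e-12

    def test_zero_range_feature_contributes_zero(self):
        names = ["f1", "f2"]
        norm = pd.DataFrame({"min": [0.0, 3.0], "max": [10.0, 3.0]}, index=names)
        a = pd.Series({"f1": 0.0, "f2": 3.0})
        b = pd.Series({"f1": 10.0, "f2": 3.0})
        with pytest.warns(UserWarning, match="zero-range"):
            assert profile_distance(a, b, norm) == pytest.approx(1.0)


def triplet_oracle(cohorts):
    """Brute-force enumeration of Gardner-matched ordered triplets."""
    embryos = []
    for ci, c in enumerate(cohorts):
        for e in c.embryos:
            if e.gardner is not None and all(
                ev in e.morphokinetics for ev in ("t2", "t3", "t4", "t8", "tM", "tSB")
            ):
                embryos.append((ci, e.gardner.as_tuple(), e.embryo_id))
    out = set()
    for (c1, g1, i1), (c2, g2, i2), (c3, g3, i3) in itertools.permutations(embryos, 3):
        if c1 == c2 and c3 != c1 and g1 == g2 == g3:
            out.add((i1, i2, i3))
    return out


class TestTripletAnalysis:
    def _toy(self):
        g = GardnerScore(4, "A", "B")
        mk = lambda shift: {k: v + shift for k, v in FULL_TIMES.items()}
        c1 = make_cohort("C1", [
            {"transferred": True, "implanted": True, "gardner": g, "morphokinetics": mk(0)},
            {"gardner": g, "morphokinetics": mk(30)},
            {"gardner": GardnerScore(3, "B", "B"), "morphokinetics": mk(60)},
        ])
        c2 = make_cohort("C2", [
            {"transferred": True, "implanted": False, "gardner": g, "morphokinetics": mk(500)},
            {"gardner": g, "morphokinetics": mk(550)},
        ])
        return [c1, c2]

    def test_count_matches_bruteforce_enumeration(self):
        cohorts = self._toy()
        rep = triplet_analysis(cohorts, seed=0)
        assert rep.n_triplets == len(triplet_oracle(cohorts))

    def test_distinct_gardner_scores_yield_zero_triplets(self):
        cohorts = self._toy()
        # make every Gardner score unique
        grades = itertools.product(range(2, 7), "ABCD")
        for c in cohorts:
            for e in c.embryos:
                g, icm = next(grades)
                e.gardner = GardnerScore(g, icm, "A")
        rep = triplet_analysis(cohorts, seed=0)
        assert rep.n_triplets == 0
        assert rep.p_value is None

    def test_subsampling_caps_count(self):
        cohorts = self._toy()
        full = triplet_analysis(cohorts, seed=0)
        capped = triplet_analysis(cohorts, max_triplets=3, seed=0)
        assert full.n_triplets > 3
        assert capped.n_triplets == 3

    def test_siblings_closer_at_matched_gardner(self, medium_cohorts):
        rep = triplet_analysis(medium_cohorts, seed=2)
        assert rep.n_triplets > 100
        assert float(np.mean(rep.sibling_distances)) < float(np.mean(rep.nonsibling_distances))


class TestCohortCompare:
    def test_two_cohort_arithmetic(self):
        big = make_cohort("P", [{"transferred": True, "implanted": True}] + [{}] * 11)
        small = make_cohort("N", [{"transferred": True, "implanted": False}] + [{}] * 7)
        rep = cohort_compare([big, small], "cohort_size")
        assert float(np.mean(rep.positive_values)) == 12.0
        assert float(np.mean(rep.negative_values)) == 8.0

    def test_positive_cohorts_blastulate_more(self, medium_cohorts):
        rep = cohort_compare(medium_cohorts, "frac_blastulation")
        assert float(np.mean(rep.positive_values)) > float(np.mean(rep.negative_values))
        assert rep.p_value < 0.01

    def test_gardner_part_reports_category_fractions(self, medium_cohorts):
        rep = cohort_compare(medium_cohorts, "gardner_icm")
        assert rep.category_fractions is not None
        assert set(rep.category_fractions.columns) == {"positive", "negative"}
        assert (rep.category_fractions.sum() <= 1.0 + 1e-9).all()

    def test_single_label_dataset_rejected(self):
        c = make_cohort("C1", [{"transferred": True, "implanted": True}, {}])
        with pytest.raises(ValueError):
            cohort_compare([c], "cohort_size")

    def test_shuffled_labels_null_p_not_extreme(self, medium_cohorts):
        """After cohort-level label shuffling the comparison p-values are not
        systematically tiny."""
        rng = np.random.default_rng(0)
        shuffled = [c.copy() for c in medium_cohorts]
        outcomes = [c.label == "positive" for c in shuffled]
        rng.shuffle(outcomes)
        for c, o in zip(shuffled, outcomes):
            for e in c.transferred_embryos:
                e.implanted = o
        ps = [cohort_compare(shuffled, "frac_blastulation").p_value]
        assert min(ps) > 1e-4
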