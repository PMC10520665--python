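import numpy as np
import pandas as pd
import pytest

from embryocohort.data_model import CORE_EVENTS, GardnerScore, cohorts_to_dataframe
from embryocohort.features import (
    COHORT_FEATURE_NAMES,
    KINETIC_FEATURE_NAMES,
    MORPHO_FEATURE_NAMES,
    assemble,
    complete_annotations,
    encode_cohort,
    encode_kinetics,
    encode_morphology,
    encode_morphology_ordinal,
)
from embryocohort.simulate import SimulationConfig, apply_missingness, generate
from conftest import FULL_TIMES, make_cohort, make_embryo


def knn_completion_oracle(embryos_mk):
    """Independent brute-force re-derivation of the two completion stages.

    ``embryos_mk``: list of event->minutes dicts.  Returns the completed
    dicts (rule offsets from observed sources, then 5-NN means over the
    min-max-normalised shared events of fully annotated embryos).
    """
    rules = [("t2", "tPNf", 120.0), ("t4", "t3", 60.0), ("t3", "t4", -60.0),
             ("t8", "t7", 180.0), ("tM", "tSB", -360.0)]
    completed = []
    for mk in embryos_mk:
        mk = dict(mk)
        for target, source, offset in rules:
            if target not in mk and source in embryos_mk[len(completed)]:
                mk[target] = embryos_mk[len(completed)][source] + offset
        completed.append(mk)

    lo, hi = {}, {}
    for mk in completed:
        for ev in CORE_EVENTS:
            if ev in mk:
                lo[ev] = min(lo.get(ev, np.inf), mk[ev])
                hi[ev] = max(hi.get(ev, -np.inf), mk[ev])

    def norm(ev, v):
        span = hi[ev] - lo[ev]
        return (v - lo[ev]) / span if span > 0 else 0.0

    full = [i for i, mk in enumerate(completed)
            if all(ev in mk for ev in CORE_EVENTS)]
    out = [dict(mk) for mk in completed]
    for i, mk in enumerate(completed):
        missing = [ev for ev in CORE_EVENTS if ev not in mk]
        if len(missing) != 1:
            continue
        target = missing[0]
        dists = []
        for j in full:
            if j == i:
                continue
            shared = [ev for ev in CORE_EVENTS if ev in mk]
            d = np.sqrt(sum((norm(ev, mk[ev]) - norm(ev, completed[j][ev])) ** 2
                            for ev in shared))
            dists.append((d, j))
        dists.sort(key=lambda t: t[0])
        nn = [j for _, j in dists[:5]]
        out[i][target] = float(np.mean([completed[j][target] for j in nn]))
    return out


class TestCompletionRules:
    def test_t2_from_pronuclei_fade(self):
        c = make_cohort("C1", [
            {"transferred": True, "implanted": True,
             "morphokinetics": {"tPNf": 1500.0, "t3": 2160.0}},
        ])
        done, log = complete_annotations([c])
        assert done[0].embryos[0].morphokinetics["t2"] == pytest.approx(1620.0)
        assert any(e["event"] == "t2" and e["method"].startswith("rule")
                   for e in log.entries)

    @pytest.mark.parametrize("present, target, expected", [
        ({"t3": 2160.0}, "t4", 2220.0),
        ({"t4": 2220.0}, "t3", 2160.0),
        ({"t7": 3120.0}, "t8", 3300.0),
        ({"tSB": 6600.0}, "tM", 6240.0),
    ])
    def test_offset_rules_exact(self, present, target, expected):
        c = make_cohort("C1", [
            {"transferred": True, "implanted": True, "morphokinetics": present},
        ])
        done, _ = complete_annotations([c])
        assert done[0].embryos[0].morphokinetics[target] == pytest.approx(expected, abs=0)

    def test_circular_pair_defers_when_both_missing(self):
        mk = {k: v for k, v in FULL_TIMES.items() if k not in ("t3", "t4")}
        mk["tPNf"] = 1440.0
        c = make_cohort("C1", [
            {"transferred": True, "implanted": True, "morphokinetics": mk},
        ])
        done, log = complete_annotations([c])
        e = done[0].embryos[0]
        assert "t3" not in e.morphokinetics and "t4" not in e.morphokinetics
        assert e.embryo_id in log.excluded

    def test_input_untouched_and_idempotent(self, small_cohorts):
        before = cohorts_to_dataframe(small_cohorts)
        once, log1 = complete_annotations(small_cohorts)
        assert cohorts_to_dataframe(small_cohorts).equals(before)
        twice, log2 = complete_annotations(once)
        assert cohorts_to_dataframe(twice).equals(cohorts_to_dataframe(once))
        assert not log2.entries

    def test_knn_hand_example(self):
        """One embryo missing tSB among neighbours with known tSB values
        gets their mean; neighbour set verified by construction."""
        specs = []
        # 7 fully annotated embryos whose t2..tM are close to the query's
        for i, tsb in enumerate([7000.0, 7100.0, 7200.0, 7300.0, 7400.0]):
            mk = dict(FULL_TIMES, tSB=tsb)
            mk = {k: v + i for k, v in mk.items() if k != "tSB"} | {"tSB": tsb}
            specs.append({"morphokinetics": mk})
        # two remote embryos that must not be neighbours
        far = {k: v + 3000.0 for k, v in FULL_TIMES.items()}
        specs.append({"morphokinetics": far})
        specs.append({"morphokinetics": dict(far, tSB=20000.0)})
        query = {k: v for k, v in FULL_TIMES.items() if k != "tSB"}
        specs.append({"transferred": True, "implanted": True, "morphokinetics": query})
        c = make_cohort("C1", specs)
        done, log = complete_annotations([c])
        imputed = done[0].embryos[-1].morphokinetics["tSB"]
        assert imputed == pytest.approx(7200.0)

    def test_knn_matches_bruteforce_oracle(self):
        """5-NN completion equals an independent all-pairs oracle on ~200
        embryos with realistic missingness."""
        cohorts = generate(SimulationConfig(n_cohorts=20, seed=21))
        done, _ = complete_annotations(cohorts)
        flat = [e for c in cohorts for e in c.embryos]
        oracle = knn_completion_oracle([e.morphokinetics for e in flat])
        done_flat = [e for c in done for e in c.embryos]
        assert len(flat) >= 150
        for e, mk_oracle in zip(done_flat, oracle):
            for ev in CORE_EVENTS:
                if ev in mk_oracle:
                    assert e.morphokinetics[ev] == pytest.approx(mk_oracle[ev], abs=1e-9)

    def test_too_few_complete_embryos_is_hard_error(self):
        specs = [{"morphokinetics": {k: v for k, v in FULL_TIMES.items() if k != "tSB"}}
                 for _ in range(4)]
        specs.append({"transferred": True, "implanted": True,
                      "morphokinetics": dict(FULL_TIMES)})
        c = make_cohort("C1", specs)
        with pytest.raises(ValueError, match="5-NN"):
            complete_annotations([c])


class TestEncoders:
    def test_morphology_one_hot(self):
        v = encode_morphology(GardnerScore(4, "A", "B"))
        assert list(v.index) == MORPHO_FEATURE_NAMES
        assert v.sum() == 3
        assert v["exp_4"] == v["icm_A"] == v["te_B"] == 1.0

    def test_morphology_blocks_each_sum_to_one(self):
        v = encode_morphology(GardnerScore(2, "C", "D"))
        assert v[[f"exp_{g}" for g in range(1, 7)]].sum() == 1
        assert v[[f"icm_{c}" for c in "ABCD"]].sum() == 1
        assert v[[f"te_{c}" for c in "ABCD"]].sum() == 1

    def test_morphology_injective(self):
        scores = [GardnerScore(e, i, t) for e in (2, 5) for i in "AC" for t in "BD"]
        vectors = {tuple(encode_morphology(s)) for s in scores}
        assert len(vectors) == len(scores)

    def test_morphology_ordinal_recoding(self):
        v = encode_morphology_ordinal(GardnerScore(5, "A", "D"))
        assert list(v) == [5.0, 4.0, 1.0]

    def test_kinetics_arithmetic(self):
        e = make_embryo("e1", morphokinetics=FULL_TIMES)
        v = encode_kinetics(e)
        assert list(v.index) == KINETIC_FEATURE_NAMES
        assert list(v[:5]) == [600.0, 60.0, 1080.0, 2100.0, 1200.0]
        assert list(v[5:]) == [1560.0, 2160.0, 2220.0, 3300.0, 5400.0, 6600.0]

    def test_kinetics_translation_leaves_intervals(self):
        e1 = make_embryo("e1", morphokinetics=FULL_TIMES)
        e2 = make_embryo("e2", morphokinetics={k: v + 100 for k, v in FULL_TIMES.items()})
        v1, v2 = encode_kinetics(e1), encode_kinetics(e2)
        assert list(v1[:5]) == list(v2[:5])
        assert all(v2[5:] - v1[5:] == 100.0)

    def test_kinetics_requires_all_events(self):
        e = make_embryo("e1", morphokinetics={"t2": 1560.0})
        with pytest.raises(ValueError, match="missing"):
            encode_kinetics(e)

    def test_cohort_counting(self):
        c = make_cohort("C1", [
            {"transferred": True, "implanted": True, "gardner": GardnerScore(4, "A", "A")},
            {"gardner": GardnerScore(3, "B", "B")},
            {"gardner": GardnerScore(5, "A", "C"), "morphokinetics": {"tSB": 6600.0}},
            {"gardner": None},
        ])
        v = encode_cohort(c, c.embryos[0].embryo_id)
        assert list(v.index) == COHORT_FEATURE_NAMES
        assert v["cohort_size"] == 4.0
        assert v["frac_hatched"] == pytest.approx(1 / 3)
        assert v["frac_blastulation"] == pytest.approx(2 / 3)
        assert v["frac_exp_BC"] == pytest.approx(1 / 3)
        assert v["frac_icm_A"] == pytest.approx(1 / 3)
        # gardner blocks sum to <= 1: the unscored sibling leaves mass out
        assert v[[f"frac_icm_{c_}" for c_ in "ABCD"]].sum() == pytest.approx(2 / 3)

    def test_cohort_invariant_to_sibling_order(self):
        specs = [
            {"transferred": True, "implanted": False, "gardner": GardnerScore(4, "B", "B")},
            {"gardner": GardnerScore(3, "A", "C")},
            {"gardner": GardnerScore(5, "B", "A"), "morphokinetics": {"tSB": 6000.0}},
        ]
        c1 = make_cohort("C1", specs)
        c2 = make_cohort("C1", [specs[0], specs[2], specs[1]])
        tid = c1.embryos[0].embryo_id
        assert encode_cohort(c1, tid).equals(
            encode_cohort(c2, c2.embryos[0].embryo_id)
        )

    def test_double_transfer_gets_distinct_sibling_sets(self):
        c = make_cohort("C1", [
            {"transferred": True, "implanted": True, "gardner": GardnerScore(5, "A", "A"),
             "morphokinetics": {"tSB": 6000.0}},
            {"transferred": True, "implanted": True, "gardner": GardnerScore(3, "C", "C")},
            {"gardner": GardnerScore(4, "B", "B"), "morphokinetics": {"tSB": 6300.0}},
        ])
        va = encode_cohort(c, c.embryos[0].embryo_id)
        vb = encode_cohort(c, c.embryos[1].embryo_id)
        assert va["cohort_size"] == vb["cohort_size"] == 3.0
        assert not va.equals(vb)  # each sees the other transferred embryo as sibling

    def test_singleton_cohort_warns_and_zeroes(self):
        c = make_cohort("C1", [{"transferred": True, "implanted": True}])
        with pytest.warns(UserWarning, match="singleton"):
            v = encode_cohort(c, c.embryos[0].embryo_id)
        assert v["frac_blastulation"] == 0.0


class TestAssemble:
    @pytest.mark.parametrize("blocks, n_cols", [
        (("morphology",), 14),
        (("kinetics",), 11),
        (("morphology", "kinetics", "age", "cohort"), 42),
        (("morphology", "kinetics", "age", "dl_score", "cohort"), 43),
    ])
    def test_block_dimensions(self, small_cohorts, blocks, n_cols):
        fm = assemble(small_cohorts, blocks)
        assert fm.X.shape[1] == n_cols

    def test_rows_are_transferred_embryos_only(self, small_cohorts):
        fm = assemble(small_cohorts, ("age",))
        transferred = {e.embryo_id for c in small_cohorts for e in c.transferred_embryos}
        assert set(fm.embryo_ids) <= transferred
        assert len(fm) == len(transferred)  # age is never missing

    def test_missing_gardner_rows_dropped_and_counted(self, small_cohorts):
        fm = assemble(small_cohorts, ("morphology",))
        n_missing = sum(
            1 for c in small_cohorts for e in c.transferred_embryos if e.gardner is None
        )
        if n_missing:
            assert fm.dropped["missing_gardner"] == n_missing

    def test_empty_blocks_rejected(self, small_cohorts):
        with pytest.raises(ValueError):
            assemble(small_cohorts, ())
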