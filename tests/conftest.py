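import pytest

from embryocohort.data_model import Cohort, EmbryoRecord, GardnerScore
from embryocohort.simulate import SimulationConfig, generate


def make_embryo(
    embryo_id,
    cycle_id="C1",
    transferred=False,
    implanted=None,
    morphokinetics=None,
    gardner=None,
    oocyte_age=35.0,
    dl_confidence=None,
    donor_cycle=False,
):
    return EmbryoRecord(
        embryo_id=embryo_id,
        cycle_id=cycle_id,
        transferred=transferred,
        implanted=implanted,
        morphokinetics=dict(morphokinetics or {}),
        gardner=gardner,
        oocyte_age=oocyte_age,
        dl_confidence=dl_confidence,
        donor_cycle=donor_cycle,
    )


def make_cohort(cycle_id, specs):
    """specs: list of dicts passed to make_embryo (cycle_id filled in)."""
    embryos = [
        make_embryo(cycle_id=cycle_id, **{"embryo_id": f"{cycle_id}-E{i}", **s})
        for i, s in enumerate(specs)
    ]
    return Cohort(cycle_id, embryos)


FULL_TIMES = {"t2": 1560.0, "t3": 2160.0, "t4": 2220.0, "t8": 3300.0, "tM": 5400.0, "tSB": 6600.0}


@pytest.fixture(scope="session")
def small_cohorts():
    """60 synthetic cohorts under generator defaults."""
    return generate(SimulationConfig(n_cohorts=60, seed=11))


@pytest.fixture(scope="session")
def medium_cohorts():
    """300 synthetic cohorts under generator defaults (the analysis scale)."""
    return generate(SimulationConfig(n_cohorts=300, seed=0))
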