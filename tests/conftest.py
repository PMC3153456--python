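import pytest

from dsbrepair import (CellTypeCoefficients, DoseProfile, RunSpec,
                       default_parameters, run)
from dsbrepair.damage_generation import MEAN_FIELD


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def cell():
    return CellTypeCoefficients()


@pytest.fixture(scope="session")
def run_8gy_meanfield():
    """One full mean-field reference run at constant 8 Gy (shared, read-only)."""
    spec = RunSpec(profile=DoseProfile.constant(8.0, 2500),
                   params=default_parameters(), mode=MEAN_FIELD)
    return run(spec)


@pytest.fixture(scope="session")
def run_8gy_stochastic():
    """One full stochastic reference run at constant 8 Gy (shared, read-only)."""
    spec = RunSpec(profile=DoseProfile.constant(8.0, 2500),
                   params=default_parameters(), seed=20260919)
    return run(spec)


def ledger_errors(result):
    """Max absolute DSB-pairing and RP conservation errors over all states."""
    s0 = result.states[0]
    dsb_err = max(abs(s0.dsb + st.cum_dsb_generated + st.cum_dissynthesized
                      - (st.dsb + st.cum_synthesized)) for st in result.states)
    rp_err = max(abs(s0.rp + st.cum_rp_produced + st.cum_dissynthesized
                     - st.cum_rp_degraded - st.cum_synthesized - st.rp)
                 for st in result.states)
    scale = max(1.0, max(st.cum_dsb_generated for st in result.states),
                max(st.cum_rp_produced + st.cum_synthesized for st in result.states))
    return dsb_err, rp_err, scale
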