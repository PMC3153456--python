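"""DSB + RP -> DSB-protein-complex (DSBC) synthesis and dis-synthesis.

Repair proceeds through four channels: a fast and a slow kinetics (70%
of breaks are routed fast at generation time; fast rates are 10x the
slow ones at the defaults), each with a first-order branch (both ends of
one break rejoined, flux linear in the cohort) and a second-order branch
(ends of two different breaks rejoined, flux quadratic in the cohort).

One RP unit binds per DSB.  RP is limiting: the per-DSB synthesis rates
are scaled by a saturating share rp / (rp + demand / eta_rp_dsb) and the
total synthesis in a step is additionally capped at the available RP, so
synthesis never exceeds either reactant.  Each synthesis event yields a
misrepaired complex (mDSBC) with a per-channel probability, otherwise a
correctly repaired one (rDSBC).  Complexes are unstable and dis-
synthesize back into one free DSB plus one free RP at first-order rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import CellState, KineticParameters


@dataclass(frozen=True)
class ChannelFluxes:
    """Realized synthesis/dis-synthesis fluxes of one step, by channel."""

    synth_fast_1: float
    synth_fast_2: float
    synth_slow_1: float
    synth_slow_2: float
    rdsbc_gain: float
    mdsbc_gain: float
    rdsbc_dissynth: float
    mdsbc_dissynth: float

    @property
    def total_synthesis(self) -> float:
        return self.synth_fast_1 + self.synth_fast_2 + self.synth_slow_1 + self.synth_slow_2


def channel_rates(params: KineticParameters) -> dict[tuple[str, int], float]:
    """The four channel rate constants beta_(speed, order)."""
    return {(speed, order): params.beta(speed, order)
            for speed in ("fast", "slow") for order in (1, 2)}


def _cohort_removal(cohort: float, beta1: float, beta2: float,
                    rp_share: float) -> tuple[float, float]:
    """First/second-order synthesis out of one cohort over one step.

    The cohort decays by 1 - exp(-(beta1 + beta2 * cohort) * rp_share),
    split across the two branches in proportion to their rates; the
    exponential form keeps the cohort non-negative at any rate.
    """
    rate1 = beta1 * rp_share
    rate2 = beta2 * cohort * rp_share
    total_rate = rate1 + rate2
    if total_rate <= 0.0 or cohort <= 0.0:
        return 0.0, 0.0
    removed = cohort * -math.expm1(-total_rate)
    return removed * rate1 / total_rate, removed * rate2 / total_rate


def step_dsbc(state: CellState, params: KineticParameters) -> ChannelFluxes:
    """Advance complex synthesis and dis-synthesis one time scale in place.

    Order within the step: synthesis out of both cohorts first (consuming
    equal amounts of DSB and RP), then dis-synthesis of existing
    complexes, whose freed breaks re-enter the cohorts under the same
    fast/slow routing as newly generated ones.
    """
    bad = state.validate(params.s0)
    if bad:
        raise ValueError(f"invalid state: {bad}")

    # raw mass-action demand sets the RP-limitation scale
    demand = (params.beta_fast_1 * state.dsb_fast
              + params.beta_fast_2 * state.dsb_fast ** 2
              + params.beta_slow_1 * state.dsb_slow
              + params.beta_slow_2 * state.dsb_slow ** 2)
    if demand > 0.0 and state.rp > 0.0 and params.eta_rp_dsb > 0.0:
        rp_share = state.rp / (state.rp + demand / params.eta_rp_dsb)
    else:
        rp_share = 0.0

    f1, f2 = _cohort_removal(state.dsb_fast, params.beta_fast_1,
                             params.beta_fast_2, rp_share)
    s1, s2 = _cohort_removal(state.dsb_slow, params.beta_slow_1,
                             params.beta_slow_2, rp_share)
    total = f1 + f2 + s1 + s2
    if total > state.rp:  # hard cap: one RP binds per DSB
        scale = state.rp / total
        f1, f2, s1, s2 = f1 * scale, f2 * scale, s1 * scale, s2 * scale
        total = state.rp

    state.dsb_fast -= f1 + f2
    state.dsb_slow -= s1 + s2
    state.rp -= total

    mdsbc_gain = (params.p_mis_fast_1 * f1 + params.p_mis_fast_2 * f2
                  + params.p_mis_slow_1 * s1 + params.p_mis_slow_2 * s2)
    rdsbc_gain = total - mdsbc_gain
    state.rdsbc += rdsbc_gain
    state.mdsbc += mdsbc_gain
    state.cum_synthesized += total
    state.cum_rdsbc_synth += rdsbc_gain
    state.cum_synth_fast += f1 + f2
    state.cum_synth_slow += s1 + s2

    # reversible dis-synthesis: complex -> one DSB + one RP
    rd = state.rdsbc * -math.expm1(-params.delta_r)
    md = state.mdsbc * -math.expm1(-params.delta_m)
    state.rdsbc -= rd
    state.mdsbc -= md
    released = rd + md
    state.rp += released
    state.dsb_fast += params.f_fast * released
    state.dsb_slow += (1.0 - params.f_fast) * released
    state.cum_dissynthesized += released

    return ChannelFluxes(synth_fast_1=f1, synth_fast_2=f2,
                         synth_slow_1=s1, synth_slow_2=s2,
                         rdsbc_gain=rdsbc_gain, mdsbc_gain=mdsbc_gain,
                         rdsbc_dissynth=rd, mdsbc_dissynth=md)


def fast_channel_fraction(n_dsbs: float = 1000.0,
                          params: KineticParameters | None = None,
                          rp_clamp: float = 1e9,
                          tol: float = 1e-6,
                          max_steps: int = 100_000) -> float:
    """Run a DSB bolus to exhaustion with abundant RP; return the fast share.

    Mean-field experiment: ``n_dsbs`` breaks are routed into cohorts by
    ``f_fast``, the RP pool is clamped abundant each step, and synthesis
    runs until the remaining DSB pool falls below ``tol``.  Dis-synthesis
    is switched off for the experiment (otherwise complexes keep leaking
    breaks back and the pool never empties).  The returned value is the
    fraction of all repaired breaks that went through the fast channels —
    at the defaults, 0.70 by construction of the routing.
    """
    import dataclasses

    from .core_model import default_parameters, make_initial_state

    if params is None:
        params = default_parameters()
    params = dataclasses.replace(params, delta_r=0.0, delta_m=0.0)
    state = make_initial_state(params, dsb=float(n_dsbs),
                               at_basal_equilibrium=False)
    for _ in range(max_steps):
        if state.dsb < tol:
            break
        state.rp = rp_clamp
        step_dsbc(state, params)
    else:
        raise RuntimeError(f"bolus not exhausted after {max_steps} steps")
    if state.cum_synthesized <= 0.0:
        raise RuntimeError("no synthesis occurred")
    return state.cum_synth_fast / state.cum_synthesized
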