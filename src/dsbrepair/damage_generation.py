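"""DSB induction under ionizing radiation and DNA/repair-gene bookkeeping.

Per time scale, the number of new double-strand breaks is a Poisson draw
with mean ``k_t * a_ir * dose`` (linear in dose, ~35 DSBs per Gy at the
defaults, matching the experimentally measured 30-40 per Gy).  Each
resulting break is additionally counted as a new DNA molecule.  DNA and
the repair gene are destroyed by interaction with the radiation field;
destroyed repair gene is removed permanently (no gene synthesis exists,
so the gene pool is monotone non-increasing).

Destruction fluxes use exponential-decay updates, pool * (1 - exp(-rate)),
which keep every pool non-negative at any rate and dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .core_model import CellState, CellTypeCoefficients, KineticParameters

MEAN_FIELD = "mean-field"
STOCHASTIC = "stochastic"

RngOrMode = Union[np.random.Generator, str]


@dataclass(frozen=True)
class DamageStepResult:
    """Realized fluxes of one damage step."""

    new_dsbs: float        # integer-valued in stochastic mode
    dna_destroyed: float
    gene_destroyed: float


def _check_mode(rng_or_mode: RngOrMode) -> np.random.Generator | None:
    """Return the generator for stochastic mode, None for mean-field."""
    if isinstance(rng_or_mode, np.random.Generator):
        return rng_or_mode
    if rng_or_mode == MEAN_FIELD:
        return None
    raise ValueError(
        f"expected a numpy Generator or {MEAN_FIELD!r}, got {rng_or_mode!r}")


def sample_dsb_count(dose: float, params: KineticParameters,
                     rng_or_mode: RngOrMode) -> float:
    """Number of DSBs induced in one time scale at the given dose (Gy).

    Stochastic mode draws Poisson(k_t * a_ir * dose); mean-field mode
    returns the mean itself, so the expectation is identical in both
    modes and scales linearly with dose.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0 Gy, got {dose!r}")
    mean = params.k_t * params.a_ir * dose
    rng = _check_mode(rng_or_mode)
    if rng is None:
        return mean
    return float(rng.poisson(mean))


def destruction_fraction(gamma: float, rate: float, dose: float) -> float:
    """Fraction of a pool destroyed in one time scale: 1 - exp(-gamma*rate*dose)."""
    return -math.expm1(-gamma * rate * dose)


def step_damage(state: CellState, dose: float, params: KineticParameters,
                cell: CellTypeCoefficients, rng_or_mode: RngOrMode) -> DamageStepResult:
    """Apply one time scale of radiation damage to ``state`` in place.

    New breaks are routed to the fast/slow repair cohorts at generation
    time (fraction ``f_fast`` fast; a binomial split in stochastic mode).
    By default new DNA counted from breaks accrues only to the DNA ledger
    and is not itself breakable substrate; ``params.new_dna_feedback``
    switches the positive feedback on.
    """
    bad = state.validate(params.s0)
    if bad:
        raise ValueError(f"invalid state: {bad}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0 Gy, got {dose!r}")

    rng = _check_mode(rng_or_mode)
    new_dsbs = sample_dsb_count(dose, params, rng_or_mode)

    # cohort routing at generation time
    if rng is None:
        fast = params.f_fast * new_dsbs
    else:
        fast = float(rng.binomial(int(new_dsbs), params.f_fast)) if new_dsbs else 0.0
    state.dsb_fast += fast
    state.dsb_slow += new_dsbs - fast
    state.cum_dsb_generated += new_dsbs

    # DNA destruction acts on breakable substrate only
    substrate = state.dna if params.new_dna_feedback else state.dna - state.dna_new
    substrate = max(substrate, 0.0)
    dna_destroyed = substrate * destruction_fraction(
        cell.gamma_dna, params.mu_dna_rate, dose)
    state.dna -= dna_destroyed

    # each resulting DSB is counted as a new DNA
    added = params.nu_new_dna * new_dsbs
    state.dna += added
    if not params.new_dna_feedback:
        state.dna_new += added

    # repair gene is destroyed permanently
    gene_destroyed = state.repair_gene * destruction_fraction(
        cell.gamma_gene, params.mu_gene_rate, dose)
    state.repair_gene -= gene_destroyed

    return DamageStepResult(new_dsbs=new_dsbs, dna_destroyed=dna_destroyed,
                            gene_destroyed=gene_destroyed)
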