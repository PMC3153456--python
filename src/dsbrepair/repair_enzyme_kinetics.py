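"""Repair-mRNA transcription and repair-protein (RP) translation kinetics.

Transcription is driven by the repair gene at a basal rate plus a
mass-action gene-DSB encounter term; translation mirrors this with the
mRNA pool and an mRNA-DSB encounter term.  Both interaction terms carry
a saturation factor that equals 1 below a DSB threshold and decreases
beyond it: past the capability threshold of the repair machinery,
additional damage slows rather than speeds enzyme production.

Degradation is first-order.  Pools relax exponentially toward the
production/degradation balance within each time scale, which makes the
zero-damage fixed point exact:

    mrna* = k_mrna_basal * gene / d_mrna
    rp*   = k_rp_basal * mrna* / d_rp
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import CellState, KineticParameters


@dataclass(frozen=True)
class EnzymeFluxes:
    """Realized per-time-scale enzyme fluxes (all non-negative)."""

    mrna_produced: float
    mrna_degraded: float
    rp_produced: float
    rp_degraded: float


def saturation_factor(dsb: float, threshold: float) -> float:
    """Rational saturation factor: 1 up to the threshold, ~threshold/dsb beyond.

    threshold / (threshold + max(0, dsb - threshold)); non-increasing in
    dsb, equal to 1 for dsb <= threshold.  A zero threshold disables the
    interaction beyond dsb = 0 entirely.
    """
    excess = max(0.0, dsb - threshold)
    if excess == 0.0:
        return 1.0
    return threshold / (threshold + excess)


def transcription_flux(dsb: float, gene: float, params: KineticParameters) -> float:
    """Repair-mRNA production rate from the gene pool at the given DSB load."""
    if dsb < 0 or gene < 0:
        raise ValueError(f"dsb and gene must be >= 0, got {dsb!r}, {gene!r}")
    interaction = params.eta_gene_dsb * gene * dsb * saturation_factor(dsb, params.theta_mrna)
    return params.k_mrna_basal * gene + interaction


def translation_flux(dsb: float, mrna: float, params: KineticParameters) -> float:
    """RP production rate from the mRNA pool at the given DSB load."""
    if dsb < 0 or mrna < 0:
        raise ValueError(f"dsb and mrna must be >= 0, got {dsb!r}, {mrna!r}")
    interaction = params.eta_mrna_dsb * mrna * dsb * saturation_factor(dsb, params.theta_rp)
    return params.k_rp_basal * mrna + interaction


def _relax(pool: float, production: float, decay: float) -> tuple[float, float, float]:
    """Exponential relaxation of a pool toward production/decay over one step.

    Returns (new_pool, produced, degraded) with new_pool = pool + produced
    - degraded exactly; degraded <= pool always.
    """
    if decay <= 0.0:
        return pool + production, production, 0.0
    frac = -math.expm1(-decay)          # 1 - exp(-decay) in (0, 1]
    target = production / decay
    new_pool = pool + (target - pool) * frac
    degraded = pool * frac
    produced = target * frac
    return new_pool, produced, degraded


def step_enzymes(state: CellState, params: KineticParameters) -> EnzymeFluxes:
    """Advance mRNA and RP pools one time scale in place; returns the fluxes.

    Sequential operator splitting: transcription is evaluated at the
    step's starting pools, translation at the freshly updated mRNA pool.
    The RP production/degradation ledgers are updated so the RP
    conservation identity stays exact.
    """
    bad = state.validate(params.s0)
    if bad:
        raise ValueError(f"invalid state: {bad}")

    dsb = state.dsb
    t_flux = transcription_flux(dsb, state.repair_gene, params)
    state.mrna, mrna_produced, mrna_degraded = _relax(state.mrna, t_flux, params.d_mrna)

    r_flux = translation_flux(dsb, state.mrna, params)
    state.rp, rp_produced, rp_degraded = _relax(state.rp, r_flux, params.d_rp)

    state.cum_rp_produced += rp_produced
    state.cum_rp_degraded += rp_degraded
    return EnzymeFluxes(mrna_produced=mrna_produced, mrna_degraded=mrna_degraded,
                        rp_produced=rp_produced, rp_degraded=rp_degraded)
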