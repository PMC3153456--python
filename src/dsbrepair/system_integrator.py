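"""Whole-cell time stepping: damage -> enzymes -> synthesis -> toxins/stability.

One time scale applies the three process stages in a fixed operator-
splitting order and then updates the toxin burden and genome stability.
Toxins are the misrepaired complexes plus the still-intact breaks; when
the burden exceeds the tolerable threshold, stability decays
multiplicatively,

    S <- S * exp(-lambda_tox * max(0, toxins - theta_tox)),

which keeps S in [0, s0] without clipping and makes it non-increasing by
construction.

Runs are reproducible: a stochastic run is a pure function of
(spec, seed); mean-field runs are seed-independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_model import (CellState, CellTypeCoefficients, DoseProfile,
                         KineticParameters, SimulationResult,
                         default_parameters, make_initial_state)
from .damage_generation import MEAN_FIELD, STOCHASTIC, step_damage
from .dsbc_synthesis import step_dsbc
from .repair_enzyme_kinetics import step_enzymes

logger = logging.getLogger("dsbrepair")


class IntegratorError(RuntimeError):
    """A pool went negative or non-finite during stepping (bug trap)."""


@dataclass
class RunSpec:
    """Everything needed to reproduce one simulation run."""

    profile: DoseProfile
    params: KineticParameters = field(default_factory=default_parameters)
    cell: CellTypeCoefficients = field(default_factory=CellTypeCoefficients)
    initial: Optional[CellState] = None
    seed: Optional[int] = None
    mode: str = STOCHASTIC
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in (STOCHASTIC, MEAN_FIELD):
            raise ValueError(f"mode must be {STOCHASTIC!r} or {MEAN_FIELD!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.initial is None:
            self.initial = make_initial_state(self.params)
        if self.mode == STOCHASTIC and self.seed is None:
            self.seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
            logger.info("no seed given; drew seed=%d", self.seed)


def _update_toxins_and_stability(state: CellState, params: KineticParameters) -> None:
    state.toxins = state.mdsbc + state.dsb
    excess = state.toxins - params.theta_tox
    if excess > 0.0:
        state.stability *= math.exp(-params.lambda_tox * excess)


def step(state: CellState, dose: float, spec: RunSpec,
         rng: np.random.Generator | None = None) -> float:
    """Advance ``state`` one time scale in place; returns the DSB draw.

    Stage order: radiation damage, enzyme production/degradation, complex
    synthesis/dis-synthesis, toxin and stability update.  ``rng`` is the
    run's generator (None in mean-field mode).
    """
    rng_or_mode = rng if rng is not None else MEAN_FIELD
    damage = step_damage(state, dose, spec.params, spec.cell, rng_or_mode)
    step_enzymes(state, spec.params)
    step_dsbc(state, spec.params)
    _update_toxins_and_stability(state, spec.params)

    bad = state.validate(spec.params.s0)
    if bad:
        raise IntegratorError(f"state invalid after update: {bad}")
    return damage.new_dsbs


def run(spec: RunSpec) -> SimulationResult:
    """Run the full dose profile; returns the complete trajectory.

    ``states[0]`` is the initial state; ``states[t]`` is the state after
    ``t`` time scales.  Identical (spec, seed) pairs give bit-identical
    results; mean-field mode ignores the seed.
    """
    state = spec.initial.copy()
    bad = state.validate(spec.params.s0)
    if bad:
        raise ValueError(f"invalid initial state: {bad}")

    rng = (np.random.default_rng(spec.seed) if spec.mode == STOCHASTIC else None)
    states = [state.copy()]
    draws: list[float] = []
    for t, dose in enumerate(spec.profile.doses()):
        try:
            draws.append(step(state, dose, spec, rng))
        except (ValueError, IntegratorError) as exc:
            raise IntegratorError(f"at time scale {t}: {exc}") from exc
        states.append(state.copy())
    return SimulationResult(states=states, dsb_draws=draws, params=spec.params,
                            profile=spec.profile, cell=spec.cell,
                            seed=spec.seed if spec.mode == STOCHASTIC else None,
                            mode=spec.mode)
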