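"""Domain types, default parameters, and validation for the repair-kinetics model.

The model describes a single cell under ionizing radiation (IR) as two
interacting populations of "active particles": a DNA-damage population
(DNA, double-strand breaks, repaired and misrepaired DSB-protein
complexes) and a repair-enzyme population (repair gene, repair mRNA,
repair protein).  Time advances in abstract discrete units ("time
scales"); each step applies damage generation, enzyme kinetics, complex
synthesis, and toxin/stability bookkeeping in that order.

Every rate constant, threshold, and channel fraction used anywhere in
the simulator is a field of :class:`KineticParameters` and lives here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import yaml

logger = logging.getLogger("dsbrepair")

#: Where the default parameter values come from.  The published parameter
#: table for this model is distributed as a supplementary document that is
#: not machine-readable; the defaults shipped here are surrogate values
#: calibrated so that the qualitative single-cell trajectories under
#: constant 8 Gy (mRNA rise/peak/collapse, late repair-protein collapse,
#: monotone repair-gene loss, staged genome-stability decay) are
#: reproduced.  See docs/methods.md.
PARAMETER_PROVENANCE = "surrogate"


# ---------------------------------------------------------------------------
# Dose profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseProfile:
    """Piecewise-constant IR dose schedule over discrete time scales.

    ``schedule`` is an ordered list of ``(n_steps, dose_gy)`` segments; a
    constant-dose exposure is a single segment.
    """

    schedule: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        for n, dose in self.schedule:
            if int(n) != n or n <= 0:
                raise ValueError(f"segment length must be a positive integer, got {n!r}")
            if dose < 0:
                raise ValueError(f"dose must be >= 0 Gy, got {dose!r}")

    @classmethod
    def constant(cls, dose: float, n_steps: int) -> "DoseProfile":
        return cls(schedule=((int(n_steps), float(dose)),))

    @property
    def total_steps(self) -> int:
        return sum(n for n, _ in self.schedule)

    def doses(self) -> Iterator[float]:
        """Yield the dose applied at each of the ``total_steps`` time scales."""
        for n, dose in self.schedule:
            for _ in range(n):
                yield dose

    def dose_at(self, t: int) -> float:
        if t < 0 or t >= self.total_steps:
            raise IndexError(f"time scale {t} outside [0, {self.total_steps})")
        acc = 0
        for n, dose in self.schedule:
            acc += n
            if t < acc:
                return dose
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Cell type
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTypeCoefficients:
    """Cell-type sensitivity coefficients for destruction under IR.

    ``gamma_dna`` scales the DNA destruction rate, ``gamma_gene`` the
    repair-gene destruction rate; both are dimensionless in [0, 1].
    """

    gamma_dna: float = 0.8
    gamma_gene: float = 0.8


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------

@dataclass
class KineticParameters:
    """All rate constants, thresholds and channel fractions of the model.

    Units: abundances are molecule counts; rates are per time scale; the
    dose unit is Gy.  The four synthesis channels are indexed by repair
    speed (fast/slow) and reaction order (first: both ends of one break
    rejoined; second: ends of two different breaks rejoined).  Only the
    slow rates are free parameters: the fast rates default to
    ``rate_ratio_fast_slow`` times the matching slow rate, making the
    fast/slow rate ratio a structural constraint.
    """

    # damage generation
    k_t: float = 1.0          # per-time-scale DSB-count scaling
    a_ir: float = 35.0        # mean DSBs induced per Gy
    mu_dna_rate: float = 1.0e-5    # DNA x IR interaction rate (per Gy per time scale)
    mu_gene_rate: float = 2.2e-4   # repair gene x IR interaction rate
    nu_new_dna: float = 1.0   # new DNA counted per resulting DSB

    # repair enzyme kinetics
    k_mrna_basal: float = 0.02   # basal transcription (mRNA per gene per step)
    k_rp_basal: float = 0.05     # basal translation (RP per mRNA per step)
    d_mrna: float = 0.05         # mRNA self-degradation rate
    d_rp: float = 0.005           # RP self-degradation rate
    eta_gene_dsb: float = 1.0e-4  # gene-DSB encounter coefficient
    eta_mrna_dsb: float = 0.05  # mRNA-DSB encounter coefficient
    eta_rp_dsb: float = 1.0       # RP-DSB encounter coefficient (RP affinity scale)
    theta_mrna: float = 300.0    # DSB threshold past which transcription saturates
    theta_rp: float = 300.0      # DSB threshold past which translation saturates

    # DSBC synthesis channels
    f_fast: float = 0.70           # fraction of DSBs routed to fast kinetics
    rate_ratio_fast_slow: float = 10.0
    beta_slow_1: float = 0.02      # slow first-order rate (per DSB per step)
    beta_slow_2: float = 2.0e-6    # slow second-order rate (per DSB pair per step)
    beta_fast_1: Optional[float] = None   # derived: ratio x beta_slow_1
    beta_fast_2: Optional[float] = None   # derived: ratio x beta_slow_2
    p_mis_fast_1: float = 0.02     # misrepair probability per channel
    p_mis_fast_2: float = 0.08
    p_mis_slow_1: float = 0.05
    p_mis_slow_2: float = 0.15
    delta_r: float = 2.0e-4         # rDSBC dis-synthesis rate
    delta_m: float = 2.0e-4         # mDSBC dis-synthesis rate

    # toxins and genome stability
    theta_tox: float = 2000.0       # maximal toxin burden a cell tolerates
    lambda_tox: float = 2.0e-7     # toxin effect rate on genome stability
    s0: float = 1.0                # initial genome-stability level

    # modelling switch: whether DSB-derived new DNA feeds back into the
    # breakable DNA substrate (default: ledger-only, no positive feedback)
    new_dna_feedback: bool = False

    def __post_init__(self) -> None:
        if self.beta_fast_1 is None:
            self.beta_fast_1 = self.rate_ratio_fast_slow * self.beta_slow_1
        if self.beta_fast_2 is None:
            self.beta_fast_2 = self.rate_ratio_fast_slow * self.beta_slow_2

    def beta(self, speed: str, order: int) -> float:
        return {("fast", 1): self.beta_fast_1, ("fast", 2): self.beta_fast_2,
                ("slow", 1): self.beta_slow_1, ("slow", 2): self.beta_slow_2}[(speed, order)]

    def p_misrepair(self, speed: str, order: int) -> float:
        return {("fast", 1): self.p_mis_fast_1, ("fast", 2): self.p_mis_fast_2,
                ("slow", 1): self.p_mis_slow_1, ("slow", 2): self.p_mis_slow_2}[(speed, order)]

    # -- config serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            logger.warning("config missing keys %s; falling back to defaults",
                           sorted(missing))
        return cls(**d)


def default_parameters() -> KineticParameters:
    """Return the shipped default parameter set (surrogate provenance)."""
    return KineticParameters()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_NONNEGATIVE_FIELDS = (
    "k_t", "a_ir", "mu_dna_rate", "mu_gene_rate", "nu_new_dna",
    "k_mrna_basal", "k_rp_basal", "d_mrna", "d_rp",
    "eta_gene_dsb", "eta_mrna_dsb", "eta_rp_dsb",
    "theta_mrna", "theta_rp", "rate_ratio_fast_slow",
    "beta_slow_1", "beta_slow_2", "beta_fast_1", "beta_fast_2",
    "delta_r", "delta_m", "theta_tox", "lambda_tox", "s0",
)
_UNIT_INTERVAL_FIELDS = (
    "f_fast", "p_mis_fast_1", "p_mis_fast_2", "p_mis_slow_1", "p_mis_slow_2",
)


def validate_parameters(params: KineticParameters) -> list[str]:
    """Check every structural invariant; return the violations (empty == valid).

    Validation reports rather than raising, so a partially edited config
    can surface all its problems at once.
    """
    violations: list[str] = []
    for name in _NONNEGATIVE_FIELDS:
        v = getattr(params, name)
        if v is None or v < 0:
            violations.append(f"{name}: must be >= 0, got {v!r}")
    for name in _UNIT_INTERVAL_FIELDS:
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            violations.append(f"{name}: must be in [0, 1], got {v!r}")
    for j, slow_name, fast_name in ((1, "beta_slow_1", "beta_fast_1"),
                                    (2, "beta_slow_2", "beta_fast_2")):
        slow = getattr(params, slow_name)
        fast = getattr(params, fast_name)
        if slow and fast is not None:
            ratio = fast / slow
            if abs(ratio - params.rate_ratio_fast_slow) > 1e-9 * max(1.0, params.rate_ratio_fast_slow):
                violations.append(
                    f"rate_ratio_fast_slow: {fast_name}/{slow_name} = {ratio:g} "
                    f"!= rate_ratio_fast_slow = {params.rate_ratio_fast_slow:g}")
    return violations


# ---------------------------------------------------------------------------
# Cell state
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """Instantaneous abundances of all active particles plus ledgers.

    The DSB pool is carried as two cohorts (``dsb_fast``/``dsb_slow``):
    cohort membership is assigned when a break is generated (a fraction
    ``f_fast`` of each draw) and determines which synthesis channel pair
    can consume it.  ``dna_new`` tracks DNA counted from resulting DSBs
    ("each resulting DSB is dealt as a new DNA"); unless the feedback
    switch is on, this part of the DNA ledger is not breakable substrate.

    Cumulative ledgers (``cum_*``) are non-decreasing and make the two
    conservation identities checkable to floating-point tolerance:

    * DSB pairing:  dsb0 + cum_dsb_generated + cum_dissynthesized
      == dsb_fast + dsb_slow + cum_synthesized
    * RP:  rp0 + cum_rp_produced + cum_dissynthesized
      - cum_rp_degraded - cum_synthesized == rp
      (cum_synthesized counts the RP ever bound into complexes, one per
      DSB; cum_dissynthesized counts the RP released back)
    """

    dna: float
    repair_gene: float
    dsb_fast: float = 0.0
    dsb_slow: float = 0.0
    mrna: float = 0.0
    rp: float = 0.0
    rdsbc: float = 0.0
    mdsbc: float = 0.0
    toxins: float = 0.0
    stability: float = 1.0
    dna_new: float = 0.0
    cum_dsb_generated: float = 0.0
    cum_synthesized: float = 0.0
    cum_rdsbc_synth: float = 0.0
    cum_synth_fast: float = 0.0
    cum_synth_slow: float = 0.0
    cum_dissynthesized: float = 0.0
    cum_rp_produced: float = 0.0
    cum_rp_degraded: float = 0.0

    @property
    def dsb(self) -> float:
        """Total intact (unrepaired) DSB count across both cohorts."""
        return self.dsb_fast + self.dsb_slow

    def copy(self) -> "CellState":
        return dataclasses.replace(self)

    def validate(self, s0: float = 1.0) -> list[str]:
        bad = []
        for name in ("dna", "repair_gene", "dsb_fast", "dsb_slow", "mrna", "rp",
                     "rdsbc", "mdsbc", "toxins", "cum_dsb_generated",
                     "cum_synthesized", "cum_dissynthesized",
                     "cum_rp_produced", "cum_rp_degraded"):
            v = getattr(self, name)
            if not (v >= 0.0):  # catches NaN too
                bad.append(f"{name}: must be >= 0, got {v!r}")
        if not (0.0 <= self.stability <= s0 + 1e-12):
            bad.append(f"stability: must be in [0, {s0}], got {self.stability!r}")
        return bad


def make_initial_state(params: KineticParameters,
                       dna: float = 10_000.0,
                       repair_gene: float = 100.0,
                       dsb: float = 0.0,
                       at_basal_equilibrium: bool = True) -> CellState:
    """Build a valid initial state.

    With ``at_basal_equilibrium`` the mRNA and RP pools start at the
    zero-IR fixed point (basal production balancing self-degradation), so
    an unirradiated cell is stationary from the first step.  An initial
    DSB bolus is split into fast/slow cohorts by ``f_fast``, the same
    routing applied to breaks generated during a run.
    """
    if at_basal_equilibrium and params.d_mrna > 0 and params.d_rp > 0:
        mrna = params.k_mrna_basal * repair_gene / params.d_mrna
        rp = params.k_rp_basal * mrna / params.d_rp
    else:
        mrna = 0.0
        rp = 0.0
    return CellState(
        dna=dna,
        repair_gene=repair_gene,
        dsb_fast=params.f_fast * dsb,
        dsb_slow=(1.0 - params.f_fast) * dsb,
        mrna=mrna,
        rp=rp,
        toxins=dsb,
        stability=params.s0,
    )


# ---------------------------------------------------------------------------
# Simulation result container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Full trajectory of one run: states[0] is the initial state."""

    states: list[CellState]
    dsb_draws: list[float]
    params: KineticParameters
    profile: DoseProfile
    cell: CellTypeCoefficients
    seed: Optional[int]
    mode: str  # "stochastic" | "mean-field"

    def __post_init__(self) -> None:
        if len(self.states) != self.profile.total_steps + 1:
            raise ValueError("states must cover every time scale plus t=0")
        if len(self.dsb_draws) != self.profile.total_steps:
            raise ValueError("one DSB draw per time scale required")

    def series(self, name: str) -> list[float]:
        """Extract one state variable as a per-time-scale series."""
        return [getattr(s, name) for s in self.states]


# ---------------------------------------------------------------------------
# Config file I/O (flat YAML key-value document)
# ---------------------------------------------------------------------------

_CELL_KEYS = ("gamma_dna", "gamma_gene")


def save_config(path, params: KineticParameters,
                cell: CellTypeCoefficients | None = None) -> None:
    """Write a flat YAML config; includes parameter provenance as a comment."""
    doc = params.to_dict()
    if cell is not None:
        doc.update(gamma_dna=cell.gamma_dna, gamma_gene=cell.gamma_gene)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dsbrepair parameters (provenance: {PARAMETER_PROVENANCE})\n")
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[KineticParameters, CellTypeCoefficients]:
    """Read a flat YAML config back into parameter and cell-type objects.

    Unknown keys are an error; missing keys fall back to defaults with a
    logged warning (handled by :meth:`KineticParameters.from_dict`).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config must be a flat mapping, got {type(doc).__name__}")
    cell_kwargs = {k: doc.pop(k) for k in list(doc) if k in _CELL_KEYS}
    params = KineticParameters.from_dict(doc)
    return params, CellTypeCoefficients(**cell_kwargs)
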