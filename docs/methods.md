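# Methods

## Scope and state

`dsbrepair` simulates the damage-repair kinetics of one cell under
ionizing radiation as a discrete-time population-balance model. The
state is the vector of active-particle abundances — DNA, repair gene,
intact double-strand breaks (DSBs, carried as a fast and a slow cohort),
repair mRNA, repair protein (RP), correctly repaired complexes (rDSBC),
misrepaired complexes (mDSBC) — plus the toxin burden, a genome-stability
level in [0, s₀], and cumulative ledgers for every creation/destruction
flux. Time advances in abstract "time scales"; the model deliberately
does not assign a physical duration to one step, and abundances are
molecule counts, not concentrations. Downstream signalling (P53 and its
pathways) and toxin degradation are outside the model: toxins only
accumulate, which is what makes sustained exposure eventually lethal.

## Update scheme

One step applies four stages in fixed operator-splitting order —
radiation damage, enzyme kinetics, complex synthesis, toxin/stability
update — with Δt = 1 time scale. All destruction/degradation updates use
the exponential form pool·(1 − exp(−rate)), which is the exact solution
of the corresponding linear decay over the step and keeps every pool
non-negative at any rate; linear production/degradation pairs (mRNA, RP)
relax exponentially toward their balance point, so the zero-damage fixed
point

    mrna* = k_mrna_basal · gene / d_mrna,   rp* = k_rp_basal · mrna* / d_rp

is stationary to machine precision, and an unirradiated cell initialized
there does not drift.

Only DSB generation is stochastic: a Poisson draw with mean
k_t · a_ir · dose per time scale, binomially split into the fast/slow
cohorts. All other fluxes are smooth functions of the state — a hybrid
scheme in which the mean-field mode (every draw replaced by its
expectation) is the exact expectation of the generation process.
Misrepair is applied as a per-channel fraction of the (real-valued)
synthesis flux in both modes rather than as a separate integer draw;
this keeps the conservation ledgers exact and the stochastic/mean-field
pair consistent, at the cost of not modelling misrepair-count noise.

Two identities hold at every step, checked in the tests at relative
tolerance 1e-9 (the errors observed are at the 1e-15 relative level,
i.e. pure floating-point accumulation):

- break pairing: dsb₀ + generated + dis-synthesized = intact + synthesized;
- RP: rp₀ + produced + released − degraded − ever-bound = rp
  (one RP binds per break; dis-synthesis releases exactly one of each).

## Saturation of enzyme production

The damage-driven transcription and translation terms are mass-action
encounters (gene·DSB, mRNA·DSB) multiplied by a rational saturation
factor

    g(N; θ) = θ / (θ + max(0, N − θ)),

equal to 1 up to the capability threshold θ and decaying like θ/N beyond
it: past the threshold, additional damage no longer accelerates — and
eventually effectively caps — enzyme production. The published
description of this mechanism is qualitative (production "begins to
decrease" beyond a threshold); the rational form above is this package's
concrete choice, selected because it is continuous, parameter-sparse,
and exactly neutral (g ≡ 1) below threshold.

## RP limitation and channel structure

Breaks are routed to the fast cohort with probability f_fast = 0.70 at
generation time; fast channel rates are structurally
rate_ratio_fast_slow (= 10) times the slow ones (the fast rates are
derived fields, so the ratio cannot drift apart silently). Within a
cohort, the first-order channel removes breaks at rate β_i1 (both ends
of one break rejoined) and the second-order channel at β_i2·cohort
(ends of two different breaks), both scaled by the RP availability share

    s = rp / (rp + demand / eta_rp_dsb),

where demand is the total raw mass-action synthesis demand; total
synthesis is additionally hard-capped at the available RP. The share
form is this package's choice for "limited repair proteins around
increasing damage sites"; any saturating, monotone-in-rp form with the
same cap would serve. Dis-synthesized complexes return one DSB and one
RP; the freed break re-enters the cohorts under the same 70/30 routing,
which leaves the fast-channel share of all repairs at exactly f_fast.

## Toxins and genome stability

Toxins are the instantaneous burden mdsbc + intact dsb. Stability decays
multiplicatively, S ← S·exp(−λ_tox·max(0, toxins − θ_tox)), which keeps
it in [0, s₀] and non-increasing without clipping. "Cellular activity of
transferring DNA damage" is reported as the per-time-scale rDSBC
synthesis flux (a derived indicator track), not as an extra state
variable.

## Parameters

Biologically anchored defaults: a_ir = 35 DSBs per Gy (measured range
30–40), f_fast = 0.70, rate ratio 10, γ = 0.8 for the reference cell
type, s₀ = 1 so stability reads as a fraction.

The remaining rate constants are **surrogate** values (the config
provenance says so): the published parameter table for this model family
is distributed as a non-machine-readable supplementary document, so the
defaults here were calibrated once so that the qualitative single-cell
trajectories under constant 8 Gy reproduce the expected staging —
mRNA rises to a single early peak and then decays monotonically towards
zero; RP rises to a climax and later collapses by three orders of
magnitude; the intact-DSB track holds a dynamic equilibrium (~4×10³ at
8 Gy) for roughly 1,500 time scales and then rises steeply; stability
decreases in stages; and collapse times shorten monotonically with dose
over 10/15/20 Gy. The defaults are, per time scale: mu_dna_rate 1e-5,
mu_gene_rate 2.2e-4 (per Gy), k_mrna_basal 0.02, k_rp_basal 0.05,
d_mrna 0.05, d_rp 0.005, eta_gene_dsb 1e-4, eta_mrna_dsb 0.05,
eta_rp_dsb 1, θ_mrna = θ_rp = 300 DSBs, β_slow = (0.02, 2e-6),
misrepair probabilities (fast/slow × 1st/2nd) = 0.02/0.08/0.05/0.15
(second-order channels misrepair more, consistent with wrong-end
joining), δ_r = δ_m = 2e-4, θ_tox = 2000, λ_tox = 2e-7. With surrogate
rates the *timing* of collapse events (e.g. "about 1,500 time scales")
is not a calibrated quantity; only orderings — a collapse exists, the
activity turnover follows the RP peak, collapse is dose-monotone — are
asserted by the tests.

Two structural knobs deserve mention:

- `new_dna_feedback` (default off): each resulting break is counted as a
  new DNA; by default that new DNA is ledger-only and not itself
  breakable substrate, avoiding a positive feedback loop the model
  description does not call for. The flag turns the feedback on.
- `delta_r`/`delta_m` must be small relative to the synthesis rates:
  complexes are the model's only damage sink, and if the complex pool
  reaches its dis-synthesis equilibrium within the run, every generated
  break eventually leaks back and the intact-DSB plateau disappears.

## Degenerate inputs and numerical choices

Zero dose is exactly neutral (no draws, no destruction). Zero pools give
zero fluxes. Rates of any magnitude are safe (exponential updates).
Validation reports all violations rather than raising. Stochastic runs
are a pure function of (spec, seed); the integrator traps NaN/negative
pools as an internal error with the time index attached — reaching it is
a bug, not a user error.

Detection operations: "near zero" defaults to 1% of a track's maximum,
searched after the track's peak; the activity turnover is the first
smoothed (trailing 25-step window) sign change of the per-step rDSBC
flux increments. The moving average recomputes each window sum directly
— a running cumulative sum can lose the sign of near-zero window means
to cancellation.

## What the simulations do and do not show

All quantitative behaviour here is produced by this model's own
dynamics under surrogate rate constants, at the problem sizes used in
the test suite (2,500-step runs; 100,000-draw sampling experiments;
60-trajectory ensembles over 40 steps for the stochastic/mean-field
consistency check). The model abstracts away molecular mechanism
(HR/NHEJ enzyme identity, end resection, dose-rate and track-structure
effects, transcription delays), assumes spatial homogeneity, and keeps
time and abundance units abstract; agreement of its trajectories with
the qualitative staging above shows internal consistency of the
kinetic scheme, not validation against cell-biology measurements.
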