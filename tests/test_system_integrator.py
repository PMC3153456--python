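"""Whole-run behaviour: determinism, conservation, stability, dose response."""

import numpy as np
import pytest

from dsbrepair import DoseProfile, RunSpec, make_initial_state, run
from dsbrepair.damage_generation import MEAN_FIELD
from dsbrepair.indicators_io import first_below

from conftest import ledger_errors


class TestStep:
    def test_zero_dose_fixed_point_is_stationary(self, params):
        spec = RunSpec(profile=DoseProfile.constant(0.0, 50), params=params,
                       mode=MEAN_FIELD)
        res = run(spec)
        first, last = res.states[0], res.states[-1]
        for name in ("dna", "repair_gene", "mrna", "rp", "stability"):
            assert getattr(last, name) == pytest.approx(getattr(first, name),
                                                        abs=1e-9)

    def test_stability_constant_without_toxins(self, params):
        spec = RunSpec(profile=DoseProfile.constant(0.0, 100), params=params,
                       mode=MEAN_FIELD)
        res = run(spec)
        assert all(s.toxins == 0.0 for s in res.states)
        assert all(s.stability == params.s0 for s in res.states)


class TestRunContract:
    def test_empty_profile_returns_initial_state_only(self, params):
        spec = RunSpec(profile=DoseProfile(schedule=()), params=params,
                       mode=MEAN_FIELD)
        empty = run(spec)
        assert len(empty.states) == 1
        assert empty.dsb_draws == []
        assert empty.states[0] == spec.initial

    def test_same_seed_gives_identical_trajectories(self, params):
        mk = lambda: RunSpec(profile=DoseProfile.constant(8.0, 200),
                             params=params, seed=11)
        r1, r2 = run(mk()), run(mk())
        assert r1.dsb_draws == r2.dsb_draws
        assert r1.states[-1] == r2.states[-1]

    def test_different_seeds_differ(self, params):
        r1 = run(RunSpec(profile=DoseProfile.constant(8.0, 50), params=params, seed=1))
        r2 = run(RunSpec(profile=DoseProfile.constant(8.0, 50), params=params, seed=2))
        assert r1.dsb_draws != r2.dsb_draws

    def test_mean_field_ignores_seed(self, params):
        r1 = run(RunSpec(profile=DoseProfile.constant(8.0, 50), params=params,
                         mode=MEAN_FIELD, seed=1))
        r2 = run(RunSpec(profile=DoseProfile.constant(8.0, 50), params=params,
                         mode=MEAN_FIELD, seed=99))
        assert r1.states[-1] == r2.states[-1]
        assert r1.seed is None


class TestConservation:
    def test_ledgers_conserved_every_step_mean_field(self, run_8gy_meanfield):
        dsb_err, rp_err, scale = ledger_errors(run_8gy_meanfield)
        assert dsb_err <= 1e-9 * scale
        assert rp_err <= 1e-9 * scale

    def test_ledgers_conserved_every_step_stochastic(self, run_8gy_stochastic):
        dsb_err, rp_err, scale = ledger_errors(run_8gy_stochastic)
        assert dsb_err <= 1e-9 * scale
        assert rp_err <= 1e-9 * scale

    def test_ledgers_conserved_with_initial_bolus(self, params):
        initial = make_initial_state(params, dsb=1000.0)
        spec = RunSpec(profile=DoseProfile.constant(4.0, 300), params=params,
                       initial=initial, seed=5)
        dsb_err, rp_err, scale = ledger_errors(run(spec))
        assert dsb_err <= 1e-9 * scale
        assert rp_err <= 1e-9 * scale

    def test_ledgers_are_non_decreasing(self, run_8gy_stochastic):
        for name in ("cum_dsb_generated", "cum_synthesized",
                     "cum_dissynthesized", "cum_rp_produced",
                     "cum_rp_degraded"):
            series = run_8gy_stochastic.series(name)
            assert np.all(np.diff(series) >= 0.0)


class TestStability:
    def test_non_increasing_and_bounded(self, run_8gy_stochastic):
        s = np.array(run_8gy_stochastic.series("stability"))
        assert np.all(np.diff(s) <= 0.0)
        assert np.all(s >= 0.0)
        assert np.all(s <= run_8gy_stochastic.params.s0)

    def test_collapse_time_non_increasing_with_dose(self, params):
        halves = []
        for dose in (10.0, 15.0, 20.0):
            res = run(RunSpec(profile=DoseProfile.constant(dose, 2500),
                              params=params, mode=MEAN_FIELD))
            t_half = first_below(res.series("stability"), 0.5 * params.s0)
            assert t_half is not None
            halves.append(t_half)
        assert halves == sorted(halves, reverse=True)


class TestStochasticMeanFieldConsistency:
    def test_ensemble_mean_matches_mean_field(self, params):
        steps, n_traj = 40, 60
        profile = DoseProfile.constant(8.0, steps)
        mf = np.array(run(RunSpec(profile=profile, params=params,
                                  mode=MEAN_FIELD)).series("dsb"))
        trajs = np.array([
            run(RunSpec(profile=profile, params=params, seed=1000 + s)).series("dsb")
            for s in range(n_traj)])
        mean = trajs.mean(axis=0)
        se = trajs.std(axis=0, ddof=1) / np.sqrt(n_traj)
        z = np.abs(mean - mf)[1:] / se[1:]
        assert z.max() < 3.0


class TestQualitativeShapes:
    """Reference-run shapes at constant 8 Gy (mean-field)."""

    def test_intact_dsb_plateau_then_late_rise(self, run_8gy_meanfield):
        dsb = np.array(run_8gy_meanfield.series("dsb_fast")) \
            + np.array(run_8gy_meanfield.series("dsb_slow"))
        plateau = dsb[500:1200]
        # dynamic equilibrium mid-run, steep rise late in the run
        assert plateau.max() < 2.0 * plateau.min()
        assert dsb[-1] > 10.0 * plateau.mean()

    def test_mrna_single_peak_then_collapse(self, run_8gy_meanfield):
        mrna = np.array(run_8gy_meanfield.series("mrna"))
        peak = int(mrna.argmax())
        assert 0 < peak < 500
        assert np.all(np.diff(mrna[peak:]) <= 1e-12)  # monotone decay after peak
        assert mrna[-1] < 0.05 * mrna[peak]

    def test_rp_rises_then_collapses(self, run_8gy_meanfield):
        rp = np.array(run_8gy_meanfield.series("rp"))
        peak = int(rp.argmax())
        assert 0 < peak < 2000
        assert rp[-1] < 0.05 * rp[peak]
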