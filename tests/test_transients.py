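"""Stopped-flow fitting: global multi-exponential, phase counting, k_obs."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from recbcd_kinetics import (
    ExperimentalCondition,
    ExponentialFitResult,
    FitError,
    KobsCurve,
    StoppedFlowTrace,
    fit_kobs_hyperbola,
    global_fit_transients,
    multi_exp_model,
    phase_count_test,
)
from recbcd_kinetics.synthetic import GroundTruth, gen_transients


def biexp_trace(t, conc, A1, k1, A2, k2, alpha=0.002, beta=0.1):
    return alpha * conc + beta + A1 * (1 - np.exp(-k1 * t)) + A2 * (1 - np.exp(-k2 * t))


class TestMultiExpModel:
    def test_initial_value_is_baseline(self):
        r = ExponentialFitResult(0.01, 0.2, np.array([1.0]), np.array([5.0]), np.array([0.0]))
        assert multi_exp_model(0.0, 30.0, r) == pytest.approx(0.01 * 30 + 0.2)

    def test_half_life(self):
        r = ExponentialFitResult(0.0, 0.0, np.array([1.0]), np.array([1.0]), np.array([0.0]))
        assert multi_exp_model(np.log(2.0), 0.0, r) == pytest.approx(0.5)

    def test_asymptote(self):
        r = ExponentialFitResult(0.0, 0.3, np.array([1.0, 0.5]), np.array([50.0, 5.0]), np.zeros(2))
        assert multi_exp_model(1e3, 0.0, r) == pytest.approx(1.8)


class TestGlobalFit:
    def test_noiseless_round_trip(self):
        t = np.linspace(0, 0.05, 400)
        design = [(20.0, (0.5, 300.0, 0.3, 40.0)), (60.0, (0.9, 500.0, 0.5, 60.0)), (100.0, (1.2, 700.0, 0.7, 80.0))]
        traces = [StoppedFlowTrace(t, biexp_trace(t, c, *ps), c) for c, ps in design]
        results = global_fit_transients(traces, n_phases=2)
        for res, (_, (A1, k1, A2, k2)) in zip(results, design):
            assert res.rates[0] == pytest.approx(k1, rel=1e-3)
            assert res.rates[1] == pytest.approx(k2, rel=1e-3)
            assert res.baseline_slope == pytest.approx(0.002, rel=1e-6)
            assert res.baseline_intercept == pytest.approx(0.1, rel=1e-6)

    def test_fast_slow_ordering_invariant(self, rng):
        t = np.linspace(0, 0.1, 300)
        traces = [
            StoppedFlowTrace(t, biexp_trace(t, c, 0.5, 30.0, 0.8, 400.0) + 0.002 * rng.standard_normal(len(t)), c)
            for c in (20.0, 80.0)
        ]
        for res in global_fit_transients(traces, n_phases=2):
            assert res.rates[0] > res.rates[1]

    def test_dead_time_points_are_masked(self):
        t = np.linspace(0, 0.05, 400)
        y = biexp_trace(t, 50.0, 1.0, 200.0, 0.4, 30.0)
        corrupted = y.copy()
        corrupted[t < 0.001] = 99.0  # garbage inside the dead time
        traces = [
            StoppedFlowTrace(t, corrupted, 50.0, dead_time=0.001),
            StoppedFlowTrace(t, biexp_trace(t, 100.0, 1.2, 250.0, 0.5, 35.0), 100.0, dead_time=0.001),
        ]
        res = global_fit_transients(traces, n_phases=2)
        assert res[0].rates[0] == pytest.approx(200.0, rel=1e-3)

    def test_all_points_inside_dead_time_rejected(self):
        t = np.linspace(0, 0.0009, 50)
        traces = [
            StoppedFlowTrace(t, np.ones(50), 10.0, dead_time=0.001),
            StoppedFlowTrace(t, np.ones(50), 50.0, dead_time=0.001),
        ]
        with pytest.raises(FitError):
            global_fit_transients(traces)

    def test_needs_two_distinct_concentrations(self):
        t = np.linspace(0, 0.05, 100)
        traces = [StoppedFlowTrace(t, biexp_trace(t, 50.0, 1, 100, 0.5, 10), 50.0) for _ in range(2)]
        with pytest.raises(FitError):
            global_fit_transients(traces)


class TestPhaseCount:
    def test_single_exponential_classified_single(self, rng):
        t = np.linspace(0, 0.1, 500)
        hits = 0
        for _ in range(20):
            y = 1.0 * (1 - np.exp(-100.0 * t)) + 0.01 * rng.standard_normal(len(t))
            n, _ = phase_count_test(StoppedFlowTrace(t, y, 50.0), noise_sd=0.01)
            hits += n == 1
        assert hits >= 19

    def test_double_exponential_classified_double(self, rng):
        t = np.linspace(0, 0.15, 600)
        hits = 0
        for _ in range(20):
            y = 0.6 * (1 - np.exp(-300.0 * t)) + 0.6 * (1 - np.exp(-30.0 * t))
            y = y + 0.012 * rng.standard_normal(len(t))
            n, _ = phase_count_test(StoppedFlowTrace(t, y, 50.0), noise_sd=0.012)
            hits += n == 2
        assert hits >= 19

    def test_constant_trace_single_phase_zero_amplitude(self):
        t = np.linspace(0, 0.1, 200)
        n, diag = phase_count_test(StoppedFlowTrace(t, np.full(200, 0.7), 50.0))
        assert n == 1
        assert diag.get("constant")

    def test_blocked_auxiliary_sites_give_single_phase(self, truth):
        # no auxiliary binding: the simulated mixing trace is one-phase
        blocked = GroundTruth(
            params=truth.params.replace(kw_on_intercept=0.0, kw_on_slope_ado=0.0),
            seed=truth.seed,
        )
        traces = gen_transients(blocked, concentrations=(60.0,), t_max=0.05, seed=3)
        n, _ = phase_count_test(traces[0])
        assert n == 1


class TestKobsHyperbola:
    CONC = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])

    def test_exact_recovery_with_offset(self):
        kobs = 5.0 + 100.0 * self.CONC / (20.0 + self.CONC)
        kmax, khalf, off = fit_kobs_hyperbola(KobsCurve(self.CONC, kobs), with_offset=True)
        assert kmax == pytest.approx(100.0, rel=1e-6)
        assert khalf == pytest.approx(20.0, rel=1e-6)
        assert off == pytest.approx(5.0, rel=1e-5)

    def test_half_saturation_point(self):
        kobs = 100.0 * self.CONC / (20.0 + self.CONC)
        kmax, khalf, off = fit_kobs_hyperbola(KobsCurve(self.CONC, kobs))
        assert kmax / 2 == pytest.approx(100.0 * khalf / (khalf + khalf), rel=1e-6)
        assert off == 0.0

    def test_fitted_curve_monotone(self):
        kobs = 100.0 * self.CONC / (20.0 + self.CONC)
        kmax, khalf, off = fit_kobs_hyperbola(KobsCurve(self.CONC, kobs))
        grid = np.linspace(1, 200, 50)
        pred = off + kmax * grid / (khalf + grid)
        assert np.all(np.diff(pred) > 0)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_kobs_hyperbola(KobsCurve(self.CONC[:3], np.ones(3)))


class TestPhasePathwayAttribution:
    def test_recovered_phases_track_their_pathways(self, slow_params):
        """In a slow, decoupled regime the fitted fast phase follows the
        catalytic binding rate and the slow phase the auxiliary pathway
        (rank correlation across a parameter sweep)."""
        T = 80.0
        t = np.linspace(0, 0.5, 800)
        fast_in, fast_out, slow_in, slow_out = [], [], [], []
        for factor in (0.5, 0.8, 1.2, 1.8, 2.6, 3.5):
            for which in ("cat", "aux"):
                if which == "cat":
                    p = slow_params.replace(ks_on=slow_params.ks_on * factor)
                else:
                    p = slow_params.replace(kw_on_intercept=slow_params.kw_on_intercept * factor)
                truth = GroundTruth(params=p, transient_sd_frac=0.002)
                traces = gen_transients(truth, concentrations=(T, 40.0), t_max=0.5, n_points=800, seed=11)
                res = global_fit_transients(traces, n_phases=2)
                if which == "cat":
                    fast_in.append(p.ks_on * T)
                    fast_out.append(res[0].rates[0])
                else:
                    slow_in.append(p.kw_on_intercept * T)
                    slow_out.append(res[0].rates[1])
        assert spearmanr(fast_in, fast_out).statistic > 0.9
        assert spearmanr(slow_in, slow_out).statistic > 0.9
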