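"""Generators: determinism, zero-noise exactness, and closed-loop recovery."""

import numpy as np
import pytest

from recbcd_kinetics import ExperimentalCondition, chung_kennedy, detect_pauses, extension_to_contour, model_isotherm, segment_velocities
from recbcd_kinetics.equilibrium import dialysis_bound_count
from recbcd_kinetics.synthetic import (
    DEFAULT_ISOTHERM_CONCS,
    GroundTruth,
    gen_dataset,
    gen_dialysis,
    gen_isotherm,
    gen_kobs_curve,
    gen_transients,
    gen_tweezers_trace,
    gen_unwinding,
)
from recbcd_kinetics.unwinding import fit_lag_trace, unwinding_rate


@pytest.fixture(scope="module")
def quiet_truth(truth):
    """Zero-noise variant of the session truth."""
    return GroundTruth(
        params=truth.params,
        isotherm_sd=0.0,
        transient_sd_frac=0.0,
        fa_sd=0.0,
        tweezers_ext_sd_nm=0.0,
        kobs_sd_frac=0.0,
        rate_sd_frac=0.0,
        dialysis_sd_frac=0.0,
    )


class TestDeterminism:
    def test_isotherm_reproducible(self, truth):
        a = gen_isotherm(truth, seed=7)
        b = gen_isotherm(truth, seed=7)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_different_seeds_differ(self, truth):
        a = gen_isotherm(truth, seed=7)
        b = gen_isotherm(truth, seed=8)
        assert not np.array_equal(a.signal, b.signal)

    def test_tweezers_reproducible(self, truth):
        a, _ = gen_tweezers_trace(truth, duration_s=0.5, seed=3)
        b, _ = gen_tweezers_trace(truth, duration_s=0.5, seed=3)
        np.testing.assert_array_equal(a.extension, b.extension)

    def test_dataset_reproducible(self, truth):
        ds1, _ = gen_dataset(truth, seed=5)
        ds2, _ = gen_dataset(truth, seed=5)
        np.testing.assert_array_equal(ds1.isotherms[0][0].signal, ds2.isotherms[0][0].signal)
        np.testing.assert_array_equal(ds1.kobs_curves[0].k_obs, ds2.kobs_curves[0].k_obs)
        assert ds1.unwinding[0].rate == ds2.unwinding[0].rate


class TestZeroNoiseExactness:
    def test_isotherm_equals_forward_model(self, quiet_truth):
        iso = gen_isotherm(quiet_truth, seed=0)
        expected = model_isotherm(
            quiet_truth.params, iso.condition, iso.conc, quiet_truth.signal_weights
        )
        np.testing.assert_array_equal(iso.signal, expected)

    def test_default_design_spans_titration_range(self, truth):
        iso = gen_isotherm(truth, seed=0)
        assert len(iso.conc) == 20
        assert iso.conc[-1] == pytest.approx(550.0)
        np.testing.assert_allclose(iso.conc, DEFAULT_ISOTHERM_CONCS)

    def test_transients_scale_with_observable(self, quiet_truth):
        tr = gen_transients(quiet_truth, concentrations=(60.0,), t_max=0.02, n_points=100, seed=0)[0]
        assert tr.signal[0] == pytest.approx(
            quiet_truth.baseline_alpha * 60.0 + quiet_truth.baseline_beta
        )
        assert np.all(np.diff(tr.signal) >= -1e-9)

    def test_dialysis_mass_conservation_exact(self, quiet_truth):
        m = gen_dialysis(quiet_truth, 45.0, 1000.0, seed=0)
        n = dialysis_bound_count(m)
        # the generated free/bound split must satisfy the conservation law
        assert m.ligand_initial == pytest.approx(2 * m.ligand_final + n * 45.0, rel=1e-10)

    def test_dialysis_no_binding_limit(self, quiet_truth):
        apo = GroundTruth(
            params=quiet_truth.params.replace(
                ks_on=0.0, kw_on_intercept=0.0, kw_on_slope_ado=0.0
            ),
            dialysis_sd_frac=0.0,
        )
        m = gen_dialysis(apo, 45.0, 1000.0, seed=0)
        assert m.ligand_final == pytest.approx(500.0)

    def test_dialysis_high_regime_stoichiometry(self, truth):
        # saturating regime: ~4 of the 6 sites occupied at equilibrium
        m = gen_dialysis(truth, 45.0, 1000.0, seed=2)
        assert 3.5 <= dialysis_bound_count(m) <= 4.5

    def test_unwinding_lag_ordering(self, quiet_truth):
        traces = gen_unwinding(quiet_truth, seed=0)
        lags = [fit_lag_trace(tr).t_lag for tr in traces]
        assert lags[0] < lags[1] < lags[2]

    def test_tweezers_zero_noise_velocity_exact(self, quiet_truth):
        trace, _ = gen_tweezers_trace(quiet_truth, duration_s=1.2, seed=0, pause_schedule=[])
        contour = extension_to_contour(trace)
        v = segment_velocities(contour)
        assert np.allclose(v, quiet_truth.sm_velocity, rtol=1e-6)


class TestClosedLoops:
    def test_unwinding_round_trip(self, quiet_truth):
        cond = ExperimentalCondition(ligand_conc=350.0)
        traces = gen_unwinding(quiet_truth, condition=cond, seed=0, rate_bp_s=800.0)
        lags = [(tr.length_bp, fit_lag_trace(tr).t_lag) for tr in traces]
        res = unwinding_rate(lags)
        assert res.rate == pytest.approx(800.0, rel=1e-3)
        assert res.intercept == pytest.approx(quiet_truth.unwind_intercept, rel=1e-3)

    def test_scheduled_pauses_recovered(self, truth):
        trace, schedule = gen_tweezers_trace(truth, duration_s=3.0, seed=4)
        contour = extension_to_contour(trace)
        contour.contour = chung_kennedy(contour.contour)
        pauses = detect_pauses(contour)
        assert len(pauses) == len(schedule)
        for p, (t0, t1, pos) in zip(pauses, schedule):
            assert p.position == pytest.approx(pos, abs=5.0)
            assert p.duration == pytest.approx(t1 - t0, abs=0.15)

    def test_kobs_curve_matches_reduction(self, quiet_truth):
        from recbcd_kinetics import biexp_rates

        curve = gen_kobs_curve(quiet_truth, concentrations=(300.0, 400.0, 500.0), seed=0)
        for c, k in zip(curve.conc, curve.k_obs):
            kf, _ = biexp_rates(quiet_truth.params, ExperimentalCondition(ligand_conc=c))
            assert k == pytest.approx(kf, rel=1e-9)


class TestDatasetBundle:
    def test_record_counts_match_design(self, truth):
        ds, _ = gen_dataset(truth, seed=1)
        assert len(ds.isotherms) == 5
        assert len(ds.dialysis) == 2
        assert len(ds.kobs_curves) == 4  # fast+slow at two salt levels
        assert len(ds.unwinding) == 16

    def test_manifest_round_trip_lossless(self, truth, tmp_path):
        from recbcd_kinetics.io import load_dataset, write_dataset

        ds, _ = gen_dataset(truth, seed=1)
        write_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        assert back.n_records() == ds.n_records()
        np.testing.assert_allclose(back.isotherms[0][0].signal, ds.isotherms[0][0].signal)
        np.testing.assert_allclose(back.kobs_curves[2].k_obs, ds.kobs_curves[2].k_obs)
        assert back.unwinding[5].rate == pytest.approx(ds.unwinding[5].rate)
        assert back.unwinding[5].condition == ds.unwinding[5].condition
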