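"""State space, binding polynomial, generator and dynamics of the scheme."""

from fractions import Fraction as F

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recbcd_kinetics import (
    ExperimentalCondition,
    InvalidArgumentError,
    ModelParameters,
    biexp_rates,
    binding_polynomial,
    build_generator,
    enumerate_states,
    mean_occupancy,
    resolve_rates,
    simulate_binding_kinetics,
    simulate_unwinding,
    stationary_distribution,
    steady_unwinding_rate,
)
from recbcd_kinetics.model_core import EffectiveRates, polynomial_coefficients


def brute_force_coefficients(Ks, Kw, a, n_weak, n_cat):
    """Independent oracle: sum the state weights Ks^c·a^max(w-1,0)·Kw^w."""
    coeffs = [0 * Ks] * (n_weak + n_cat + 1)
    for w in range(n_weak + 1):
        for c in range(n_cat + 1):
            coeffs[w + c] = coeffs[w + c] + Ks**c * a ** max(w - 1, 0) * Kw**w
    return coeffs


class TestStateSpace:
    @pytest.mark.parametrize(
        "n_weak, n_cat, expected_size",
        [(4, 2, 15), (0, 2, 3), (1, 1, 4)],
    )
    def test_size(self, n_weak, n_cat, expected_size):
        assert len(enumerate_states(n_weak, n_cat)) == expected_size

    def test_lexicographic_order_and_bijection(self):
        space = enumerate_states(1, 1)
        assert list(space.states) == [(0, 0), (0, 1), (1, 0), (1, 1)]
        for i, (w, c) in enumerate(space.states):
            assert space.index(w, c) == i

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            enumerate_states(-1, 2)
        with pytest.raises(InvalidArgumentError):
            enumerate_states(2, 0)


class TestResolveRates:
    def test_zero_adenosine_passthrough(self):
        p = ModelParameters()
        r = resolve_rates(p, ExperimentalCondition(nacl=0.0, adenosine=0.0))
        assert r.kw_on == p.kw_on_intercept
        assert r.kw_off == p.kw_off_intercept

    def test_clamped_at_zero(self):
        p = ModelParameters(kw_on_intercept=2.0, kw_on_slope_ado=-1.0)
        r = resolve_rates(p, ExperimentalCondition(adenosine=5.0))
        assert r.kw_on == 0.0

    def test_linear_evaluation(self):
        p = ModelParameters(ktr_fwd_intercept=10.0, ktr_fwd_slope_nacl=-0.02)
        r = resolve_rates(p, ExperimentalCondition(nacl=300.0))
        assert r.ktr_fwd == pytest.approx(4.0)


class TestBindingPolynomial:
    def test_empty_lattice(self):
        assert binding_polynomial(2.0, 3.0, 4.0, 0.0) == 1.0

    def test_catalytic_only(self):
        assert binding_polynomial(1.0, 0.0, 1.0, 1.0) == pytest.approx(3.0)

    def test_unit_product(self):
        assert binding_polynomial(1.0, 1.0, 1.0, 1.0, form="product") == pytest.approx(15.0)

    @pytest.mark.parametrize("n_weak", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n_cat", [1, 2])
    def test_exact_against_brute_force_enumeration(self, n_weak, n_cat):
        # exact rational arithmetic: the product of chain weights must equal
        # the brute-force sum over all occupancy states
        Ks, Kw, a = F(1, 3), F(2, 7), F(5, 2)
        assert polynomial_coefficients(Ks, Kw, a, n_weak, n_cat) == (
            brute_force_coefficients(Ks, Kw, a, n_weak, n_cat)
        )

    def test_printed_variant_differs_in_exactly_two_terms(self):
        Ks, Kw, a = F(1, 3), F(2, 7), F(5, 2)
        prod = polynomial_coefficients(Ks, Kw, a, 4, 2, form="product")
        printed = polynomial_coefficients(Ks, Kw, a, 4, 2, form="as_printed")
        diff = [i for i, (x, y) in enumerate(zip(prod, printed)) if x != y]
        assert diff == [4, 5]

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            binding_polynomial(-1.0, 1.0, 1.0, 1.0)


class TestMeanOccupancy:
    def test_zero_at_zero(self):
        assert mean_occupancy(1.0, 1.0, 1.0, 0.0) == 0.0

    def test_catalytic_only_value(self):
        # (1·1 + 2·1)/3 with Ks = 1, T = 1
        assert mean_occupancy(1.0, 0.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_saturates_at_total_sites(self):
        assert mean_occupancy(1.0, 1.0, 2.0, 1e9) == pytest.approx(6.0, abs=1e-3)

    @given(
        Ks=st.floats(0.01, 10.0),
        Kw=st.floats(0.001, 1.0),
        a=st.floats(0.5, 50.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, Ks, Kw, a):
        T = np.geomspace(1e-3, 1e6, 60)
        occ = mean_occupancy(Ks, Kw, a, T)
        assert np.all(np.diff(occ) >= -1e-10)
        assert np.all(occ <= 6.0 + 1e-9)


class TestGenerator:
    def test_all_zero_rates(self):
        space = enumerate_states(2, 1)
        rates = EffectiveRates(0, 0, 0, 0, 0, 0, coop_a=2.0, vmax=0)
        assert np.all(build_generator(space, rates, 10.0) == 0)

    def test_catalytic_on_rate_entry(self):
        space = enumerate_states(1, 1)
        rates = EffectiveRates(2.0, 0, 0, 0, 0, 0, coop_a=1.0, vmax=0)
        Q = build_generator(space, rates, 5.0)
        assert Q[space.index(0, 0), space.index(0, 1)] == pytest.approx(10.0)

    def test_rows_sum_to_zero(self, rng):
        space = enumerate_states(4, 2)
        for _ in range(5):
            vals = rng.uniform(0.1, 100.0, size=6)
            rates = EffectiveRates(*vals, coop_a=rng.uniform(1, 30), vmax=0)
            Q = build_generator(space, rates, rng.uniform(1, 500))
            assert np.abs(Q.sum(axis=1)).max() < 1e-12 * max(np.abs(Q).max(), 1)

    def test_cooperativity_on_second_binding(self):
        space = enumerate_states(2, 1)
        rates = EffectiveRates(0, 0, kw_on=1.0, kw_off=0, ktr_fwd=0, ktr_rev=0, coop_a=7.0, vmax=0)
        Q = build_generator(space, rates, 1.0)
        assert Q[space.index(0, 0), space.index(1, 0)] == pytest.approx(1.0)
        assert Q[space.index(1, 0), space.index(2, 0)] == pytest.approx(7.0)


class TestDynamics:
    def test_no_ligand_no_binding(self, params):
        traj = simulate_binding_kinetics(params, ExperimentalCondition(ligand_conc=0.0), 0.01, 50)
        assert np.abs(traj.observable).max() < 1e-12

    def test_probability_conserved(self, params):
        traj = simulate_binding_kinetics(
            params, ExperimentalCondition(ligand_conc=200.0), 0.05, 100
        )
        assert np.abs(traj.probabilities.sum(axis=1) - 1.0).max() < 1e-8
        assert np.all(traj.observable >= -1e-10)
        assert np.all(traj.observable <= 6.0 + 1e-8)

    def test_stationary_matches_binding_polynomial(self, params):
        # with cycle-consistent transfer rates the long-time ODE occupancy
        # must equal the equilibrium value T·Ψ'(T)/Ψ(T)
        cond = ExperimentalCondition(ligand_conc=200.0)
        traj = simulate_binding_kinetics(params, cond, 0.1, 80, cycle_consistent=True)
        r = resolve_rates(params, cond)
        expected = float(mean_occupancy(r.Ks, r.Kw, r.coop_a, 200.0))
        assert traj.observable[-1] == pytest.approx(expected, abs=1e-4)

    def test_stationary_distribution_absorbing(self):
        space = enumerate_states(1, 1)
        rates = EffectiveRates(0.0, 3.0, 0.0, 2.0, 0.0, 0.0, coop_a=1.0, vmax=0)
        pi = stationary_distribution(build_generator(space, rates, 10.0))
        assert pi[space.index(0, 0)] == pytest.approx(1.0)

    def test_stationary_distribution_matches_boltzmann_weights(self, params):
        cond = ExperimentalCondition(ligand_conc=150.0)
        space = enumerate_states(4, 2)
        r = resolve_rates(params, cond)
        Q = build_generator(space, r, 150.0, cycle_consistent=True)
        pi = stationary_distribution(Q)
        weights = np.array(
            [
                (r.Ks * 150.0) ** c * r.coop_a ** max(w - 1, 0) * (r.Kw * 150.0) ** w
                for w, c in space.states
            ]
        )
        np.testing.assert_allclose(pi, weights / weights.sum(), atol=1e-9)

    def test_stationary_agrees_with_long_time_ode(self, params):
        cond = ExperimentalCondition(ligand_conc=300.0)
        space = enumerate_states(4, 2)
        Q = build_generator(space, resolve_rates(params, cond), 300.0)
        pi = stationary_distribution(Q)
        traj = simulate_binding_kinetics(params, cond, 0.2, 60)
        np.testing.assert_allclose(pi, traj.probabilities[-1], atol=1e-6)


class TestUnwinding:
    def test_no_catalysis_no_unwinding(self, params):
        p = params.replace(vmax=0.0)
        _, rate = simulate_unwinding(p, ExperimentalCondition(ligand_conc=350.0), t_max=1.0, n_points=60)
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_rate_nondecreasing_in_atp(self, params):
        rates = [
            steady_unwinding_rate(params, ExperimentalCondition(ligand_conc=T))
            for T in (25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
        ]
        assert np.all(np.diff(rates) > 0)

    def test_direct_pathway_is_michaelian(self, params):
        # without auxiliary sites and transfer, the rate-vs-ATP curve is a
        # single hyperbola to high precision (the sequential two-site chain
        # deviates from an exact hyperbola only in the third digit) and the
        # best Hill fit has unit cooperativity
        import lmfit

        p = params.replace(
            kw_on_intercept=0.0, kw_on_slope_ado=0.0,
            ktr_fwd_intercept=0.0, ktr_fwd_slope_nacl=0.0, ktr_rev=0.0,
        )
        T = np.geomspace(10.0, 4000.0, 15)
        v = np.array([steady_unwinding_rate(p, ExperimentalCondition(ligand_conc=t)) for t in T])
        pars = lmfit.Parameters()
        pars.add("vm", value=v.max(), min=0)
        pars.add("K", value=300.0, min=1e-6)
        out = lmfit.minimize(lambda q: q["vm"].value * T / (q["K"].value + T) - v, pars)
        r2 = 1 - np.sum(out.residual**2) / np.sum((v - v.mean()) ** 2)
        assert r2 > 0.995
        pars.add("n", value=1.0, min=0.2, max=5.0)
        out_h = lmfit.minimize(
            lambda q: q["vm"].value / (1 + (q["K"].value / T) ** q["n"].value) - v, pars
        )
        # the two-motor chain shows only mild apparent cooperativity
        assert 0.8 < out_h.params["n"].value < 1.3

    def test_ode_trace_matches_stationary_rate(self, params):
        cond = ExperimentalCondition(ligand_conc=350.0)
        _, rate_ode = simulate_unwinding(params, cond, t_max=5.0, n_points=100)
        rate_ss = steady_unwinding_rate(params, cond)
        assert rate_ode == pytest.approx(rate_ss, rel=1e-3)

    def test_trace_columns_roundtrip(self, params):
        traj, _ = simulate_unwinding(params, ExperimentalCondition(ligand_conc=100.0), t_max=0.5, n_points=20)
        df = traj.to_frame()
        assert "time_s" in df and "w0c0" in df and "observable" in df and "hydrolysis_atp" in df
        assert len(df) == 20


class TestBiexpReduction:
    def test_single_site_returns_exact_rate(self):
        # one catalytic site, no auxiliary sites: relaxation is a single
        # exponential with rate ks_on·T + ks_off
        p = ModelParameters(
            ks_on=2.0, ks_off=30.0, n_weak_sites=0, n_cat_sites=1,
            kw_on_intercept=0.0, kw_on_slope_ado=0.0, ktr_fwd_intercept=0.0,
            ktr_fwd_slope_nacl=0.0, ktr_rev=0.0,
        )
        kf, ks_ = biexp_rates(p, ExperimentalCondition(ligand_conc=50.0))
        assert kf == pytest.approx(130.0, rel=1e-9)

    def test_exact_on_pure_two_mode_spectrum(self):
        # two catalytic sites, nothing else: the relaxation is genuinely
        # biexponential and the reduction must return its two rates exactly
        p = ModelParameters(
            ks_on=2.0, ks_off=50.0, n_weak_sites=0, n_cat_sites=2,
            kw_on_intercept=0.0, kw_on_slope_ado=0.0, ktr_fwd_intercept=0.0,
            ktr_fwd_slope_nacl=0.0, ktr_rev=0.0,
        )
        kf, ks_ = biexp_rates(p, ExperimentalCondition(ligand_conc=100.0))
        assert kf == pytest.approx(350.0, rel=1e-6)
        assert ks_ == pytest.approx(150.0, rel=1e-6)

    def test_decoupled_pathways_give_both_rates(self, slow_params):
        # transfer off: catalytic and auxiliary relaxations are independent,
        # and the two reported rates bracket the two pathways
        cond = ExperimentalCondition(ligand_conc=100.0)
        kf, ks_ = biexp_rates(slow_params, cond)
        assert kf > 10 * ks_ > 0
        assert kf == pytest.approx(250.0, rel=0.1)  # ks_on·T + ks_off scale

    def test_consistent_with_simulated_trajectory(self, params):
        # dual route: the closed-form biexponential reduction must agree
        # with actually fitting two exponentials to the simulated observable
        from recbcd_kinetics.transients import StoppedFlowTrace, _fit_single_trace

        cond = ExperimentalCondition(ligand_conc=350.0)
        traj = simulate_binding_kinetics(params, cond, 0.05, 800)
        ks, amps, b, rss = _fit_single_trace(traj.time[1:], traj.observable[1:], 2)
        kf, ksl = biexp_rates(params, cond)
        assert kf == pytest.approx(ks[0], rel=0.25)
        assert ksl == pytest.approx(ks[1], rel=0.1)
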