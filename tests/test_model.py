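"""Three-compartment ODE solution: back-end agreement, dissipation, asymptotics."""

import numpy as np
import pytest

from eprkit import (
    DOXIL_PK,
    DOXORUBICIN_PK,
    ModelState,
    RateConstants,
    SimulationGrid,
    asymptotic_tumor_fraction,
    blood_amount,
    build_rate_matrix,
    derive_rate_constants,
    mass_balance_residual,
    simulate_closed_form,
    simulate_numeric,
)


class TestRateMatrix:
    def test_doxil_matrix_entries(self):
        """Substituting the published rate constants with no tumor exchange."""
        k = RateConstants(k_p=0.0956, k_d=0.198, k_10=0.0228, k_el=0.0228)
        M = build_rate_matrix(k)
        expected = np.array(
            [
                [-0.1184, 0.198, 0.0],
                [0.0956, -0.198, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_zero_rates_give_zero_matrix(self):
        k = RateConstants(k_p=0, k_d=0, k_10=0, k_el=0)
        assert not build_rate_matrix(k).any()

    @pytest.mark.parametrize("epr_ratio,back_ratio", [(0, 0), (0.1, 0), (1e-3, 100)])
    def test_column_sums_encode_dissipation(self, doxil_rates, epr_ratio, back_ratio):
        """Summing the rate equations must leave only -k_el N_bl."""
        k = doxil_rates.with_epr(epr_ratio, back_ratio)
        M = build_rate_matrix(k)
        np.testing.assert_allclose(M.sum(axis=0), [-k.k_el, 0.0, 0.0], atol=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_p"):
            RateConstants(k_p=-0.1, k_d=0.2, k_10=0.1, k_el=0.1)


class TestGrid:
    def test_geometric_grid_starts_at_zero_and_is_increasing(self):
        t = SimulationGrid(t_end=240.0).times()
        assert t[0] == 0.0
        assert t.size == 400
        assert np.all(np.diff(t) > 0)
        assert t[-1] == pytest.approx(240.0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            SimulationGrid(t_end=-1.0)
        with pytest.raises(ValueError):
            SimulationGrid(t_end=1.0, n_points=1)
        with pytest.raises(ValueError):
            SimulationGrid(t_end=1.0, spacing="geometric", t_min_geometric=2.0)


class TestClosedForm:
    def test_no_tumor_exchange_reproduces_biexponential(self, doxil_rates, doxil_init, doxil_grid):
        """With k_epr = k_b = 0 the simulated blood curve is the fitted curve."""
        tc = simulate_closed_form(doxil_rates, doxil_init, doxil_grid)
        ref = blood_amount(DOXIL_PK, tc.t)
        np.testing.assert_allclose(tc.n_bl, ref, rtol=1e-6)

    def test_all_rates_zero_gives_constant_trajectory(self):
        k = RateConstants(k_p=0, k_d=0, k_10=0, k_el=0)
        tc = simulate_closed_form(k, ModelState(t=0, N_bl=10.0, N_p=2.0, N_t=1.0), SimulationGrid(t_end=100))
        np.testing.assert_allclose(tc.states, np.tile([10.0, 2.0, 1.0], (tc.t.size, 1)), atol=1e-12)

    def test_closed_two_compartment_system_conserves_mass(self):
        k = RateConstants(k_p=0.3, k_d=0.7, k_10=0.0, k_el=0.0)
        tc = simulate_closed_form(k, ModelState(t=0, N_bl=5.0), SimulationGrid(t_end=50))
        np.testing.assert_allclose(tc.n_bl + tc.n_p, 5.0, rtol=1e-9)

    def test_first_state_is_the_initial_condition(self, doxil_rates, doxil_init, doxil_grid):
        tc = simulate_closed_form(doxil_rates, doxil_init, doxil_grid)
        np.testing.assert_array_equal(tc.states[0], doxil_init.as_vector())

    def test_repeated_eigenvalues_fall_back_to_expm(self):
        """A defective rate matrix must not crash a sweep."""
        lam = 0.2
        k = RateConstants(k_p=0.0, k_d=lam, k_10=lam, k_el=lam)  # eigenvalues {0, -lam, -lam}
        tc = simulate_closed_form(k, ModelState(t=0, N_bl=1.0), SimulationGrid(t_end=30))
        assert tc.provenance["solver"] == "closed_form_expm"
        np.testing.assert_allclose(tc.n_bl, np.exp(-lam * tc.t), rtol=1e-9)


class TestNumericBackend:
    @pytest.mark.parametrize(
        "pk,epr_ratio,back_ratio,t_end",
        [
            (DOXIL_PK, 1e-3, 0.0, 240.0),
            (DOXIL_PK, 1e-3, 100.0, 240.0),
            (DOXORUBICIN_PK, 1e-3, 0.0, 48.0),  # fast phase alpha = 11.6/h
        ],
        ids=["doxil", "doxil-backflow", "doxorubicin-stiff"],
    )
    def test_agrees_with_closed_form(self, pk, epr_ratio, back_ratio, t_end):
        k = derive_rate_constants(pk).with_epr(epr_ratio, back_ratio)
        init = ModelState(t=0, N_bl=pk.initial_amount)
        grid = SimulationGrid(t_end=t_end)
        ref = simulate_closed_form(k, init, grid)
        num = simulate_numeric(k, init, grid)
        scale = np.abs(ref.states).max(axis=1, keepdims=True)
        np.testing.assert_allclose(num.states, ref.states, rtol=1e-6, atol=1e-6 * scale.max())

    def test_random_rate_sets_agree_across_backends(self):
        """Cross-backend agreement over rates spanning 1e-4..1e2 per hour."""
        rng = np.random.default_rng(42)
        grid = SimulationGrid(t_end=24.0, n_points=80)
        init = ModelState(t=0, N_bl=100.0)
        for _ in range(100):
            vals = 10.0 ** rng.uniform(-4, 2, size=5)
            k = RateConstants(k_p=vals[0], k_d=vals[1], k_10=vals[2] + vals[3],
                              k_el=vals[2], k_epr=vals[3], k_b=vals[4])
            ref = simulate_closed_form(k, init, grid)
            num = simulate_numeric(k, init, grid)
            np.testing.assert_allclose(num.states, ref.states, rtol=2e-6, atol=1e-4)

    def test_zero_initial_state_stays_zero(self, doxil_rates):
        tc = simulate_numeric(doxil_rates, ModelState(t=0, N_bl=0.0), SimulationGrid(t_end=10))
        assert not tc.states.any()

    def test_nonnegativity_for_random_nonnegative_inputs(self):
        rng = np.random.default_rng(7)
        grid = SimulationGrid(t_end=100.0, n_points=120)
        for _ in range(50):
            vals = 10.0 ** rng.uniform(-3, 1, size=5)
            k = RateConstants(k_p=vals[0], k_d=vals[1], k_10=vals[2] + vals[3],
                              k_el=vals[2], k_epr=vals[3], k_b=vals[4])
            init = ModelState(t=0, N_bl=rng.uniform(1, 100), N_p=rng.uniform(0, 10), N_t=rng.uniform(0, 10))
            tc = simulate_closed_form(k, init, grid)
            assert tc.states.min() >= 0.0


class TestMassBalance:
    def test_closed_form_residual_is_analytically_tiny(self, doxil_rates, doxil_init, doxil_grid):
        k = doxil_rates.with_epr(1e-2, 10.0)
        tc = simulate_closed_form(k, doxil_init, doxil_grid)
        res = mass_balance_residual(tc, k)
        tol = 1e-6 * doxil_init.N_bl * max(k.k_p, k.k_d, k.k_10, k.k_epr, k.k_b)
        assert np.abs(res).max() <= tol

    def test_conservative_system_keeps_total_constant(self):
        k = RateConstants(k_p=0.4, k_d=0.1, k_10=0.0, k_el=0.0, k_epr=0.05, k_b=0.02)
        tc = simulate_closed_form(k, ModelState(t=0, N_bl=50.0), SimulationGrid(t_end=200))
        total = tc.states.sum(axis=1)
        np.testing.assert_allclose(total, 50.0, rtol=1e-9)

    def test_eliminated_plus_retained_equals_initial(self, doxil_rates):
        """k_el * integral(N_bl) + amounts still in the system = N(0)."""
        k = doxil_rates.with_epr(1e-2, 0.0)
        grid = SimulationGrid(t_end=3000.0, n_points=4000)
        tc = simulate_closed_form(k, ModelState(t=0, N_bl=95.5), grid)
        eliminated = k.k_el * np.trapezoid(tc.n_bl, tc.t)
        assert eliminated + tc.states[-1].sum() == pytest.approx(95.5, rel=1e-4)

    def test_too_few_points_rejected(self, doxil_rates):
        tc = simulate_closed_form(doxil_rates, ModelState(t=0, N_bl=1.0), SimulationGrid(t_end=1.0, n_points=2))
        with pytest.raises(ValueError):
            mass_balance_residual(tc, doxil_rates)


class TestAsymptoticTumorFraction:
    @pytest.mark.parametrize(
        "epr_ratio,expected",
        [(0.1, 1 / 11), (0.0, 0.0), (1e-3, 1e-3 / (1 + 1e-3))],
    )
    def test_branching_probability(self, doxil_rates, epr_ratio, expected):
        k = doxil_rates.with_epr(epr_ratio)
        assert asymptotic_tumor_fraction(k) == pytest.approx(expected, abs=1e-15)

    def test_no_elimination_sends_everything_to_tumor(self):
        k = RateConstants(k_p=0.1, k_d=0.2, k_10=0.05, k_el=0.0, k_epr=0.05)
        assert asymptotic_tumor_fraction(k) == 1.0

    def test_simulation_converges_to_the_analytic_limit(self, doxil_rates):
        k = doxil_rates.with_epr(0.1)
        tc = simulate_closed_form(
            k, ModelState(t=0, N_bl=95.5), SimulationGrid(t_end=1e4, n_points=600)
        )
        assert tc.n_t[-1] / 95.5 == pytest.approx(asymptotic_tumor_fraction(k), abs=1e-4)

    def test_backflow_rejected(self, doxil_rates):
        with pytest.raises(ValueError, match="k_b"):
            asymptotic_tumor_fraction(doxil_rates.with_epr(0.1, 10.0))


class TestTumorKineticsShape:
    def test_monotone_uptake_without_backflow(self, doxil_rates, doxil_init, doxil_grid):
        tc = simulate_closed_form(doxil_rates.with_epr(1e-2), doxil_init, doxil_grid)
        assert np.all(np.diff(tc.n_t) >= -1e-12)

    def test_interior_maximum_with_strong_backflow(self, doxil_rates, doxil_init):
        """k_b/k_epr >= 10 drives a maximum followed by net loss from the tumor."""
        tc = simulate_closed_form(
            doxil_rates.with_epr(1e-3, 100.0), doxil_init, SimulationGrid(t_end=240.0)
        )
        i_max = np.argmax(tc.n_t)
        assert 0 < i_max < tc.t.size - 1
        assert tc.n_t[-1] < tc.n_t[i_max]

    def test_uptake_linear_in_k_epr_when_small(self, doxil_rates, doxil_init):
        """Log-log slope of N_t(fixed t) vs k_epr/k_el is 1 for ratios <= 1e-2."""
        grid = SimulationGrid(t_end=96.0)
        ratios = np.array([1e-2, 1e-3, 1e-4])
        n_t = [
            simulate_closed_form(doxil_rates.with_epr(r), doxil_init, grid).n_t[-1]
            for r in ratios
        ]
        slopes = np.diff(np.log(n_t)) / np.diff(np.log(ratios))
        np.testing.assert_allclose(slopes, 1.0, rtol=0.02)


class TestTimeCourseIO:
    def test_round_trip_preserves_12_significant_digits(self, doxil_rates, doxil_init, doxil_grid, tmp_path):
        tc = simulate_closed_form(doxil_rates.with_epr(1e-2), doxil_init, doxil_grid)
        path = tc.write(tmp_path / "traj.csv")
        back = type(tc).read(path)
        np.testing.assert_allclose(back.states, tc.states, rtol=1e-11)
        np.testing.assert_allclose(back.t, tc.t, rtol=1e-11)
        assert back.provenance["solver"] == tc.provenance["solver"]

    def test_decreasing_grid_rejected(self):
        from eprkit import TimeCourse

        with pytest.raises(ValueError, match="increasing"):
            TimeCourse(t=[0.0, 1.0, 1.0], states=np.zeros((3, 3)))
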