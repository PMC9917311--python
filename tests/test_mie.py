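"""Extinction analysis: spectral abscissa, Gershgorin screens, critical
curves, Kronecker factorization, steady states, continuum threshold."""

import numpy as np
import pytest
from scipy.linalg import eigvals
from scipy.optimize import brentq

from karyomie import (
    build_generator,
    build_space,
    constant_rates,
    sinusoidal_beta_kernel,
    tabulated_kernel,
)
from karyomie.mie import (
    ContinuumModel,
    aggregate_space,
    continuum_critical,
    critical_curve,
    critical_turnover,
    dominant_eigenvalue,
    gershgorin_conditions,
    homogeneous_critical_curve,
    multichromosome_critical,
    nearest_neighbor_generator,
    single_daughter_matrix,
    steady_state_proportions,
    table2_condition,
)


class TestDominantEigenvalue:
    def test_scalar_case(self):
        space = build_space(1, [1], [1])
        gen = build_generator(space, constant_rates(1.0, 0.5, 0.3))
        assert dominant_eigenvalue(gen) == pytest.approx(1.0 * (1 - 0.6) - 0.5)

    def test_diagonal_case(self):
        space = build_space(1, [1], [5])
        gen = build_generator(space, constant_rates(1.0, 0.4, 0.0))
        assert dominant_eigenvalue(gen) == pytest.approx(0.6)

    def test_random_metzler_matches_dense_oracle(self, rng):
        n = 30
        A = rng.random((n, n)) * 0.5
        np.fill_diagonal(A, rng.normal(-1.0, 0.5, n))
        expected = float(np.max(eigvals(A).real))
        assert dominant_eigenvalue(A) == pytest.approx(expected, abs=1e-10)

    def test_sparse_path_agrees_with_dense(self):
        # force the ARPACK branch on a larger generator
        import karyomie.mie as mie

        space = build_space(2, [1, 1], [8, 8])
        gen = build_generator(space, constant_rates(1.0, 0.3, 0.05))
        dense = dominant_eigenvalue(gen)
        old = mie._DENSE_LIMIT
        try:
            mie._DENSE_LIMIT = 10
            assert dominant_eigenvalue(gen) == pytest.approx(dense, abs=1e-9)
        finally:
            mie._DENSE_LIMIT = old


class TestGershgorin:
    def test_uncoupled_margins_are_net_growth(self):
        space = build_space(1, [1], [5])
        gen = build_generator(space, constant_rates(1.0, 0.4, 0.0))
        rep = gershgorin_conditions(gen)
        assert rep.row_margin == pytest.approx(0.6)
        assert rep.col_margin == pytest.approx(0.6)
        assert rep.mie_ruled_out

    def test_nearest_neighbor_closed_form(self):
        # beta = 0.05 < (1 - 0.7)/4 = 0.075, so the screen passes
        gen = nearest_neighbor_generator(aggregate_space(1, 5), 1.0, 0.7, 0.05)
        rep = gershgorin_conditions(gen)
        assert rep.row_margin > 0
        assert rep.mie_ruled_out

    def test_screen_is_sufficient_for_growth(self, rng):
        # whenever the screen passes, the dominant eigenvalue must be positive
        space = build_space(1, [1], [6])
        hits = 0
        for _ in range(50):
            lam = float(rng.uniform(0.5, 2.0))
            mu = float(rng.uniform(0.0, 0.6 * lam))
            beta = float(rng.uniform(0.0, 0.15))
            gen = build_generator(space, constant_rates(lam, mu, beta))
            rep = gershgorin_conditions(gen)
            if rep.mie_ruled_out:
                hits += 1
                assert dominant_eigenvalue(gen) > 0
        assert hits > 0  # the draw ranges do exercise the screen


class TestTable2:
    def test_scenario1_closed_form(self):
        space = aggregate_space(1, 5)
        out = table2_condition(1, constant_rates(1.0, 0.6, 0.05), space)
        assert out["beta_c"] == pytest.approx(0.1)
        assert out["satisfied"]

    def test_scenario1_homeostasis_boundary(self):
        space = aggregate_space(1, 5)
        out = table2_condition(1, constant_rates(1.0, 1.0, 0.0), space)
        assert out["beta_c"] == pytest.approx(0.0)
        assert not out["satisfied"]  # beta must be strictly below beta_c

    def test_scenario1_boundary_matches_gershgorin_zero_crossing(self):
        # the beta at which the nearest-neighbor Gershgorin margin crosses
        # zero must equal (1 - mu/lam)/4 to machine precision
        space = aggregate_space(1, 6)
        lam, mu = 1.0, 0.6

        def margin(beta):
            gen = nearest_neighbor_generator(space, lam, mu, beta)
            rep = gershgorin_conditions(gen)
            return max(rep.row_margin, rep.col_margin)

        crossing = brentq(margin, 1e-6, 0.5, xtol=1e-14)
        assert crossing == pytest.approx(0.25 * (1 - mu / lam), abs=1e-10)

    def test_scenario2_heterogeneous_margins(self):
        space = aggregate_space(1, 5)
        out = table2_condition(2, constant_rates(1.0, 0.0, 0.2), space)
        # interior margin 1 - 3(0.2) - 0.2 = 0.2 > 0
        assert out["satisfied"]
        assert out["per_state_margins"][0] == pytest.approx(0.2)

    def test_scenario3_constant_beta(self):
        space = aggregate_space(1, 5)
        out = table2_condition(3, constant_rates(1.0, 0.2, 0.1), space)
        # interior bound (1 - 0.2)/(3 + 1) = 0.2
        assert out["beta_c"] == pytest.approx(0.2)
        assert out["satisfied"]

    def test_scenario1_requires_homogeneous(self):
        space = aggregate_space(1, 5)
        het = constant_rates(1.0, 0.0, 0.0).with_misseg(lambda k: 0.01 * k[0], "custom")
        with pytest.raises(ValueError):
            table2_condition(1, het, space)

    def test_conditions_are_sufficient(self, rng):
        # no false "safe" verdicts across random homogeneous draws
        space = aggregate_space(1, 5)
        for _ in range(30):
            lam = float(rng.uniform(0.5, 2.0))
            mu = float(rng.uniform(0.0, lam))
            beta = float(rng.uniform(0.0, 0.3))
            rates = constant_rates(lam, mu, beta)
            if table2_condition(2, rates, space)["satisfied"]:
                gen = build_generator(space, rates)
                assert dominant_eigenvalue(gen) > 0


class TestCriticalTurnover:
    def test_single_state_closed_form(self):
        space = build_space(1, [1], [1])
        assert critical_turnover(space, constant_rates(1.0, 0.0, 0.1)) == pytest.approx(
            0.8
        )

    def test_faithful_division_boundary_is_homeostasis(self, single_chrom_space):
        assert critical_turnover(
            single_chrom_space, constant_rates(1.0, 0.0, 0.0)
        ) == pytest.approx(1.0)

    def test_matches_dense_eigensolver_oracle(self, single_chrom_space):
        from karyomie.missegregation import division_tensor

        beta = 0.05
        rates = constant_rates(1.0, 0.0, beta)
        got = critical_turnover(single_chrom_space, rates)
        # oracle: dense eigendecomposition of the death-free generator
        tensor = division_tensor(single_chrom_space, rates)
        A = 2 * tensor.daughter_form.toarray().T - np.eye(5)
        expected = float(np.max(eigvals(A).real))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_shift_identity_locates_zero_eigenvalue(self, single_chrom_space):
        beta = 0.08
        mu_crit = critical_turnover(single_chrom_space, constant_rates(1.0, 0.0, beta))
        gen = build_generator(single_chrom_space, constant_rates(1.0, mu_crit, beta))
        assert abs(dominant_eigenvalue(gen)) < 1e-10


class TestCriticalCurve:
    def test_homogeneous_curve_shape(self, single_chrom_space):
        grid = np.linspace(0.0, 1.0, 21)
        curve = homogeneous_critical_curve(single_chrom_space, grid)
        ct = curve.critical_turnover
        assert ct[0] == pytest.approx(1.0)  # beta -> 0: boundary at homeostasis
        assert np.all(ct > 0)  # MIE impossible at low turnover for any beta
        assert np.all(ct <= 1.0 + 1e-12)
        assert not np.any(np.isnan(ct))

    def test_single_chromosome_more_restrictive_than_ploidy(self):
        # a single critical chromosome on [1,5] contracts viability more than
        # an aggregate-ploidy constraint on [22,88]
        beta_grid = [0.05, 0.1, 0.2]
        chrom = homogeneous_critical_curve(build_space(1, [1], [5]), beta_grid)
        ploidy = homogeneous_critical_curve(build_space(1, [22], [88]), beta_grid)
        assert np.all(chrom.critical_turnover < ploidy.critical_turnover)

    def test_kernel_curve_refuge_bound(self):
        # sinusoidal beta kernel: the low-rate refuge keeps the population
        # above the homogeneous curve at the kernel's *maximum* rate, and a
        # deeper refuge (larger amplitude) tolerates more turnover
        space = aggregate_space(2, 10)
        theta2_grid = [0.0, 0.01, 0.03]
        b0 = 0.05

        def factory(theta2):
            return constant_rates(1.0, 0.0, 0.0).with_misseg(
                sinusoidal_beta_kernel(theta2, b0, p_peak=6, period=4, floor=1e-4),
                kind="sinusoidal",
            )

        curve = critical_curve(space, "theta2", theta2_grid, factory)
        assert curve.assumptions == "kernel"
        for theta2, ct in curve.as_points():
            rm = factory(theta2)
            beta_max = max(rm.misseg(s) for s in space.states)
            homog = critical_turnover(space, constant_rates(1.0, 0.0, beta_max))
            assert ct >= homog - 1e-9
        assert np.all(np.diff(curve.critical_turnover) >= -1e-12)

    def test_heterogeneous_death_uses_bisection(self):
        space = aggregate_space(1, 5)

        def factory(beta):
            base = constant_rates(1.0, 0.0, beta)
            return base.with_death(lambda k: 0.1 + 0.05 * k[0], kind="linear")

        curve = critical_curve(space, "beta", [0.05], factory)
        c = curve.critical_turnover[0]
        assert np.isfinite(c)
        # at the reported multiplier the dominant eigenvalue is zero
        rates = factory(0.05).with_death(
            lambda k: c * (0.1 + 0.05 * k[0]), kind="scaled"
        )
        gen = build_generator(space, rates)
        assert abs(dominant_eigenvalue(gen)) < 1e-8

    def test_straddling_points_classified_by_simulation(self, single_chrom_space):
        # +-5% in mu around the curve: growth below, extinction above
        from karyomie import simulate_to_qss

        betas = np.linspace(0.02, 0.5, 10)
        curve = homogeneous_critical_curve(single_chrom_space, betas)
        for beta, mu_crit in curve.as_points():
            for factor, expected in [(0.95, "growth"), (1.05, "extinction")]:
                gen = build_generator(
                    single_chrom_space, constant_rates(1.0, factor * mu_crit, beta)
                )
                res = simulate_to_qss(gen, t_max=5e3, qss_tol=1e-5)
                assert res.converged
                assert res.classification == expected, (beta, factor)


class TestKroneckerFactorization:
    def test_two_singleton_chromosomes_closed_form(self):
        got = multichromosome_critical([(1, 1), (1, 1)], 0.1)
        assert got == pytest.approx(2 * 0.9**2 - 1)

    def test_single_factor_matches_critical_turnover(self, single_chrom_space):
        beta = 0.07
        got = multichromosome_critical([(1, 5)], beta)
        expected = critical_turnover(single_chrom_space, constant_rates(1.0, 0.0, beta))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("box", [(1, 3), (1, 8), (2, 6)])
    def test_joint_generator_oracle(self, box):
        beta, lam, mu = 0.01, 1.0, 0.3
        lo, hi = box
        space = build_space(2, [lo, lo], [hi, hi])
        gen = build_generator(space, constant_rates(lam, mu, beta))
        s_full = dominant_eigenvalue(gen)
        rho = np.max(np.abs(eigvals(single_daughter_matrix(lo, hi, beta))))
        assert s_full == pytest.approx(2 * lam * rho**2 - (lam + mu), abs=1e-10)

    def test_joint_generator_equals_kron_identity(self):
        from karyomie.missegregation import division_tensor

        lam, mu, beta = 1.0, 0.2, 0.05
        space = build_space(2, [1, 1], [4, 4])
        rates = constant_rates(lam, mu, beta)
        gen = build_generator(space, rates)
        Q = single_daughter_matrix(1, 4, beta)
        joint = np.kron(Q, Q)
        expected = 2 * lam * joint.T - (lam + mu) * np.eye(16)
        assert np.allclose(gen.toarray(), expected, atol=1e-12)

    def test_contraction_with_diminishing_increments(self):
        beta = 0.02
        crits = [
            multichromosome_critical([(1, 8)], beta, n_copies_equal=m)
            for m in range(1, 23)
        ]
        diffs = -np.diff(crits)
        assert np.all(diffs >= -1e-12)  # non-increasing in chromosome count
        assert np.all(np.diff(diffs) <= 1e-12)  # decrements shrink

    def test_22_autosome_value_is_power_of_single_rho(self):
        beta = 0.01
        rho = np.max(np.abs(eigvals(single_daughter_matrix(1, 8, beta))))
        got = multichromosome_critical([(1, 8)], beta, n_copies_equal=22)
        assert got == pytest.approx(2 * rho**22 - 1, abs=1e-12)


class TestSteadyStateProportions:
    def test_single_state(self):
        space = build_space(1, [1], [1])
        gen = build_generator(space, constant_rates(1.0, 0.0, 0.1))
        assert steady_state_proportions(gen) == pytest.approx([1.0])

    def test_diagonal_case_is_argmax_indicator(self):
        space = build_space(1, [1], [4])
        rates = constant_rates(1.0, 0.0, 0.0).with_death(
            tabulated_kernel({(1,): 0.5, (2,): 0.1, (3,): 0.4, (4,): 0.6}),
            kind="tabulated",
        )
        gen = build_generator(space, rates)
        p = steady_state_proportions(gen)
        expected = np.zeros(4)
        expected[space.index_of((2,))] = 1.0
        assert p == pytest.approx(expected)

    def test_refuge_concentration(self):
        # heterogeneous beta: mass concentrates near the minimum-beta state
        # and the population-average beta stays above the minimum
        space = build_space(1, [1], [8])
        kernel = sinusoidal_beta_kernel(0.05, 0.06, p_peak=3, period=6, floor=1e-4)
        rates = constant_rates(1.0, 0.0, 0.0).with_misseg(kernel, kind="sinusoidal")
        gen = build_generator(space, rates)
        p = steady_state_proportions(gen)
        betas = np.array([rates.misseg(s) for s in space.states])
        assert np.argmax(p) == np.argmin(betas)
        assert p @ betas >= betas.min()

    def test_degenerate_dominant_pair_rejected(self):
        # two identical uncoupled blocks share the dominant eigenvalue
        J = np.diag([0.5, 0.5, -1.0])
        with pytest.raises(ValueError, match="simple"):
            steady_state_proportions(J)


class TestRefugeEigenvalueBound:
    def test_heterogeneous_beta_bounded_by_worst_homogeneous(self):
        # with homogeneous death, the heterogeneous-beta population grows at
        # least as fast as a homogeneous population at the maximum beta
        space = build_space(1, [1], [8])
        kernel = sinusoidal_beta_kernel(0.05, 0.06, p_peak=3, period=6, floor=1e-4)
        het = constant_rates(1.0, 0.3, 0.0).with_misseg(kernel, kind="sinusoidal")
        beta_max = max(het.misseg(s) for s in space.states)
        s_het = dominant_eigenvalue(build_generator(space, het))
        s_hom = dominant_eigenvalue(
            build_generator(space, constant_rates(1.0, 0.3, beta_max))
        )
        assert s_het >= s_hom - 1e-10

    def test_mie_needs_high_death_at_low_beta_states(self):
        # a refuge (low beta) state with low death keeps the population alive;
        # extinction requires the interplay where low-beta states die fast
        space = build_space(1, [1], [4])
        beta_tab = tabulated_kernel({(1,): 0.3, (2,): 0.01, (3,): 0.3, (4,): 0.3})
        lam = 1.0
        base = constant_rates(lam, 0.0, 0.0).with_misseg(beta_tab, kind="tabulated")
        # low death on the refuge: no MIE even with heavy death elsewhere
        safe = base.with_death(
            tabulated_kernel({(1,): 0.9, (2,): 0.05, (3,): 0.9, (4,): 0.9}),
            kind="tabulated",
        )
        assert dominant_eigenvalue(build_generator(space, safe)) > 0
        # high death concentrated on the refuge tips the population into MIE
        doomed = base.with_death(
            tabulated_kernel({(1,): 0.9, (2,): 1.2, (3,): 0.9, (4,): 0.9}),
            kind="tabulated",
        )
        assert dominant_eigenvalue(build_generator(space, doomed)) < 0


class TestContinuum:
    def test_closed_form_threshold(self):
        m = ContinuumModel(lam=1.0, mu=0.0, beta=0.1, p_min=0.0, p_max=2.0)
        out = continuum_critical(m)
        assert out["mu_crit_over_lambda"] == pytest.approx(
            1 - 0.1 * np.pi**2 / 4, abs=1e-12
        )

    def test_zero_rate_threshold_is_homeostasis(self):
        m = ContinuumModel(lam=1.0, mu=0.0, beta=0.0, p_min=1.0, p_max=5.0)
        assert continuum_critical(m)["mu_crit_over_lambda"] == pytest.approx(1.0)

    def test_finite_difference_oracle(self):
        # discretized reaction-diffusion operator: the dominant eigenvalue
        # changes sign at the closed-form threshold within 1%
        lam, beta, L = 1.0, 0.1, 2.0
        nodes = 200
        h = L / (nodes + 1)
        lap = (
            np.diag(-2.0 * np.ones(nodes))
            + np.diag(np.ones(nodes - 1), 1)
            + np.diag(np.ones(nodes - 1), -1)
        ) / h**2

        def s_of_mu(mu):
            A = beta * lam * lap + (lam - mu) * np.eye(nodes)
            return float(np.max(eigvals(A).real))

        mu_crit_fd = brentq(s_of_mu, 0.0, 1.0, xtol=1e-12)
        mu_crit_cf = continuum_critical(
            ContinuumModel(lam=lam, mu=0.0, beta=beta, p_min=0.0, p_max=L)
        )["mu_crit_over_lambda"]
        assert mu_crit_fd == pytest.approx(mu_crit_cf, rel=0.01)

    def test_heuristic_inequality(self):
        fast_misseg = ContinuumModel(
            lam=1.0, mu=0.99, beta=0.5, p_min=0.0, p_max=1.0
        )
        assert continuum_critical(fast_misseg)["mie_heuristic"]
        slow_misseg = ContinuumModel(
            lam=1.0, mu=0.0, beta=0.001, p_min=0.0, p_max=10.0
        )
        assert not continuum_critical(slow_misseg)["mie_heuristic"]

    def test_timescales(self):
        m = ContinuumModel(lam=2.0, mu=0.5, beta=0.1, p_min=0.0, p_max=4.0)
        assert m.r == pytest.approx(1.5)
        assert m.T_r == pytest.approx(1 / 1.5)
        assert m.T_p == pytest.approx(16 / 0.2)
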