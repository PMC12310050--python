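import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from selhmm import (
    ConstraintSpec,
    EMConfig,
    InitialDistribution,
    SelectionParams,
    TemporalObservations,
    beta_init_update,
    chebychev_grid,
    fit_all_modes,
    forward_backward,
    m_step_constrained,
    m_step_unconstrained,
    mean_next_freq,
    run_em,
    trajectory_mle,
    transition_matrix,
)
from selhmm.em_fit import discretized_beta
from selhmm.hmm_core import EStepMoments


def random_moments(rng, T=8, M=5):
    """Valid posterior-expectation accumulators from random marginals
    (independent joint across time, which is a legitimate distribution)."""
    g = np.sort(rng.uniform(0.05, 0.95, M))
    gam = rng.dirichlet(np.ones(M), T)
    h = g * (1 - g)
    cross = sum(float((gam[t] @ g) * (gam[t + 1] @ g)) for t in range(T - 1))
    gs = gam[: T - 1].sum(axis=0)
    return EStepMoments(
        s_h=float(gs @ h),
        s_fh=float(gs @ (g * h)),
        s_f2h=float(gs @ (g * g * h)),
        s_f2=float(gs @ (g * g)),
        s_cross=cross,
        e_first=float(gam[0] @ g),
        e_last=float(gam[-1] @ g),
    )


def expected_gauss_ll(s, mom):
    """Expected Gaussian-increment log-likelihood, written directly from the
    posterior moment sums (up to additive constants and the 2Ne factor):

      E[-(dF - s1 H(1-2F) - s2 H F)^2 / H]  summed over transitions.
    """
    s1, s2 = s
    lin1 = (mom.e_last - mom.e_first) - 2.0 * (mom.s_cross - mom.s_f2)
    lin2 = mom.s_cross - mom.s_f2
    quad = (
        s1 * s1 * (mom.s_h - 4 * mom.s_fh + 4 * mom.s_f2h)
        + 2 * s1 * s2 * (mom.s_fh - 2 * mom.s_f2h)
        + s2 * s2 * mom.s_f2h
    )
    return 2.0 * (s1 * lin1 + s2 * lin2) - quad


def polished_minimize(fun, x0, h=1e-4):
    """Nelder-Mead followed by finite-difference Newton polish.

    The objectives checked here are quadratics (possibly ill-conditioned),
    for which the central-difference Newton step recovers the stationary
    point essentially exactly.
    """
    res = minimize(
        fun, np.asarray(x0, dtype=float), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    x = res.x
    n = x.size
    for _ in range(3):
        grad = np.empty(n)
        hess = np.empty((n, n))
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h
            grad[i] = (fun(x + ei) - fun(x - ei)) / (2 * h)
            for j in range(i, n):
                ej = np.zeros(n)
                ej[j] = h
                hess[i, j] = hess[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h * h)
        try:
            x = x - np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
    res.x = x
    return res


class TestTrajectoryMLE:
    def test_constant_trajectory_is_neutral(self):
        est = trajectory_mle(np.full(20, 0.3))
        assert est.s1 == 0.0 and est.s2 == 0.0

    def test_recovers_deterministic_recursion(self):
        p = [0.3]
        for _ in range(150):
            p.append(mean_next_freq(p[-1], SelectionParams(0.01, 0.02)))
        est = trajectory_mle(np.array(p))
        assert est.s1 == pytest.approx(0.01, abs=1e-6)
        assert est.s2 == pytest.approx(0.02, abs=1e-6)

    def test_matches_numeric_path_likelihood(self, rng):
        def neg_path_ll(s, p, ne=500.0):
            pt, pn = p[:-1], p[1:]
            h = pt * (1 - pt)
            mu = pt + h * (s[0] * (1 - 2 * pt) + s[1] * pt)
            return np.sum((pn - mu) ** 2 / (h / (2 * ne)))

        for _ in range(5):
            p = np.clip(0.4 + np.cumsum(rng.normal(0, 0.02, 25)), 0.05, 0.95)
            est = trajectory_mle(p)
            res = polished_minimize(lambda s: neg_path_ll(s, p), [0.0, 0.0])
            assert est.s1 == pytest.approx(res.x[0], abs=1e-6)
            assert est.s2 == pytest.approx(res.x[1], abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            trajectory_mle(np.array([0.5]))
        with pytest.raises(ValueError):
            trajectory_mle(np.array([0.5, 1.3]))


class TestMStep:
    def test_point_mass_posteriors_reduce_to_trajectory_mle(self):
        p = np.array([0.2, 0.25, 0.24, 0.3, 0.33])
        pt, pn = p[:-1], p[1:]
        h = pt * (1 - pt)
        mom = EStepMoments(
            s_h=float(h.sum()),
            s_fh=float((pt * h).sum()),
            s_f2h=float((pt**2 * h).sum()),
            s_f2=float((pt**2).sum()),
            s_cross=float((pt * pn).sum()),
            e_first=float(p[0]),
            e_last=float(p[-1]),
        )
        em = m_step_unconstrained(mom)
        tr = trajectory_mle(p)
        assert em.s1 == pytest.approx(tr.s1, abs=1e-12)
        assert em.s2 == pytest.approx(tr.s2, abs=1e-12)

    def test_unconstrained_matches_numeric_optimizer(self, rng):
        for _ in range(100):
            mom = random_moments(rng)
            est = m_step_unconstrained(mom)
            res = polished_minimize(lambda s: -expected_gauss_ll(s, mom), [0.0, 0.0])
            assert est.s1 == pytest.approx(res.x[0], abs=1e-8)
            assert est.s2 == pytest.approx(res.x[1], abs=1e-8)

    @pytest.mark.parametrize("mode", ["additive", "dominant", "recessive", "het_diff"])
    def test_constrained_matches_line_search(self, mode, rng):
        c = ConstraintSpec.for_mode(mode)
        v = c.direction()
        for _ in range(100):
            mom = random_moments(rng)
            est = m_step_constrained(mom, c)
            fun = lambda s: -expected_gauss_ll(s * v, mom)
            res = minimize_scalar(
                fun, bounds=(-100, 100), method="bounded",
                options={"xatol": 1e-12},
            )
            # Newton polish: the restricted objective is an exact quadratic
            x, h = float(res.x), 1e-4
            for _ in range(3):
                d1 = (fun(x + h) - fun(x - h)) / (2 * h)
                d2 = (fun(x + h) - 2 * fun(x) + fun(x - h)) / (h * h)
                if d2 <= 0:
                    break
                x -= d1 / d2
            got = est.s1 if mode == "het_diff" else est.s2
            assert got == pytest.approx(x, abs=1e-8)

    def test_constraint_lines_exact(self, rng):
        mom = random_moments(rng)
        rec = m_step_constrained(mom, ConstraintSpec.for_mode("recessive"))
        assert rec.s1 == 0.0
        add = m_step_constrained(mom, ConstraintSpec.for_mode("additive"))
        assert 2 * add.s1 - add.s2 == pytest.approx(0.0, abs=1e-12)
        het = m_step_constrained(mom, ConstraintSpec.for_mode("het_diff"))
        assert het.s2 == 0.0

    def test_martingale_posteriors_give_zero_selection(self):
        # symmetric stationary marginals with cross moments consistent with
        # a driftless (martingale) process: E[F_t F_{t+1}] = E[F_t^2]
        g = np.array([0.3, 0.5, 0.7])
        gam = np.full((6, 3), 1.0 / 3)
        h = g * (1 - g)
        gs = gam[:5].sum(axis=0)
        mean = float(gam[0] @ g)
        mom = EStepMoments(
            s_h=float(gs @ h),
            s_fh=float(gs @ (g * h)),
            s_f2h=float(gs @ (g * g * h)),
            s_f2=float(gs @ (g * g)),
            s_cross=float(gs @ (g * g)),
            e_first=mean,
            e_last=mean,
        )
        est = m_step_unconstrained(mom)
        assert abs(est.s1) < 1e-9 and abs(est.s2) < 1e-9


class TestConstraintSpec:
    def test_mode_coefficients(self):
        assert ConstraintSpec.for_mode("additive").a == 2.0
        assert ConstraintSpec.for_mode("recessive").b == 0.0
        with pytest.raises(ValueError):
            ConstraintSpec("bogus")
        with pytest.raises(ValueError):
            ConstraintSpec("additive", 0.0, 0.0)

    @pytest.mark.parametrize(
        "mode", ["additive", "dominant", "recessive", "het_diff"]
    )
    def test_direction_on_constraint_line(self, mode):
        c = ConstraintSpec.for_mode(mode)
        v = c.direction()
        assert c.a * v[0] - c.b * v[1] == pytest.approx(0.0, abs=1e-15)


class TestBetaInitUpdate:
    def test_recovers_beta_2_5(self):
        grid = chebychev_grid(500)
        al, be = beta_init_update(discretized_beta(2.0, 5.0, grid), grid)
        assert al == pytest.approx(2.0, rel=0.05)
        assert be == pytest.approx(5.0, rel=0.05)

    def test_uniform_recovers_one_one(self):
        grid = chebychev_grid(500)
        al, be = beta_init_update(discretized_beta(1.0, 1.0, grid), grid)
        assert al == pytest.approx(1.0, rel=0.05)
        assert be == pytest.approx(1.0, rel=0.05)

    def test_symmetric_posterior_gives_symmetric_shapes(self):
        grid = chebychev_grid(200)
        mass = discretized_beta(3.0, 3.0, grid)
        al, be = beta_init_update(mass, grid)
        assert al == pytest.approx(be, abs=1e-6 * max(al, 1.0) + 1e-6)

    def test_discretized_beta_mass(self):
        grid = chebychev_grid(100)
        mass = discretized_beta(2.0, 5.0, grid)
        assert mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(mass >= 0)
        # boundary intervals hold the beta tail mass
        from scipy.special import betainc

        b = grid.boundaries01()
        assert mass[0] == pytest.approx(betainc(2.0, 5.0, b[1]), abs=1e-12)


class TestRunEM:
    def test_neutral_fixed_uniform_is_single_forward_pass(self, rng):
        grid = chebychev_grid(80)
        obs = TemporalObservations.from_samples(30, [1, 15, 30], [20, 20, 20], [5, 8, 9])
        res = run_em(
            obs,
            ConstraintSpec.for_mode("neutral"),
            200.0,
            EMConfig(M=80),
            InitialDistribution.uniform(),
            grid,
        )
        P = transition_matrix(grid, SelectionParams(0, 0), 200.0)
        direct = forward_backward(obs, P, discretized_beta(1, 1, grid), grid)
        assert res.log_likelihood == pytest.approx(direct.log_likelihood, abs=1e-10)
        assert res.s1 == 0.0 and res.s2 == 0.0

    def test_modes_nest_neutral(self):
        obs = TemporalObservations.from_samples(
            51, [1, 11, 21, 31, 41, 51], [30] * 6, [6, 9, 12, 16, 18, 21]
        )
        results = fit_all_modes(obs, 300.0, EMConfig(M=100))
        ll0 = results["neutral"].log_likelihood
        for mode in ("additive", "dominant", "recessive", "het_diff"):
            assert results[mode].log_likelihood >= ll0 - 1e-6
            # constrained MLEs lie exactly on their constraint line
            c = ConstraintSpec.for_mode(mode)
            r = results[mode]
            assert c.a * r.s1 - c.b * r.s2 == pytest.approx(0.0, abs=1e-12)

    def test_reported_ll_is_trace_maximum(self):
        obs = TemporalObservations.from_samples(
            41, [1, 21, 41], [24, 24, 24], [4, 10, 17]
        )
        res = run_em(obs, ConstraintSpec.for_mode("additive"), 250.0, EMConfig(M=80))
        assert res.log_likelihood == pytest.approx(max(res.ll_trace), abs=0)
        assert res.n_iter >= 5

    def test_all_missing_rejected(self):
        obs = TemporalObservations(np.zeros(5, int), np.zeros(5, int))
        with pytest.raises(ValueError):
            run_em(obs, ConstraintSpec.for_mode("neutral"), 100.0, EMConfig(M=20))

    def test_sample_triple_order_is_plumbing(self):
        """The order in which sparse (t, n, a) triples are supplied is pure
        plumbing: the dense representation and hence the fit are identical."""
        a = TemporalObservations.from_samples(21, [1, 11, 21], [20] * 3, [5, 9, 12])
        b = TemporalObservations.from_samples(21, [21, 1, 11], [20] * 3, [12, 5, 9])
        ra = run_em(a, ConstraintSpec.for_mode("additive"), 200.0, EMConfig(M=60))
        rb = run_em(b, ConstraintSpec.for_mode("additive"), 200.0, EMConfig(M=60))
        assert ra.log_likelihood == rb.log_likelihood
        assert ra.s2 == rb.s2

    def test_monomorphic_flagged(self):
        obs = TemporalObservations.from_samples(11, [1, 11], [10, 10], [0, 0])
        res = run_em(obs, ConstraintSpec.for_mode("neutral"), 100.0, EMConfig(M=40))
        assert "monomorphic_samples" in res.flags
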