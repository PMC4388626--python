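"""Solver correctness: closed-form coefficient update vs an independent
iterative linear solve, model-limit behavior, convergence and guards."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balmri import (
    DivergenceError,
    SolverConfig,
    admm_b,
    apg,
    csalsa_b,
    generate_mask,
    make_fixture,
    make_orthogonal_dwt_frame,
    make_sidwt_frame,
    measure,
    rlne,
    soft_threshold,
    zero_fill_adjoint,
)
from balmri.phantoms import PhantomSpec
from balmri.solvers import (
    AuxState,
    alpha_update,
    beta_from_gamma,
    gamma_from_beta,
    smooth_gradient,
    subproblem_oracle,
)

from conftest import random_complex


def small_instance(rng, shape=(16, 16), fraction=0.4, levels=2, seed=3):
    frame = make_sidwt_frame(shape, "db2", levels)
    mask = generate_mask(shape, fraction, seed=seed)
    x = random_complex(rng, shape)
    y = measure(x, mask)
    state = AuxState(
        z=random_complex(rng, frame.n_coefficients),
        d=random_complex(rng, frame.n_coefficients),
        h=random_complex(rng, mask.n_samples),
    )
    return frame, mask, x, y, state


class TestGammaBeta:
    def test_reference_value(self):
        assert gamma_from_beta(1.0, 1.0) == pytest.approx(0.5)

    def test_endpoints(self):
        assert gamma_from_beta(0.0, 1.0) == 1.0  # synthesis
        assert gamma_from_beta(np.inf, 1.0) == 0.0  # analysis
        assert beta_from_gamma(0.0, 1.0) == np.inf
        assert beta_from_gamma(1.0, 1.0) == 0.0

    def test_roundtrip_and_monotonicity(self):
        betas = [0.0, 0.5, 1.0, 4.0, 100.0]
        gammas = [gamma_from_beta(b, 2.0) for b in betas]
        assert all(g1 > g2 for g1, g2 in zip(gammas, gammas[1:]))
        for b, g in zip(betas, gammas):
            assert beta_from_gamma(g, 2.0) == pytest.approx(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gamma_from_beta(-1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_from_beta(1.0, 0.0)


class TestSoftThreshold:
    def test_real_reference_values(self):
        assert soft_threshold(np.array([2.0]), 1.0)[0] == pytest.approx(1.0)
        assert soft_threshold(np.array([-2.0]), 1.0)[0] == pytest.approx(-1.0)
        assert soft_threshold(np.array([0.5]), 1.0)[0] == 0.0

    def test_zero_threshold_is_identity(self, rng):
        v = random_complex(rng, 50)
        assert np.array_equal(soft_threshold(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @settings(deadline=None, max_examples=50)
    @given(
        re=st.floats(-10, 10, allow_nan=False),
        im=st.floats(-10, 10, allow_nan=False),
        t=st.floats(0, 5, allow_nan=False),
    )
    def test_magnitude_shrinkage_preserves_phase(self, re, im, t):
        v = np.array([complex(re, im)])
        out = soft_threshold(v, t)[0]
        assert abs(out) == pytest.approx(max(abs(v[0]) - t, 0.0), abs=1e-12)
        if abs(out) > 1e-9:
            assert np.angle(out) == pytest.approx(np.angle(v[0]), abs=1e-9)

    def test_is_prox_of_l1(self, rng):
        # prox property: out minimizes t*|u| + 0.5|u - v|^2 entrywise
        v = random_complex(rng, 20)
        t = 0.3
        out = soft_threshold(v, t)
        obj = t * np.abs(out) + 0.5 * np.abs(out - v) ** 2
        for _ in range(20):
            u = out + 0.05 * random_complex(rng, 20)
            alt = t * np.abs(u) + 0.5 * np.abs(u - v) ** 2
            assert np.all(obj <= alt + 1e-12)


class TestAlphaUpdate:
    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_matches_iterative_oracle(self, rng, gamma):
        frame, mask, x, y, state = small_instance(rng, seed=int(10 * gamma) + 1)
        mu, rho = 1.3, 0.7
        a = alpha_update(state, y, frame, mu, rho, gamma)
        ref = subproblem_oracle(state, y, frame, mu, rho, beta_from_gamma(gamma, rho))
        assert np.linalg.norm(a - ref) / np.linalg.norm(ref) < 1e-8

    def test_oracle_satisfies_normal_equations(self, rng):
        from balmri.kspace import mask_adjoint
        from balmri.solvers import _forward_samples

        frame, mask, x, y, state = small_instance(rng)
        mu, rho, beta = 1.0, 1.0, 2.0
        a = subproblem_oracle(state, y, frame, mu, rho, beta)
        lhs = (
            beta * (a - frame.range_projection(a))
            + mu * frame.analysis(mask_adjoint(_forward_samples(frame.synthesis(a), mask.grid), mask))
            + rho * a
        )
        rhs = mu * frame.analysis(mask_adjoint(y.samples + state.h, mask)) + rho * (
            state.z + state.d
        )
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-10

    def test_zero_weight_data_term_projector_split(self, rng):
        # with no data term the minimizer is gamma*(z+d) + (1-gamma)*P(z+d)
        frame, mask, x, y, state = small_instance(rng)
        gamma = 0.3
        a = alpha_update(state, y, frame, 0.0, 1.0, gamma)
        s = state.z + state.d
        expected = gamma * s + (1 - gamma) * frame.range_projection(s)
        assert np.linalg.norm(a - expected) / np.linalg.norm(expected) < 1e-10

    def test_synthesis_limit_full_mask_convex_combination(self, rng):
        # gamma=1, full mask, h=0, z+d = Psi x0: the update is Psi applied to
        # (mu * F*y-image + rho * x0)/(mu+rho) plus the off-range part of z+d
        shape = (16, 16)
        frame = make_sidwt_frame(shape, "db2", 2)
        mask = generate_mask(shape, 1.0, pattern="full")
        x = random_complex(rng, shape)
        y = measure(x, mask)
        x0 = random_complex(rng, shape)
        s = frame.analysis(x0)
        state = AuxState(z=s, d=np.zeros_like(s), h=np.zeros(mask.n_samples, dtype=complex))
        mu, rho = 2.0, 1.0
        a = alpha_update(state, y, frame, mu, rho, 1.0)
        expected = frame.analysis((mu * zero_fill_adjoint(y) + rho * x0) / (mu + rho))
        # s is canonical here so its off-range part vanishes
        assert np.linalg.norm(a - expected) / np.linalg.norm(expected) < 1e-10

    def test_oracle_synthesis_full_mask_closed_form(self, rng):
        # beta=0, full mask: normal equations are diagonal in k-space
        shape = (16, 16)
        frame = make_sidwt_frame(shape, "db2", 2)
        mask = generate_mask(shape, 1.0, pattern="full")
        x = random_complex(rng, shape)
        y = measure(x, mask)
        D = frame.n_coefficients
        state = AuxState(
            z=random_complex(rng, D), d=random_complex(rng, D),
            h=np.zeros(mask.n_samples, dtype=complex),
        )
        mu, rho = 1.5, 0.5
        a = subproblem_oracle(state, y, frame, mu, rho, 0.0)
        s = state.z + state.d
        # [mu A*A + rho] a = mu A* y + rho s with A*A = P for a full mask:
        # split s into range and off-range parts and average on the range
        ps = frame.range_projection(s)
        expected = (mu * frame.analysis(zero_fill_adjoint(y)) + rho * ps) / (mu + rho) + (
            s - ps
        )
        assert np.linalg.norm(a - expected) / np.linalg.norm(expected) < 1e-8


class TestCSalsaB:
    def test_full_sampling_recovers_image(self, rng):
        spec = PhantomSpec(shape=(32, 32), seed=7)
        x, mask, y = make_fixture(spec, 1.0, 0.0, seed=7)
        frame = make_sidwt_frame((32, 32), "db4", 2)
        for gamma in (0.0, 0.5, 1.0):
            cfg = SolverConfig(gamma=gamma, lambda_=1e-4, max_iter=200, tol=1e-6)
            res = csalsa_b(y, frame, cfg, x_true=x)
            assert res.trace_rlne[-1] < 1e-3

    def test_orthogonal_frame_gamma_invariance(self, frozen_fixture, dwt64):
        # with an invertible transform the three models coincide exactly
        x, mask, y = frozen_fixture
        traces = {}
        for gamma in (0.0, 0.5, 1.0):
            res = csalsa_b(y, dwt64, SolverConfig(gamma=gamma, max_iter=50), x_true=x)
            traces[gamma] = res.trace_rlne
        assert np.abs(traces[0.0] - traces[1.0]).max() < 1e-6
        assert np.abs(traces[0.0] - traces[0.5]).max() < 1e-6

    def test_analysis_no_worse_than_synthesis(self, sidwt64):
        # qualitative model ordering on undersampled data, median over seeds
        finals = {0.0: [], 1.0: []}
        for seed in range(5):
            spec = PhantomSpec(shape=(64, 64), seed=1234)
            x, mask, y = make_fixture(spec, 0.4, 0.0, seed=seed)
            for gamma in finals:
                res = csalsa_b(y, sidwt64, SolverConfig(gamma=gamma, max_iter=60), x_true=x)
                finals[gamma].append(res.trace_rlne[-1])
        assert np.median(finals[0.0]) <= np.median(finals[1.0])

    def test_lambda_zero_full_sampling_returns_zero_fill(self, rng):
        spec = PhantomSpec(shape=(32, 32), seed=3)
        x, mask, y = make_fixture(spec, 1.0, 0.0, seed=3)
        frame = make_sidwt_frame((32, 32), "db4", 2)
        res = csalsa_b(y, frame, SolverConfig(lambda_=0.0, max_iter=30))
        assert rlne(res.image, zero_fill_adjoint(y)) < 1e-6

    def test_deterministic_traces(self, frozen_fixture, sidwt64):
        x, mask, y = frozen_fixture
        cfg = SolverConfig(max_iter=10)
        r1 = csalsa_b(y, sidwt64, cfg, x_true=x)
        r2 = csalsa_b(y, sidwt64, cfg, x_true=x)
        assert np.array_equal(r1.trace_rlne, r2.trace_rlne)
        assert np.array_equal(r1.image, r2.image)

    def test_trace_lengths_match_iterations(self, frozen_fixture, sidwt64):
        x, mask, y = frozen_fixture
        res = csalsa_b(y, sidwt64, SolverConfig(max_iter=7), x_true=x)
        assert res.iterations_run == 7
        assert len(res.trace_objective) == len(res.trace_constraint) == 7
        assert len(res.trace_rlne) == 7

    def test_divergence_raises(self, frozen_fixture, sidwt64):
        x, mask, y = frozen_fixture
        with pytest.raises(DivergenceError, match="delta_h"):
            csalsa_b(y, sidwt64, SolverConfig(delta_h=1e8, mu=1e8, max_iter=80))


class TestADMMB:
    def test_dominant_fidelity_full_sampling(self, rng):
        spec = PhantomSpec(shape=(32, 32), seed=5)
        x, mask, y = make_fixture(spec, 1.0, 0.0, seed=5)
        frame = make_sidwt_frame((32, 32), "db4", 2)
        res = admm_b(y, frame, SolverConfig(lambda_=0.01, delta_fid=500.0, max_iter=100), x_true=x)
        assert res.trace_rlne[-1] < 1e-2

    def test_subproblem_matches_oracle(self, rng):
        # ADMM-B's coefficient update is the same closed form with the
        # fidelity weight in place of mu and no measurement multiplier
        frame, mask, x, y, state = small_instance(rng)
        state.h = np.zeros_like(state.h)
        delta, rho, gamma = 2.0, 1.0, 0.5
        a = alpha_update(state, y, frame, delta, rho, gamma)
        ref = subproblem_oracle(state, y, frame, delta, rho, beta_from_gamma(gamma, rho))
        assert np.linalg.norm(a - ref) / np.linalg.norm(ref) < 1e-8

    def test_slower_than_csalsa_to_threshold(self, frozen_fixture, sidwt64):
        from balmri.solvers import iterations_to_threshold

        x, mask, y = frozen_fixture
        rc = csalsa_b(y, sidwt64, SolverConfig(lambda_=0.05, max_iter=150, tol=1e-12), x_true=x)
        ra = admm_b(y, sidwt64, SolverConfig(lambda_=0.01, max_iter=150, tol=1e-12), x_true=x)
        thr = 1.05 * rc.trace_rlne[-1]
        ic = iterations_to_threshold(rc.trace_rlne, thr)
        ia = iterations_to_threshold(ra.trace_rlne, thr)
        assert ic is not None
        assert ia is None or ic <= ia


class TestAPG:
    def test_gradient_matches_finite_differences(self, rng):
        frame, mask, x, y, state = small_instance(rng)
        beta, delta = 1.5, 0.8
        a0 = random_complex(rng, frame.n_coefficients)
        g = smooth_gradient(a0, y, frame, beta, delta)

        def f(a):
            from balmri.solvers import _forward_samples

            resid = _forward_samples(frame.synthesis(a), mask.grid) - y.samples
            off = a - frame.range_projection(a)
            return 0.5 * beta * np.linalg.norm(off) ** 2 + 0.5 * delta * np.linalg.norm(resid) ** 2

        eps = 1e-6
        idx = rng.choice(frame.n_coefficients, size=12, replace=False)
        for i in idx:
            for direction in (1.0, 1.0j):
                e = np.zeros(frame.n_coefficients, dtype=complex)
                e[i] = direction
                fd = (f(a0 + eps * e) - f(a0 - eps * e)) / (2 * eps)
                # directional derivative of a real function along e is Re<g, e>
                an = np.real(np.vdot(e, g))
                assert fd == pytest.approx(an, abs=1e-5, rel=1e-5)

    def test_objective_monotone_with_restart(self, frozen_fixture, sidwt64):
        x, mask, y = frozen_fixture
        res = apg(y, sidwt64, SolverConfig(lambda_=0.005, max_iter=60), x_true=x)
        obj = res.trace_objective
        assert np.all(np.diff(obj[3:]) <= 1e-10 * max(1.0, obj[0]))

    def test_fixed_point_satisfies_stationarity(self, rng):
        # synthesis model on an orthogonal basis: the limit point obeys
        # alpha = soft_threshold(alpha - grad/L, lambda/L)
        spec = PhantomSpec(shape=(32, 32), seed=11)
        x, mask, y = make_fixture(spec, 0.5, 0.0, seed=11)
        frame = make_orthogonal_dwt_frame((32, 32), "db4", 2)
        cfg = SolverConfig(gamma=1.0, lambda_=0.01, delta_fid=1.0, max_iter=500, tol=1e-14)
        res = apg(y, frame, cfg, x_true=x)
        a = res.coefficients
        L = cfg.beta + cfg.delta_fid
        step = a - smooth_gradient(a, y, frame, cfg.beta, cfg.delta_fid) / L
        resid = a - soft_threshold(step, cfg.lambda_ / L)
        assert np.linalg.norm(resid) / np.linalg.norm(a) < 1e-6

    def test_analysis_limit_rejected(self, frozen_fixture, sidwt64):
        x, mask, y = frozen_fixture
        with pytest.raises(ValueError, match="gamma"):
            apg(y, sidwt64, SolverConfig(gamma=0.0))


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(gamma=1.5)
    with pytest.raises(ValueError):
        SolverConfig(rho=0.0)
    with pytest.raises(ValueError):
        SolverConfig(lambda_=-1.0)
    cfg = SolverConfig.from_beta(1.0)
    assert cfg.gamma == pytest.approx(0.5)
    assert cfg.beta == pytest.approx(1.0)
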