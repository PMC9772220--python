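import numpy as np
import pytest
from scipy.special import gammaln

from mcginv.tikhonov import solve_tikhonov
from mcginv.vblr import (
    NIGPrior,
    VBLinearRegression,
    VBPosterior,
    elbo,
    vb_update_alpha,
    vb_update_s_beta,
    vblr_fit,
)


class TestSBetaUpdate:
    def test_toy_ridge_identity(self, toy_problem):
        A, b = toy_problem
        s, C, a_hat, b_hat = vb_update_s_beta(A, b, E_alpha=1.0)
        assert np.allclose(s, [0.5, 0.8], atol=1e-12)
        assert a_hat == pytest.approx(1e-6 + 1.0)  # a0 + M/2

    def test_strong_alpha_limit(self, toy_problem):
        A, b = toy_problem
        e_alpha = 1e12
        s, C, *_ = vb_update_s_beta(A, b, e_alpha)
        assert np.linalg.norm(s) < 1e-9
        assert np.allclose(C, np.eye(2) / e_alpha, rtol=1e-9)

    def test_b_hat_quadratic_completion_identity(self):
        # b0 + (||b - A s||^2 + E_a s's)/2 equals b0 + (b'b - s'C^{-1}s)/2
        rng = np.random.default_rng(0)
        A = rng.standard_normal((9, 4))
        b = rng.standard_normal(9)
        e_alpha = 0.7
        s, C, _, b_hat = vb_update_s_beta(A, b, e_alpha, b0=1e-6)
        alt = 1e-6 + 0.5 * (b @ b - s @ np.linalg.solve(C, s))
        assert b_hat == pytest.approx(alt, rel=1e-9)

    def test_nonpositive_alpha_rejected(self, toy_problem):
        A, b = toy_problem
        with pytest.raises(ValueError):
            vb_update_s_beta(A, b, 0.0)


class TestAlphaUpdate:
    def test_direct_substitution(self):
        # s = 0, C = I, Q = 2, c0 = d0 = 1e-6 -> c = 1 + 1e-6, d = 1 + 1e-6
        c_hat, d_hat = vb_update_alpha(
            np.zeros(2), np.eye(2), a_hat=1.0, b_hat=1.0, c0=1e-6, d0=1e-6
        )
        assert c_hat == pytest.approx(1.0 + 1e-6)
        assert d_hat == pytest.approx(1.0 + 1e-6)

    def test_quadratic_scaling_in_s(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(3)
        C = np.eye(3)
        _, d1 = vb_update_alpha(s, C, 2.0, 1.0)  # E[beta] = 2
        _, d2 = vb_update_alpha(2 * s, C, 2.0, 1.0)
        # doubling s raises d by 3 * E[beta] * s's / 2
        assert d2 - d1 == pytest.approx(3 * 2.0 * (s @ s) / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            vb_update_alpha(np.zeros(2), np.eye(2), -1.0, 1.0)


def conjugate_toy_quadrature(a0, b0, alpha, y=1.0, n_s=2401, n_lb=1601):
    """Exact 2-D quadrature of p(s, beta | y) for A = [1] with pinned alpha:
    N(y | s, beta^-1) N(s | 0, (beta alpha)^-1) Gam(beta | a0, b0).

    Use informative (a0, b0) so the small-beta tail (where the conditional
    s-spread grows like beta^{-1/2}) carries negligible mass inside the
    truncated grid.
    """
    s = np.linspace(-11, 12, n_s)
    lb = np.linspace(-9, 9, n_lb)
    beta = np.exp(lb)
    S, B = np.meshgrid(s, beta, indexing="ij")
    log_joint = (
        0.5 * np.log(B)
        - 0.5 * B * (y - S) ** 2
        + 0.5 * np.log(B * alpha)
        - 0.5 * B * alpha * S**2
        + a0 * np.log(b0)
        - gammaln(a0)
        + (a0 - 1) * np.log(B)
        - b0 * B
        + np.log(B)  # jacobian of the log-beta substitution
    )
    log_joint -= log_joint.max()
    w = np.exp(log_joint)
    z = np.trapezoid(np.trapezoid(w, lb, axis=1), s)
    mean_s = np.trapezoid(np.trapezoid(w * S, lb, axis=1), s) / z
    mean_beta = np.trapezoid(np.trapezoid(w * B, lb, axis=1), s) / z
    log_evidence = np.log(z) + log_joint.max() - np.log(2 * np.pi)
    return mean_s, mean_beta, log_evidence


class TestQuadratureOracle:
    def test_conjugate_toy_posterior_mean_within_1pct(self):
        a0 = b0 = 3.0
        alpha = 1.0
        mean_s, mean_beta, _ = conjugate_toy_quadrature(a0, b0, alpha)
        s, post, trace, ok = vblr_fit(
            np.array([[1.0]]),
            np.array([1.0]),
            NIGPrior(a0, b0, 1e-6, 1e-6),
            fixed_alpha=alpha,
        )
        assert s[0] == pytest.approx(mean_s, rel=0.01)
        assert post.E_beta == pytest.approx(mean_beta, rel=0.01)

    def test_update_equations_match_conjugate_posterior(self):
        # with alpha pinned, q(s, beta) is the exact NIG posterior
        a0 = b0 = 3.0
        alpha = 1.0
        s, C, a_hat, b_hat = vb_update_s_beta(
            np.array([[1.0]]), np.array([1.0]), alpha, a0, b0
        )
        mean_s, mean_beta, _ = conjugate_toy_quadrature(a0, b0, alpha)
        assert s[0] == pytest.approx(mean_s, rel=1e-3)
        assert a_hat / b_hat == pytest.approx(mean_beta, rel=1e-3)

    def test_elbo_bounded_by_log_evidence(self):
        # free-alpha 1-D toy: the bound L(q) <= ln p(y) must hold
        from scipy.special import gammaln as gl

        a0 = b0 = 3.0
        c0 = d0 = 2.0

        def log_joint(s, beta, alpha, y=1.0):
            return (
                0.5 * np.log(beta / (2 * np.pi))
                - 0.5 * beta * (y - s) ** 2
                + 0.5 * np.log(beta * alpha / (2 * np.pi))
                - 0.5 * beta * alpha * s**2
                + a0 * np.log(b0)
                - gl(a0)
                + (a0 - 1) * np.log(beta)
                - b0 * beta
                + c0 * np.log(d0)
                - gl(c0)
                + (c0 - 1) * np.log(alpha)
                - d0 * alpha
            )

        s = np.linspace(-4, 5, 301)
        lb = np.linspace(-10, 10, 301)
        la = np.linspace(-10, 10, 301)
        S, B, Al = np.meshgrid(s, np.exp(lb), np.exp(la), indexing="ij")
        lj = log_joint(S, B, Al) + np.log(B) + np.log(Al)
        m = lj.max()
        z = np.trapezoid(
            np.trapezoid(np.trapezoid(np.exp(lj - m), la, axis=2), lb, axis=1), s
        )
        ln_p = np.log(z) + m
        _, post, trace, _ = vblr_fit(
            np.array([[1.0]]), np.array([1.0]), NIGPrior(a0, b0, c0, d0)
        )
        assert trace[-1] <= ln_p + 1e-6
        # the gap is the (non-negative) KL divergence of the approximation
        assert ln_p - trace[-1] >= -1e-6


class TestFit:
    def test_elbo_nondecreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.standard_normal((8, 5))
            b = rng.standard_normal(8)
            _, _, trace, _ = vblr_fit(A, b)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_final_trace_matches_public_elbo(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((10, 4))
        b = rng.standard_normal(10)
        prior = NIGPrior()
        s, post, trace, _ = vblr_fit(A, b, prior)
        assert elbo(A, b, post, prior) == pytest.approx(trace[-1], rel=1e-9)

    def test_pinned_alpha_is_ridge(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((12, 6))
        b = rng.standard_normal(12)
        s, *_ = vblr_fit(A, b, fixed_alpha=0.8)
        assert np.allclose(s, solve_tikhonov(A, b, 0.8), rtol=1e-9)

    def test_noise_free_limit_large_beta(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((15, 4))
        b = A @ rng.standard_normal(4)
        s, post, _, _ = vblr_fit(A, b)
        assert np.allclose(s, np.linalg.lstsq(A, b, rcond=None)[0], atol=1e-6)
        assert post.E_beta > 1e6

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((9, 5))
        b = rng.standard_normal(9)
        s1, _, t1, _ = vblr_fit(A, b)
        s2, _, t2, _ = vblr_fit(A, b)
        assert np.array_equal(s1, s2)
        assert np.array_equal(t1, t2)

    def test_posterior_contraction_with_duplicated_rows(self):
        # more copies of the same signal-bearing data shrink the posterior
        rng = np.random.default_rng(7)
        A = rng.standard_normal((6, 3))
        b = A @ rng.standard_normal(3) + 0.3 * rng.standard_normal(6)
        traces = []
        for k in (1, 2, 4):
            Ak = np.tile(A, (k, 1))
            bk = np.tile(b, k)
            _, post, _, _ = vblr_fit(Ak, bk, store_covariance=True)
            traces.append(np.trace(post.C_hat) / post.E_beta)
        assert traces[0] > traces[1] > traces[2]


class TestEstimator:
    def test_multi_target_and_params(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((20, 7))
        Y = rng.standard_normal((20, 3))
        est = VBLinearRegression().fit(A, Y)
        assert est.coef_.shape == (3, 7)
        assert len(est.posteriors_) == 3
        assert est.get_params()["rel_tol"] == 1e-5
        assert est.predict(A).shape == (20, 3)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            VBLinearRegression(a0=-1.0).fit(np.eye(2), np.ones(2))
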