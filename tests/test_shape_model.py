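"""Shape-statistics estimation, prior sampling and prior density."""

import numpy as np
import pytest
from scipy import stats

from ellipstack.errors import (
    InsufficientDataError,
    InvalidParameterError,
    ShapeMismatchError,
)
from ellipstack.geometry import EllipseStack
from ellipstack.model import ShapeModelResults, StackedEllipseModel, train
from ellipstack.registration import CenterCurve
from conftest import smooth_stack


def flat_curve():
    return CenterCurve(coeffs=np.zeros((3, 2)))


def stack_on_unit_grid(theta, alpha, phi):
    L = len(phi)
    return EllipseStack.from_arrays(np.linspace(0, 1, L), theta, alpha, phi)


def known_model(L=5, n_train=23) -> ShapeModelResults:
    """A hand-specified model used as a sampling ground truth."""
    t = np.linspace(0, 1, L)
    prof = np.sqrt(1 - 0.8 * (2 * t - 1) ** 2)
    return ShapeModelResults(
        L=L,
        n_train=n_train,
        position_mode="eta",
        t_grid=t,
        mu_eta=np.column_stack([0.1 * np.sin(np.pi * t), np.zeros(L)]),
        sigma_eta=np.full((L, 2), 0.05),
        mu_theta=np.zeros((L, 3)),
        sigma_theta=np.zeros((L, 3)),
        Sigma_theta=np.zeros((L, 3, 3)),
        mu_a=np.log(np.column_stack([0.9 * prof, 0.7 * prof])),
        sigma_a=np.full((L, 2), 0.08),
        mu_phi=np.full(L, 0.2),
        sigma_phi=np.full(L, 0.1),
    )


class TestTrain:
    def test_identical_stacks_give_zero_variance_and_exact_mean(self):
        s = stack_on_unit_grid(
            np.zeros((5, 2)), np.full((5, 2), 3.0), np.full(5, 0.3)
        )
        res = train([s] * 4, [flat_curve()] * 4, L=5)
        assert np.allclose(res.mu_eta, 0.0)
        assert np.allclose(np.exp(res.mu_a), 3.0)
        assert np.allclose(res.mu_phi, 0.3)
        assert np.allclose(res.sigma_eta, 0.0)
        assert np.allclose(res.sigma_a, 0.0)
        assert np.allclose(res.sigma_phi, 0.0)

    def test_alpha_mean_is_geometric(self):
        a = stack_on_unit_grid(np.zeros((3, 2)), np.full((3, 2), 2.0), np.zeros(3))
        b = stack_on_unit_grid(np.zeros((3, 2)), np.full((3, 2), 8.0), np.zeros(3))
        res = train([a, b], [flat_curve()] * 2, L=3)
        assert np.allclose(np.exp(res.mu_a), 4.0)  # geometric, not arithmetic

    def test_permutation_invariance_exact(self, rng):
        stacks = [
            stack_on_unit_grid(
                rng.normal(0, 1, (4, 2)), rng.uniform(1, 3, (4, 2)), rng.normal(0, 0.1, 4)
            )
            for _ in range(6)
        ]
        curves = [flat_curve()] * 6
        r1 = train(stacks, curves, L=4)
        order = [3, 0, 5, 1, 4, 2]
        r2 = train([stacks[i] for i in order], curves, L=4)
        for name in ("mu_eta", "sigma_eta", "mu_a", "sigma_a", "mu_phi", "sigma_phi"):
            assert np.array_equal(getattr(r1, name), getattr(r2, name))

    def test_single_case_rejected(self):
        s = stack_on_unit_grid(np.zeros((3, 2)), np.ones((3, 2)), np.zeros(3))
        with pytest.raises(InsufficientDataError):
            train([s], [flat_curve()], L=3)

    def test_mismatched_L_rejected(self):
        s3 = stack_on_unit_grid(np.zeros((3, 2)), np.ones((3, 2)), np.zeros(3))
        s4 = stack_on_unit_grid(np.zeros((4, 2)), np.ones((4, 2)), np.zeros(4))
        with pytest.raises(ShapeMismatchError):
            train([s3, s4], [flat_curve()] * 2, L=3)

    def test_moment_recovery_from_known_generator(self):
        # replicated populations of 23 draws from a known model: slice means
        # within 3 standard errors and variances within the chi^2 99% band
        # at (at least) their nominal rates
        truth = known_model()
        N = 23
        lo = stats.chi2.ppf(0.005, N - 1) / (N - 1)
        hi = stats.chi2.ppf(0.995, N - 1) / (N - 1)
        checks_mu, checks_sig = [], []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            stacks = [truth.sample(rng) for _ in range(N)]
            res = train(stacks, [flat_curve()] * N, L=truth.L)
            for est_mu, true_mu, true_sd in (
                (res.mu_eta, truth.mu_eta, truth.sigma_eta),
                (res.mu_a, truth.mu_a, truth.sigma_a),
                (res.mu_phi, truth.mu_phi, truth.sigma_phi),
            ):
                z = (est_mu - true_mu) / (true_sd / np.sqrt(N))
                checks_mu.append(np.abs(z) <= 3.0)
            for est_sd, true_sd in (
                (res.sigma_eta, truth.sigma_eta),
                (res.sigma_a, truth.sigma_a),
                (res.sigma_phi, truth.sigma_phi),
            ):
                ratio = est_sd**2 / true_sd**2
                checks_sig.append((ratio >= lo) & (ratio <= hi))
        frac_mu = np.mean(np.concatenate([c.ravel() for c in checks_mu]))
        frac_sig = np.mean(np.concatenate([c.ravel() for c in checks_sig]))
        assert frac_mu >= 0.97  # nominal pass rate 99.7%
        assert frac_sig >= 0.95  # nominal pass rate 99%

    def test_estimator_consistency_with_sample_size(self):
        # the median absolute estimation error should shrink roughly like
        # 1/sqrt(N): going 23 -> 230 must at least halve it
        truth = known_model()
        errs = {}
        for N in (23, 230):
            reps = []
            for r in range(20):
                rng = np.random.default_rng(1000 * N + r)
                stacks = [truth.sample(rng) for _ in range(N)]
                res = train(stacks, [flat_curve()] * N, L=truth.L)
                reps.append(np.median(np.abs(res.mu_a - truth.mu_a)))
            errs[N] = np.median(reps)
        assert errs[230] <= 0.5 * errs[23]


class TestMeanShapeAndSampling:
    def test_mean_shape_reproduces_training_stack(self):
        s = stack_on_unit_grid(
            np.tile([0.5, -0.2], (5, 1)), np.full((5, 2), 3.0), np.full(5, 0.3)
        )
        res = train([s] * 3, [flat_curve()] * 3, L=5)
        m = res.mean_shape()
        assert np.allclose(m.theta, s.theta, atol=1e-12)
        assert np.allclose(m.alpha, s.alpha, atol=1e-12)
        assert np.allclose(m.phi, s.phi, atol=1e-12)

    def test_zero_variance_samples_equal_mean(self):
        truth = known_model()
        degenerate = ShapeModelResults(
            L=truth.L, n_train=truth.n_train, position_mode="eta",
            t_grid=truth.t_grid, mu_eta=truth.mu_eta,
            sigma_eta=np.zeros((truth.L, 2)), mu_theta=truth.mu_theta,
            sigma_theta=truth.sigma_theta, Sigma_theta=truth.Sigma_theta,
            mu_a=truth.mu_a, sigma_a=np.zeros((truth.L, 2)),
            mu_phi=truth.mu_phi, sigma_phi=np.zeros(truth.L),
        )
        s = degenerate.sample(np.random.default_rng(0))
        m = degenerate.mean_shape()
        assert np.allclose(s.theta, m.theta)
        assert np.allclose(s.alpha, m.alpha)
        assert np.allclose(s.phi, m.phi)

    def test_sampled_log_alpha_clt(self):
        truth = known_model()
        rng = np.random.default_rng(5)
        draws = np.array([truth.sample(rng).alpha[2, 0] for _ in range(10**4)])
        la = np.log(draws)
        se = truth.sigma_a[2, 0] / np.sqrt(la.size)
        assert abs(la.mean() - truth.mu_a[2, 0]) < 4 * se
        assert np.all(draws > 0)

    def test_sampling_reproducible_under_seed(self):
        truth = known_model()
        s1 = truth.sample(np.random.default_rng(9))
        s2 = truth.sample(np.random.default_rng(9))
        assert np.array_equal(s1.theta, s2.theta)
        assert np.array_equal(s1.alpha, s2.alpha)


class TestPriorLogDensity:
    def test_closed_form_at_mean_shape(self):
        truth = known_model()
        val = truth.prior_logdensity(truth.mean_shape())
        expected = 0.0
        for sd in (truth.sigma_eta.ravel(), truth.sigma_a.ravel(), truth.sigma_phi):
            expected += np.sum(-0.5 * np.log(2 * np.pi * np.asarray(sd) ** 2))
        expected -= np.sum(truth.mu_a)  # log-normal Jacobian at alpha = exp(mu_a)
        assert val == pytest.approx(expected, abs=1e-9)

    def test_k_sigma_shift_changes_by_half_k_squared(self):
        truth = known_model()
        m = truth.mean_shape()
        base = truth.prior_logdensity(m)
        for k in (1.0, 2.5):
            theta = m.theta.copy()
            theta[1, 0] += k * truth.sigma_eta[1, 0]
            shifted = EllipseStack.from_arrays(m.z, theta, m.alpha, m.phi)
            assert truth.prior_logdensity(shifted) - base == pytest.approx(
                -0.5 * k**2, abs=1e-9
            )

    def test_matches_scipy_density_product_on_toy(self, rng):
        truth = known_model(L=3)
        s = truth.sample(rng)
        val = truth.prior_logdensity(s)
        expected = 0.0
        for l in range(3):
            for j in range(2):
                expected += stats.norm.logpdf(
                    s.theta[l, j], truth.mu_eta[l, j], truth.sigma_eta[l, j]
                )
                expected += stats.lognorm.logpdf(
                    s.alpha[l, j],
                    s=truth.sigma_a[l, j],
                    scale=np.exp(truth.mu_a[l, j]),
                )
            expected += stats.norm.logpdf(s.phi[l], truth.mu_phi[l], truth.sigma_phi[l])
        assert val == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_alpha_outside_support(self):
        truth = known_model(L=3)
        arr = np.zeros((3, 5))
        arr[:, 2:4] = [[1.0, 1.0], [1.0, -0.5], [1.0, 1.0]]
        assert truth.prior_logdensity(arr) == float("-inf")

    def test_zero_sigma_sentinel_never_nan(self):
        truth = known_model(L=3)
        degenerate = ShapeModelResults(
            L=3, n_train=2, position_mode="eta", t_grid=truth.t_grid,
            mu_eta=truth.mu_eta, sigma_eta=np.zeros((3, 2)),
            mu_theta=truth.mu_theta, sigma_theta=truth.sigma_theta,
            Sigma_theta=truth.Sigma_theta, mu_a=truth.mu_a,
            sigma_a=truth.sigma_a, mu_phi=truth.mu_phi, sigma_phi=truth.sigma_phi,
        )
        at_mean = degenerate.prior_logdensity(degenerate.mean_shape())
        assert np.isfinite(at_mean)  # point-mass convention: 0 contribution
        m = degenerate.mean_shape()
        theta = m.theta.copy()
        theta[0, 0] += 0.1
        off = degenerate.prior_logdensity(
            EllipseStack.from_arrays(m.z, theta, m.alpha, m.phi)
        )
        assert off == float("-inf") and not np.isnan(off)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        truth = known_model()
        path = tmp_path / "model.json"
        truth.save(path)
        back = ShapeModelResults.load(path)
        for name in (
            "t_grid", "mu_eta", "sigma_eta", "mu_theta", "sigma_theta",
            "Sigma_theta", "mu_a", "sigma_a", "mu_phi", "sigma_phi",
        ):
            assert np.allclose(getattr(back, name), getattr(truth, name), atol=0)
        assert back.L == truth.L and back.n_train == truth.n_train

    def test_loader_validates_kind(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"kind": "something-else"}')
        with pytest.raises(InvalidParameterError):
            ShapeModelResults.load(path)

    def test_summary_mentions_dimensions(self):
        truth = known_model()
        s = truth.summary()
        assert "L = 5" in s and "N = 23" in s
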