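import numpy as np
import pytest
from scipy.optimize import minimize

from imaware import phi
from oracles import gaussian_entropy_grid


def random_model(rng, n=3, tau=1):
    """Random valid lagged Gaussian model from a Wishart-style joint."""
    a = rng.standard_normal((2 * n, 2 * n))
    joint = a @ a.T / (2 * n) + 0.2 * np.eye(2 * n)
    return phi.LaggedGaussianModel(joint[n:, n:], joint[:n, :n],
                                   joint[:n, n:], tau=tau)


def independent_model(n=3, lag=0.3):
    return phi.LaggedGaussianModel(np.eye(n), np.eye(n), lag * np.eye(n), tau=1)


def rho_model(rho=0.5):
    """Two channels, instantaneous correlation rho, no lagged dependence."""
    c = np.array([[1.0, rho], [rho, 1.0]])
    return phi.LaggedGaussianModel(c.copy(), c.copy(), np.zeros((2, 2)), tau=1)


class TestEstimateLaggedCov:
    def test_white_noise_cross_cov_vanishes(self, rng):
        x = rng.standard_normal((3, 20000))
        m = phi.estimate_lagged_cov(x, tau=2)
        assert np.abs(m.cov_cross).max() < 0.05

    def test_ar1_autocovariance(self, rng):
        a = 0.8
        e = rng.standard_normal(200000)
        x = np.empty_like(e)
        x[0] = e[0]
        for t in range(1, len(e)):
            x[t] = a * x[t - 1] + e[t]
        for tau in (1, 3):
            m = phi.estimate_lagged_cov(x[None, :], tau=tau)
            assert m.cov_cross[0, 0] / m.cov_past[0, 0] == pytest.approx(
                a ** tau, abs=0.02)

    def test_zero_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            phi.estimate_lagged_cov(rng.standard_normal((2, 100)), tau=0)

    def test_partition_must_cover(self):
        with pytest.raises(ValueError):
            phi.LaggedGaussianModel(np.eye(2), np.eye(2), np.zeros((2, 2)),
                                    tau=1, partition=[[0]])


class TestGaussianEntropy:
    def test_unit_scalar(self):
        assert phi.gaussian_entropy(np.eye(1)) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e))

    def test_block_additivity(self, rng):
        a = rng.standard_normal((2, 2))
        cov_a = a @ a.T + np.eye(2)
        b = rng.standard_normal((3, 3))
        cov_b = b @ b.T + np.eye(3)
        block = np.block([[cov_a, np.zeros((2, 3))], [np.zeros((3, 2)), cov_b]])
        assert phi.gaussian_entropy(block) == pytest.approx(
            phi.gaussian_entropy(cov_a) + phi.gaussian_entropy(cov_b))

    def test_scaling_shift(self):
        c = 4.0
        assert (phi.gaussian_entropy(c * np.eye(1))
                - phi.gaussian_entropy(np.eye(1))) == pytest.approx(0.5 * np.log(c))

    def test_non_pd_rejected(self):
        with pytest.raises(Exception):
            phi.gaussian_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_grid_oracle_agreement(self, rng):
        a = rng.standard_normal((2, 2))
        cov = a @ a.T + np.eye(2)
        assert phi.gaussian_entropy(cov) == pytest.approx(
            gaussian_entropy_grid(cov), abs=1e-6)


class TestMutualInformation:
    def test_zero_for_no_cross(self):
        m = phi.LaggedGaussianModel(np.eye(2), np.eye(2), np.zeros((2, 2)), tau=1)
        assert phi.mutual_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        rho = 0.6
        m = phi.LaggedGaussianModel(np.eye(1), np.eye(1),
                                    np.array([[rho]]), tau=1)
        assert phi.mutual_information(m) == pytest.approx(-0.5 * np.log(1 - rho ** 2))

    def test_nonnegative(self, rng):
        for _ in range(20):
            assert phi.mutual_information(random_model(rng)) >= 0.0


class TestClosedForms:
    def test_all_measures_zero_for_independent_channels(self):
        m = independent_model()
        for name in phi.PHI_MEASURES:
            assert phi.compute_phi(m, name) == pytest.approx(0.0, abs=1e-9), name

    def test_phi_mi_two_channel_value(self):
        # two independent time slices each contribute -0.5 log(1 - rho^2)
        assert phi.phi_MI(rho_model(0.5)) == pytest.approx(
            -np.log(1 - 0.25), abs=1e-6)

    def test_phi_h_two_channel_value(self):
        # conditioning is vacuous without lagged dependence
        assert phi.phi_H(rho_model(0.5)) == pytest.approx(
            -0.5 * np.log(1 - 0.25), abs=1e-6)

    def test_phi_mi_monotone_in_rho(self):
        vals = [phi.phi_MI(rho_model(r)) for r in (0.1, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(vals) > 0)

    def test_phi_mi_grid_oracle(self):
        """phi_MI of a 2-channel model against dense-grid entropies."""
        m = rho_model(0.5)
        joint = m.joint
        parts = [np.ix_([0, 2], [0, 2]), np.ix_([1, 3], [1, 3])]
        oracle = (sum(gaussian_entropy_grid(joint[p]) for p in parts)
                  - gaussian_entropy_grid(joint))
        assert phi.phi_MI(m) == pytest.approx(oracle, abs=1e-3)


class TestPhiStar:
    def test_matched_decoder_recovers_mi(self):
        # independent channels: I*(beta) peaks at I, so phi* = 0
        m = independent_model(n=2, lag=0.5)
        assert phi.phi_star(m) == pytest.approx(0.0, abs=1e-7)

    def test_bounds_on_random_models(self, rng):
        for _ in range(100):
            m = random_model(rng)
            star = phi.phi_star(m)
            assert -1e-9 <= star <= phi.mutual_information(m) + 1e-9

    def test_monte_carlo_quadrature_oracle(self, rng):
        """I*(beta) closed form against a sampled mismatched-decoding value
        with the decoder normalizer integrated on a Gauss-Hermite grid."""
        m = random_model(rng, n=2)
        a_d, sigma_d = phi._part_regression(m)
        beta = 0.7
        closed = phi._mismatched_information(m, beta, a_d, sigma_d)

        n_mc = 20000
        joint = m.joint
        L = np.linalg.cholesky(joint)
        z = rng.standard_normal((n_mc, 4)) @ L.T
        x, y = z[:, :2], z[:, 2:]
        sdi = np.linalg.inv(sigma_d)
        # numerator: beta log q(y|x) up to the q-normalizer (cancels below)
        resid = y - x @ a_d.T
        num = -0.5 * beta * np.einsum("ni,ij,nj->n", resid, sdi, resid)
        # denominator: log int p(x') q(y|x')^beta dx' on a Gauss-Hermite grid
        nodes, weights = np.polynomial.hermite_e.hermegauss(24)
        g1, g2 = np.meshgrid(nodes, nodes, indexing="ij")
        u = np.stack([g1.ravel(), g2.ravel()], axis=1)
        xp = u @ np.linalg.cholesky(m.cov_past).T
        wgt = (np.outer(weights, weights).ravel()) / (2 * np.pi)
        mu = xp @ a_d.T                       # grid of decoder means
        q = np.einsum("gi,ij,gj->g", mu, sdi, mu)
        cross = y @ sdi @ mu.T                # n_mc x grid
        log_k = -0.5 * beta * (q[None, :] - 2 * cross)
        log_k += np.log(wgt)[None, :]
        mx = log_k.max(axis=1, keepdims=True)
        den = (mx[:, 0] + np.log(np.exp(log_k - mx).sum(axis=1))
               - 0.5 * beta * np.einsum("ni,ij,nj->n", y, sdi, y))
        mc = float(np.mean(num - den))
        se = float(np.std(num - den) / np.sqrt(n_mc))
        assert closed == pytest.approx(mc, abs=max(4 * se, 0.015))


class TestPhiG:
    def test_block_diagonal_regression_on_manifold(self):
        # diagonal regression, independent innovations: already split
        a = np.diag([0.6, -0.3, 0.4])
        sp = np.eye(3)
        st = a @ sp @ a.T + np.eye(3)
        m = phi.LaggedGaussianModel(st, sp, (a @ sp).T, tau=1)
        assert phi.phi_G(m) == pytest.approx(0.0, abs=1e-9)

    def test_bounds_on_random_models(self, rng):
        for _ in range(100):
            m = random_model(rng)
            g = phi.phi_G(m)
            assert -1e-9 <= g <= phi.mutual_information(m) + 1e-9

    def test_multistart_optimizer_oracle(self, rng):
        """Alternating minimization against generic numerical minimization of
        the residual log-determinant over the diagonal regression entries."""
        m = random_model(rng, n=3)
        _, sigma_e = phi._full_regression(m)
        logdet_e = np.linalg.slogdet(sigma_e)[1]

        def objective(diag):
            a = np.diag(diag)
            r = phi._residual_cov(m, a)
            sign, ld = np.linalg.slogdet(r)
            return 0.5 * (ld - logdet_e) if sign > 0 else 1e6

        best = np.inf
        for _ in range(8):
            res = minimize(objective, rng.standard_normal(3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
            best = min(best, res.fun)
        assert phi.phi_G(m) == pytest.approx(best, abs=1e-6)


class TestTimecourse:
    def test_window_counts(self):
        spans = phi.timecourse_windows()
        assert len(spans) == 65
        before = [s for s in spans if s[1] <= 375]
        assert len(before) == 27  # hence 38 windows counted after

    def test_stationary_input_flat(self, rng):
        x = rng.standard_normal((3, 750))
        tc = phi.phi_timecourse(x, "phi_MI", taus=(1, 2))
        rel = tc["value"].std() / tc["value"].mean()
        assert rel < 1.0  # no trend beyond sampling error

    def test_single_tau_reduces_to_window_phi(self, rng):
        x = rng.standard_normal((2, 750))
        tc = phi.phi_timecourse(x, "phi_MI", taus=(3,))
        start, stop = phi.timecourse_windows()[0]
        direct = phi.phi_MI(phi.estimate_lagged_cov(x[:, start:stop], 3))
        assert tc["value"].iloc[0] == pytest.approx(direct, abs=1e-12)

    def test_coupling_step_down_detected(self):
        """An instantaneous-correlation step at the reference lowers the
        tau-averaged multi-information afterwards."""
        rng = np.random.default_rng(4)
        n = 750
        rho = np.full(n, 0.6)
        rho[n // 2:] = 0.1
        g = rng.standard_normal(n)
        x = np.sqrt(rho) * g + np.sqrt(1 - rho) * rng.standard_normal((4, n))
        tc = phi.phi_timecourse(x, "phi_MI", taus=(1, 2, 3))
        means = tc.groupby("condition")["value"].mean()
        assert means["before"] > means["after"]

    def test_short_window_rejected(self, rng):
        x = rng.standard_normal((6, 750))
        with pytest.raises(ValueError):
            phi.phi_timecourse(x, "phi_MI", taus=(100,))
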