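"""Integrated-information measures on stationary Gaussian time series.

All four measures quantify, in nats, how much the joint dynamics of a
multichannel signal exceed what a partitioned (disconnected) surrogate could
carry.  They operate on a lagged Gaussian model: the covariance of the present
state, the covariance of the state tau samples earlier, and their
cross-covariance, together with a partition of the channels (atomic by
default: every channel its own part).

* multi-information (phi_MI): total correlation of the joint past+present
  vector across parts; zero iff the parts are fully independent.
* stochastic interaction (phi_H): sum of part-wise conditional entropies of
  the present given the part's own past, minus the joint conditional entropy.
* decoding-based integrated information (phi_star): mutual information minus
  the mismatched-decoding information of a decoder that assumes independent
  parts, maximized over the decoding exponent beta.
* geometric integrated information (phi_G): minimum Kullback-Leibler
  divergence to the manifold of models whose present-on-past regression has
  no cross-part entries (residual correlations remain free).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import LinAlgError
from scipy import linalg
from scipy.optimize import minimize_scalar

LOG_2PI_E = np.log(2.0 * np.pi * np.e)


def atomic_partition(n: int) -> list[list[int]]:
    return [[i] for i in range(n)]


@dataclass
class LaggedGaussianModel:
    """Second-order description of (past, present) at lag tau."""

    cov_present: np.ndarray      # Sigma_t, channels x channels
    cov_past: np.ndarray         # Sigma_p
    cov_cross: np.ndarray        # Cov(past, present): rows past, cols present
    tau: int
    partition: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        n = self.cov_present.shape[0]
        if not self.partition:
            self.partition = atomic_partition(n)
        flat = sorted(i for part in self.partition for i in part)
        if flat != list(range(n)):
            raise ValueError("partition must cover every channel exactly once")

    @property
    def n_channels(self) -> int:
        return self.cov_present.shape[0]

    @property
    def joint(self) -> np.ndarray:
        """Covariance of the stacked (past, present) vector."""
        top = np.hstack([self.cov_past, self.cov_cross])
        bot = np.hstack([self.cov_cross.T, self.cov_present])
        return np.vstack([top, bot])


def _ridge(a: np.ndarray, eps_scale: float = 1e-8, max_tries: int = 3) -> np.ndarray:
    """Symmetrize and, if needed, add an escalating trace-scaled ridge."""
    a = 0.5 * (a + a.T)
    eps = eps_scale * np.trace(a) / a.shape[0]
    for k in range(max_tries + 1):
        try:
            linalg.cholesky(a, lower=True)
            return a
        except LinAlgError:
            warnings.warn("near-singular covariance: adding shrinkage ridge")
            a = a + (eps * 10.0 ** k) * np.eye(a.shape[0])
    raise LinAlgError("covariance not positive definite after shrinkage")


def estimate_lagged_cov(x: np.ndarray, tau: int,
                        partition: list[list[int]] | None = None) -> LaggedGaussianModel:
    """Sample lagged covariances of a channels x samples array."""
    x = np.asarray(x, float)
    n_ch, n_s = x.shape
    if tau < 1:
        raise ValueError("tau must be a positive number of samples")
    if n_s <= n_ch + tau:
        raise ValueError("too few samples for the channel count and lag")
    past = x[:, :-tau]
    pres = x[:, tau:]
    past = past - past.mean(axis=1, keepdims=True)
    pres = pres - pres.mean(axis=1, keepdims=True)
    m = past.shape[1] - 1
    cov_p = _ridge(past @ past.T / m)
    cov_t = _ridge(pres @ pres.T / m)
    cov_x = past @ pres.T / m
    model = LaggedGaussianModel(cov_t, cov_p, cov_x, tau,
                                partition or atomic_partition(n_ch))
    _ridge(model.joint)  # validate joint positive definiteness
    return model


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy 0.5 log((2 pi e)^n det Sigma), in nats."""
    cov = np.atleast_2d(np.asarray(cov, float))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise LinAlgError("covariance must be positive definite")
    n = cov.shape[0]
    return float(0.5 * (n * LOG_2PI_E + logdet))


def mutual_information(model: LaggedGaussianModel) -> float:
    """I(past; present) = H(present) + H(past) - H(joint), nats."""
    mi = (gaussian_entropy(model.cov_present) + gaussian_entropy(model.cov_past)
          - gaussian_entropy(_ridge(model.joint, 0.0, 1)))
    return max(float(mi), 0.0)


def _clip(value: float, tol: float = 1e-9) -> float:
    """Clip tiny numerically negative results to zero."""
    if value < -tol:
        warnings.warn(f"negative integrated-information value {value:.3e} clipped")
    return max(float(value), 0.0)


def phi_MI(model: LaggedGaussianModel) -> float:
    """Total correlation of the joint past+present vector across parts.

    Sum over parts of H([past_i, present_i]) minus H([past, present]); the
    tau-dependence enters through each part's own past-present coupling.
    """
    joint = model.joint
    n = model.n_channels
    h_parts = 0.0
    for part in model.partition:
        idx = np.array(part)
        sel = np.concatenate([idx, idx + n])
        h_parts += gaussian_entropy(joint[np.ix_(sel, sel)])
    return _clip(h_parts - gaussian_entropy(_ridge(joint, 0.0, 1)))


def _conditional_cov(cov_y: np.ndarray, cov_x: np.ndarray, cov_xy: np.ndarray) -> np.ndarray:
    """Cov(Y | X) via the Schur complement."""
    sol = linalg.solve(cov_x, cov_xy, assume_a="pos")
    return cov_y - cov_xy.T @ sol


def phi_H(model: LaggedGaussianModel) -> float:
    """Stochastic interaction: sum_i H(present_i | past_i) - H(present | past)."""
    h_joint = gaussian_entropy(
        _ridge(_conditional_cov(model.cov_present, model.cov_past, model.cov_cross), 0.0, 1))
    h_parts = 0.0
    for part in model.partition:
        ix = np.ix_(part, part)
        cond = _conditional_cov(model.cov_present[ix], model.cov_past[ix],
                                model.cov_cross[ix])
        h_parts += gaussian_entropy(np.atleast_2d(cond))
    return _clip(h_parts - h_joint)


def _full_regression(model: LaggedGaussianModel):
    """A = regression of present on past (present = A past + E), Sigma_E."""
    a = linalg.solve(model.cov_past, model.cov_cross, assume_a="pos").T
    sigma_e = model.cov_present - a @ model.cov_cross
    return a, _ridge(sigma_e, 1e-12, 2)

def _part_regression(model: LaggedGaussianModel):
    """Block-diagonal decoder: per-part regressions and residual covariances."""
    n = model.n_channels
    a_d = np.zeros((n, n))
    sigma_d = np.zeros((n, n))
    for part in model.partition:
        ix = np.ix_(part, part)
        a_i = linalg.solve(model.cov_past[ix], model.cov_cross[ix], assume_a="pos").T
        a_d[ix] = a_i
        sigma_d[ix] = model.cov_present[ix] - a_i @ model.cov_cross[ix]
    return a_d, _ridge(sigma_d, 1e-12, 2)


def _mismatched_information(model: LaggedGaussianModel, beta: float,
                            a_d: np.ndarray, sigma_d: np.ndarray) -> float:
    """Gaussian mismatched-decoding information I*(beta), nats.

    The decoder posterior uses q(present|past)^beta with the part-wise
    conditional model q; expectations are taken under the true joint.
    """
    sp, st, sx = model.cov_past, model.cov_present, model.cov_cross
    sdi = linalg.inv(sigma_d)
    # E[(y - A_D x)' Sigma_D^-1 (y - A_D x)] cross terms vs E[y' Sigma_D^-1 y]
    t1 = np.trace(sdi @ (sx.T @ a_d.T + a_d @ sx - a_d @ sp @ a_d.T))
    q = linalg.inv(sp) + beta * (a_d.T @ sdi @ a_d)
    sign, logdet_q = np.linalg.slogdet(q)
    if sign <= 0:
        raise LinAlgError("posterior precision not positive definite")
    sign_p, logdet_p = np.linalg.slogdet(sp)
    t2 = np.trace(linalg.solve(q, a_d.T @ sdi @ st @ sdi @ a_d, assume_a="pos"))
    return float(0.5 * beta * t1 - 0.5 * beta ** 2 * t2
                 + 0.5 * (logdet_p + logdet_q))


def phi_star(model: LaggedGaussianModel, beta_max: float = 20.0,
             xatol: float = 1e-8) -> float:
    """Decoding-based integrated information, I - max_beta I*(beta).

    The scalar maximization over the decoding exponent beta on [0, beta_max]
    uses bounded Brent search; I*(1) equals I when the partitioned decoder is
    already exact, so phi_star vanishes for independent parts.
    """
    mi = mutual_information(model)
    a_d, sigma_d = _part_regression(model)
    res = minimize_scalar(lambda b: -_mismatched_information(model, b, a_d, sigma_d),
                          bounds=(0.0, beta_max), method="bounded",
                          options={"xatol": xatol, "maxiter": 500})
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"beta optimization failed: {res.message}")
    i_star = max(-res.fun, 0.0)
    return _clip(mi - i_star)


def _support_matrix(partition: list[list[int]], n: int) -> list[tuple[int, int]]:
    support = []
    for part in partition:
        for i in part:
            for j in part:
                support.append((i, j))
    return support


def _residual_cov(model: LaggedGaussianModel, a: np.ndarray) -> np.ndarray:
    sp, st, sx = model.cov_past, model.cov_present, model.cov_cross
    return st - sx.T @ a.T - a @ sx + a @ sp @ a.T


def phi_G(model: LaggedGaussianModel, tol: float = 1e-10,
          max_iter: int = 1000) -> float:
    """Geometric integrated information.

    Minimum KL divergence from the full model to Gaussian models whose
    present-on-past regression is block-diagonal over the partition (the
    past marginal is shared and the residual covariance is unconstrained).
    Solved by alternating minimization: given the residual covariance, the
    support-restricted regression solves a linear system; given the
    regression, the optimal residual covariance is the actual residual
    covariance.  Converges when the divergence changes by less than ``tol``.
    """
    _, sigma_e = _full_regression(model)
    sign, logdet_e = np.linalg.slogdet(sigma_e)
    n = model.n_channels
    support = _support_matrix(model.partition, n)
    a, _ = _part_regression(model)  # feasible start
    sp = model.cov_past
    kl_prev = np.inf
    for _ in range(max_iter):
        sigma_q = _ridge(_residual_cov(model, a), 1e-12, 2)
        sign_q, logdet_q = np.linalg.slogdet(sigma_q)
        kl = 0.5 * (logdet_q - logdet_e)
        if abs(kl_prev - kl) < tol:
            return _clip(kl)
        kl_prev = kl
        # solve (W A Sigma_p)_support = (W Sigma_xy')_support for A on support
        w = linalg.inv(sigma_q)
        rhs_full = w @ model.cov_cross.T
        k = len(support)
        mat = np.empty((k, k))
        rhs = np.empty(k)
        for r, (i, j) in enumerate(support):
            rhs[r] = rhs_full[i, j]
            for c, (p, q) in enumerate(support):
                mat[r, c] = w[i, p] * sp[q, j]
        sol = linalg.solve(mat, rhs)
        a = np.zeros((n, n))
        for val, (i, j) in zip(sol, support):
            a[i, j] = val
    raise RuntimeError("geometric phi did not converge within the iteration cap")


_MEASURES = {"phi_star": phi_star, "phi_G": phi_G, "phi_H": phi_H, "phi_MI": phi_MI}
PHI_MEASURES = tuple(_MEASURES)


def compute_phi(model: LaggedGaussianModel, measure: str) -> float:
    try:
        fn = _MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; one of {PHI_MEASURES}")
    return fn(model)


# -- time-course construction -------------------------------------------------

PHI_SR = 125.0
PHI_EPOCH_SAMPLES = 750
PHI_WINDOW = 110     # samples (0.88 s)
PHI_STRIDE = 10      # samples (80 ms)
DEFAULT_TAUS = tuple(range(1, 11))


def timecourse_windows(n_samples: int = PHI_EPOCH_SAMPLES, window: int = PHI_WINDOW,
                       stride: int = PHI_STRIDE) -> list[tuple[int, int]]:
    """(start, stop) spans of the sliding analysis windows.

    Defaults give 65 windows over a 750-sample epoch; 27 lie entirely before
    the central time reference and the remaining 38 are counted as 'after'
    (windows straddling the reference join the 'after' set).
    """
    return [(s, s + window) for s in range(0, n_samples - window + 1, stride)]


def phi_timecourse(epoch: np.ndarray, measure: str = "phi_MI",
                   taus=DEFAULT_TAUS, window: int = PHI_WINDOW,
                   stride: int = PHI_STRIDE,
                   partition: list[list[int]] | None = None,
                   reference_index: int | None = None) -> "pd.DataFrame":
    """Tau-averaged integrated-information time course of one epoch.

    ``epoch`` is channels x samples at 125 Hz.  Within each sliding window the
    measure is computed at every lag in ``taus`` and averaged.  Returns a
    table with window index, window center time offset from the reference
    (s), condition ('before' if the window ends at or before the reference)
    and the tau-averaged value.
    """
    import pandas as pd

    epoch = np.asarray(epoch, float)
    n_ch, n_s = epoch.shape
    if window < max(taus) + n_ch + 2:
        raise ValueError("window too short for the channel count and max lag")
    ref = n_s // 2 if reference_index is None else reference_index
    rows = []
    for w_idx, (start, stop) in enumerate(timecourse_windows(n_s, window, stride)):
        seg = epoch[:, start:stop]
        vals = []
        for tau in taus:
            model = estimate_lagged_cov(seg, tau, partition)
            vals.append(compute_phi(model, measure))
        rows.append({"window": w_idx,
                     "time_s": ((start + stop) / 2 - ref) / PHI_SR,
                     "condition": "before" if stop <= ref else "after",
                     "measure": measure, "value": float(np.mean(vals))})
    return pd.DataFrame(rows)
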