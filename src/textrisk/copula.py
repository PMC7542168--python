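"""Gaussian-copula machinery behind the synthetic cohort.

Scale totals are generated by quantile-mapping correlated standard-normal
latents through fixed discrete marginal distributions.  Two calibration
problems are solved numerically, once per calibration:

* each marginal is a discretized (tail-lumped) normal on the instrument's
  integer support whose parameters are solved so the realized mean/SD equal
  the published targets; the right-skewed CSSRS total instead uses a
  zero-inflated shifted negative-binomial whose moments are matched in
  closed form;
* quantile mapping attenuates Pearson correlations, noticeably so for the
  zero-inflated suicide column, so the latent correlation for every pair is
  solved (bisection on the exact copula moment, evaluated by piecewise
  Gauss-Legendre quadrature) such that the *discretized* scores reproduce
  the published correlations.  The resulting latent matrix is repaired to
  the nearest positive-semidefinite correlation matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_nearest

from .calibration import GeneratorCalibration, MEASURE_SUPPORTS

__all__ = [
    "nearest_correlation_matrix",
    "scale_marginals",
    "latent_correlation_matrix",
    "sample_latent_profiles",
    "discretize_to_scales",
]


# ---------------------------------------------------------------------------
# PSD repair
# ---------------------------------------------------------------------------

def nearest_correlation_matrix(M: np.ndarray, threshold: float = 1e-12
                               ) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix (alternating
    projections).  A matrix that is already PSD is returned unchanged up to
    numerical tolerance."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-10):
        raise ValueError("input must have a unit diagonal")
    if np.linalg.eigvalsh(M).min() >= -threshold:
        return M.copy()
    R = corr_nearest(M, threshold=threshold, n_fact=1000)
    return np.asarray((R + R.T) / 2.0)


# ---------------------------------------------------------------------------
# Marginal distributions
# ---------------------------------------------------------------------------

def _discretized_normal_pmf(mu: float, sigma: float, lo: int, hi: int
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Normal discretized to integers on [lo, hi]; tail mass lumped into the
    endpoints, which is what keeps bounded short scales matchable."""
    k = np.arange(lo, hi + 1)
    upper = (k + 0.5 - mu) / sigma
    lower = (k - 0.5 - mu) / sigma
    upper[-1], lower[0] = np.inf, -np.inf
    p = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    return k, p / p.sum()


def _solve_bounded_marginal(lo: int, hi: int, mean: float, sd: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Solve (mu, sigma) of the discretized normal so realized moments hit
    the targets."""

    def resid(theta: np.ndarray) -> list[float]:
        k, p = _discretized_normal_pmf(theta[0], np.exp(theta[1]), lo, hi)
        m = float(k @ p)
        s = float(np.sqrt((k - m) ** 2 @ p))
        return [m - mean, s - sd]

    sol = optimize.least_squares(resid, [mean, np.log(sd)], method="lm")
    return _discretized_normal_pmf(sol.x[0], np.exp(sol.x[1]), lo, hi)


def _zero_inflated_count_pmf(p_positive: float, mean: float, sd: float,
                             kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Point mass at zero (the non-ideating majority) plus a shifted count
    distribution for everyone with any endorsement, moment-matched overall."""
    m_pos = mean / p_positive
    v_pos = (sd ** 2 + mean ** 2) / p_positive - m_pos ** 2
    lam = m_pos - 1.0            # mean of (total - 1) among positives
    excess = v_pos - lam
    ks = np.arange(0, kmax)
    if excess > 1e-9:            # overdispersed: negative binomial
        size = lam ** 2 / excess
        prob = size / (size + lam)
        tail = stats.nbinom.pmf(ks, size, prob)
    else:
        tail = stats.poisson.pmf(ks, lam)
    pmf = np.zeros(kmax + 1)
    pmf[0] = 1.0 - p_positive
    pmf[1:] = p_positive * tail / tail.sum()
    k = np.arange(0, kmax + 1)
    return k, pmf


def scale_marginals(calibration: GeneratorCalibration
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(support, pmf) per measure, in calibration order."""
    out = []
    for i, name in enumerate(calibration.measure_names):
        lo, hi = MEASURE_SUPPORTS[name]
        if name == "suicide":
            out.append(_zero_inflated_count_pmf(
                calibration.pi_general, calibration.mu[i],
                calibration.sigma[i], kmax=hi))
        else:
            out.append(_solve_bounded_marginal(
                lo, hi, calibration.mu[i], calibration.sigma[i]))
    return out


def _quantile_map(k: np.ndarray, pmf: np.ndarray, z: np.ndarray
                  ) -> np.ndarray:
    cdf = np.cumsum(pmf)
    u = stats.norm.cdf(z)
    idx = np.searchsorted(cdf, u, side="left").clip(0, len(k) - 1)
    return k[idx].astype(float)


# ---------------------------------------------------------------------------
# Latent correlation solve (NORTA)
# ---------------------------------------------------------------------------

_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)


def _pair_product_moment(ki, pi_, kj, pj, r: float) -> float:
    """E[g_i(Z1) g_j(Z2)] for bivariate standard normal (Z1, Z2) with
    correlation r, where g = quantile map through the discrete marginal.
    Integrates exactly over the cells of measure i (g_i is constant within a
    cell; the conditional expectation of g_j is smooth there)."""
    ti = stats.norm.ppf(np.clip(np.concatenate([[0.0], np.cumsum(pi_)]),
                                0.0, 1.0))
    ti = np.clip(ti, -8.5, 8.5)
    tj = stats.norm.ppf(np.clip(np.cumsum(pj)[:-1], 0.0, 1.0))
    a, b = ti[:-1], ti[1:]
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    z = mid[:, None] + half[:, None] * _GL_X[None, :]
    w = half[:, None] * _GL_W[None, :] * stats.norm.pdf(z)
    c = np.sqrt(max(1.0 - r * r, 1e-12))
    surv = stats.norm.sf((tj[None, None, :] - r * z[..., None]) / c)
    steps = np.diff(kj).astype(float)
    cond_mean_j = kj[0] + surv @ steps
    return float((w * ki[:, None] * cond_mean_j).sum())


def _solve_pair_latent_r(ki, pi_, kj, pj, target: float) -> float:
    mi = float(ki @ pi_)
    si = float(np.sqrt((ki - mi) ** 2 @ pi_))
    mj = float(kj @ pj)
    sj = float(np.sqrt((kj - mj) ** 2 @ pj))

    def f(r: float) -> float:
        return (_pair_product_moment(ki, pi_, kj, pj, r) - mi * mj) \
            / (si * sj) - target

    return optimize.brentq(f, -0.9995, 0.9995, xtol=1e-6)


def _latent_correlation_matrix_uncached(calibration: GeneratorCalibration
                                        ) -> np.ndarray:
    marginals = scale_marginals(calibration)
    k = len(marginals)
    L = np.eye(k)
    for i in range(k):
        for j in range(i):
            L[i, j] = L[j, i] = _solve_pair_latent_r(
                *marginals[i], *marginals[j], calibration.R[i, j])
    return nearest_correlation_matrix(L)


_LATENT_CACHE: dict[bytes, np.ndarray] = {}


def latent_correlation_matrix(calibration: GeneratorCalibration
                              ) -> np.ndarray:
    """Latent (copula-scale) correlation matrix whose discretized scores
    reproduce ``calibration.R``; PSD-repaired.  Cached on the calibration's
    numeric content since the solve costs a second or so."""
    key = np.concatenate([
        calibration.mu, calibration.sigma, calibration.R.ravel(),
        [calibration.pi_general, calibration.pi_high]]).tobytes()
    if key not in _LATENT_CACHE:
        if len(_LATENT_CACHE) > 16:
            _LATENT_CACHE.clear()
        _LATENT_CACHE[key] = _latent_correlation_matrix_uncached(calibration)
    return _LATENT_CACHE[key]


# ---------------------------------------------------------------------------
# Sampling and discretization
# ---------------------------------------------------------------------------

def sample_latent_profiles(calibration: GeneratorCalibration, n: int,
                           seed: int, R: np.ndarray | None = None
                           ) -> np.ndarray:
    """Draw n rows from a zero-mean, unit-variance multivariate normal with
    the given correlation matrix (default: the calibrated latent matrix).
    Reproducible for a fixed seed."""
    if n < 2:
        raise ValueError("need n >= 2")
    if R is None:
        R = latent_correlation_matrix(calibration)
    R = nearest_correlation_matrix(R)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < -1e-8:
        raise ValueError("latent correlation matrix is not PSD after repair")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, R.shape[0])) @ root.T


def discretize_to_scales(latents: np.ndarray,
                         calibration: GeneratorCalibration) -> np.ndarray:
    """Map each latent column monotonically onto its instrument's integer
    support via the calibrated marginal.  Monotonicity preserves rank
    correlations; the latent matrix is pre-adjusted so Pearson correlations
    land on target too."""
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 2 or latents.shape[1] != len(calibration.measure_names):
        raise ValueError("latents must have one column per measure")
    marginals = scale_marginals(calibration)
    cols = [_quantile_map(k, p, latents[:, i])
            for i, (k, p) in enumerate(marginals)]
    return np.column_stack(cols)
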