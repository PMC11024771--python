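"""Multivariate-normal rectangle probabilities for probit group likelihoods.

The per-group likelihood term of the liability model is the probability
that a multivariate normal liability vector falls in an orthant-type
rectangle (affected children above the threshold 0, unaffected below).
Dimension 1 is a normal CDF, dimension 2 uses a fixed Gauss-Legendre
reduction of the bivariate normal CDF, and dimension >= 3 uses the
separation-of-variables (sequential conditioning) transform evaluated with
randomized scrambled Sobol points.  All randomness is controlled by an
explicit seed; a given seed and sample budget give bit-reproducible values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

_EPS = 1e-14


@dataclass
class QMCConfig:
    """Integration control for >=3-dimensional rectangle probabilities.

    ``n_samples`` quasi-random points per randomization, ``n_randomizations``
    independent scramblings (their spread yields the standard-error
    estimate), ``abs_tol`` the target absolute accuracy per probability.
    """

    n_samples: int = 4096
    n_randomizations: int = 8
    seed: int = 0
    abs_tol: float = 1e-6

    def __post_init__(self):
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.abs_tol <= 0:
            raise ValueError("abs_tol must be positive")


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized.

    Gauss-Legendre quadrature (64 nodes) on the correlation-integral form
    d/dr P = phi2(h, k; r); accurate to ~1e-14 for |rho| <= 0.99.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    nodes, weights = np.polynomial.legendre.leggauss(64)
    # rescale nodes from [-1, 1] to [0, rho]
    r = 0.5 * rho[..., None] * (nodes + 1.0)
    w = 0.5 * rho[..., None] * weights
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - r * r
    dens = np.exp(-(hh * hh - 2.0 * r * hh * kk + kk * kk) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    val = ndtr(h) * ndtr(k) + (w * dens).sum(axis=-1)
    return np.clip(val, 0.0, 1.0)


def _sobol_points(dim: int, cfg: QMCConfig) -> np.ndarray:
    """(n_randomizations, n_samples, dim) scrambled Sobol points with
    antithetic pairing (the sequential-conditioning integrand is monotone
    in each coordinate, so pairing u with 1-u cancels the leading error)."""
    half = max(cfg.n_samples // 2, 1)
    out = np.empty((cfg.n_randomizations, 2 * half, dim))
    for r in range(cfg.n_randomizations):
        eng = qmc.Sobol(d=dim, scramble=True, seed=cfg.seed + 1000003 * r)
        pts = eng.random(half)
        out[r, :half] = pts
        out[r, half:] = 1.0 - pts
    return out


def mvn_cdf_qmc_batch(upper: np.ndarray, chol: np.ndarray,
                      points: np.ndarray):
    """P(Z <= upper) for zero-mean normals with Cholesky factors ``chol``.

    ``upper``: (G, n) standardized upper limits; ``chol``: (G, n, n) lower
    Cholesky factors of the correlation matrices; ``points``: (R, P, >=n-1)
    uniforms.  Returns (prob (G,), se (G,)).
    """
    G, n = upper.shape
    R, P = points.shape[:2]
    est = np.empty((R, G))
    for r in range(R):
        w = points[r]  # (P, n-1) used
        prob = np.ones((G, P))
        y = np.empty((G, P, max(n - 1, 1)))
        for i in range(n):
            if i == 0:
                c = np.broadcast_to(
                    (upper[:, 0] / chol[:, 0, 0])[:, None], (G, P)).copy()
            else:
                s = np.einsum("gj,gpj->gp", chol[:, i, :i], y[:, :, :i])
                c = (upper[:, i, None] - s) / chol[:, i, i, None]
            e = ndtr(c)
            prob *= e
            if i < n - 1:
                u = np.clip(e * w[None, :, i], _EPS, 1.0 - _EPS)
                y[:, :, i] = ndtri(u)
        est[r] = prob.mean(axis=1)
    p = est.mean(axis=0)
    se = est.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(G)
    return p, se


def _standardize(outcomes, means, cov):
    """Flip affected coordinates so the event becomes a CDF evaluation."""
    outcomes = np.asarray(outcomes, dtype=int)
    means = np.asarray(means, dtype=float)
    cov = np.asarray(cov, dtype=float)
    d = 1.0 - 2.0 * outcomes  # +1 control, -1 case
    sd = np.sqrt(np.diag(cov))
    upper = -d * means / sd
    corr = (d[:, None] * d[None, :]) * cov / np.outer(sd, sd)
    return upper, corr


def _chol_jittered(corr):
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        n = corr.shape[-1]
        return np.linalg.cholesky(corr + 1e-10 * np.eye(n))


def group_probability(outcomes, means, cov, qmc_config: QMCConfig | None = None):
    """Probability of an observed affection pattern in one group.

    Returns ``(prob, se, warn)``: the rectangle probability
    P(eta_i >= 0 for cases, eta_i < 0 for controls) for
    eta ~ N(means, cov), an integration standard error (0 for the exact
    closed forms at n <= 2), and a flag set when the requested tolerance
    was not met at the configured sample budget.
    """
    cfg = qmc_config or QMCConfig()
    outcomes = np.atleast_1d(np.asarray(outcomes, dtype=int))
    means = np.atleast_1d(np.asarray(means, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if not (np.all(np.isfinite(means)) and np.all(np.isfinite(cov))):
        raise ValueError("non-finite mean or covariance")
    n = len(outcomes)
    upper, corr = _standardize(outcomes, means, cov)
    if n == 1:
        return float(ndtr(upper[0])), 0.0, False
    if n == 2:
        p = float(bvn_cdf(upper[0], upper[1], corr[0, 1]))
        return p, 0.0, False
    chol = _chol_jittered(corr)[None]
    pts = _sobol_points(max(n - 1, 1), cfg)
    p, se = mvn_cdf_qmc_batch(upper[None], chol, pts)
    warn = bool(se[0] > cfg.abs_tol)
    return float(p[0]), float(se[0]), warn
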