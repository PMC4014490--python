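"""Allelic-correlation kinship and single-component REML heritability.

The kinship matrix is the average cross-product of genotypes standardized by
their sample allele frequencies, K = Z Z'/m with z = (g - 2p)/sqrt(2p(1-p)).
Heritability is estimated under y = mu + g + e with cov(g) = sigma_g^2 K and
cov(e) = sigma_e^2 I by restricted maximum likelihood: K is eigendecomposed
once and the restricted log-likelihood, profiled over the error scale, is
maximized in the variance ratio lambda = sigma_g^2/sigma_e^2 on a log grid
(2^-14 .. 2^14) refined by golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._common import DegenerateInputError, MatrixError, ParameterError

EIG_CLIP_TOL = 1e-8  # kinship eigenvalues above -tol are clipped to 0


@dataclass
class KinshipMatrix:
    K: np.ndarray
    n_markers: int
    allele_freq: np.ndarray


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    converged: bool


def kinship_allelic_corr(G: np.ndarray) -> KinshipMatrix:
    """Allelic-correlation kinship from a 0/1/2 genotype matrix.

    Monomorphic markers are excluded (they carry no correlation information);
    if none remain the input is degenerate.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ParameterError("need a 2-D genotype matrix with >= 2 individuals")
    p = G.mean(axis=0) / 2.0
    poly = G.std(axis=0) > 0.0  # rules out p in {0, 1} and constant columns
    if poly.sum() < 2:
        raise DegenerateInputError("fewer than 2 polymorphic markers")
    Gp, pp = G[:, poly], p[poly]
    Z = (Gp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    K = Z @ Z.T / Z.shape[1]
    return KinshipMatrix(K=K, n_markers=int(poly.sum()), allele_freq=p)


def _as_kinship_array(K) -> np.ndarray:
    return K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _eigendecompose(K: np.ndarray):
    if not np.allclose(K, K.T, atol=1e-10):
        raise MatrixError("kinship matrix is not symmetric")
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -EIG_CLIP_TOL * max(1.0, d.max()):
        raise MatrixError(f"kinship has eigenvalue {d.min():.3g} below tolerance")
    return np.clip(d, 0.0, None), U


def _profile_reml(lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray, n: int) -> float:
    """Restricted log-likelihood at variance ratio ``lam``, profiled over
    sigma_e^2, in the eigenbasis of K (yt, xt are rotated y and intercept)."""
    v = lam * d + 1.0
    xwx = np.sum(xt * xt / v)
    mu = np.sum(xt * yt / v) / xwx
    r = yt - xt * mu
    rss = np.sum(r * r / v)
    s2 = rss / (n - 1)
    return -0.5 * ((n - 1) * (np.log(2 * np.pi * s2) + 1.0) + np.sum(np.log(v)) + np.log(xwx))


def reml_h2(y: np.ndarray, K) -> VarianceComponents:
    """REML estimate of heritability under a single-kinship mixed model.

    When the likelihood is flat in the variance ratio (e.g. K = I, where
    genetic and environmental variance are unidentifiable) the estimate is
    reported as h2 = 0 with ``converged=False`` and a warning.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ParameterError("phenotype contains non-finite values")
    Km = _as_kinship_array(K)
    if Km.shape[0] != len(y):
        raise ParameterError("kinship and phenotype dimensions differ")
    n = len(y)
    d, U = _eigendecompose(Km)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    log2lam = np.arange(-14.0, 14.0 + 1e-9, 0.5)
    grid = 2.0**log2lam
    ll = np.array([_profile_reml(lam, d, yt, xt, n) for lam in grid])
    if ll.max() - ll.min() < 1e-8:
        warnings.warn("restricted likelihood is flat in the variance ratio; "
                      "h2 is unidentifiable and reported as 0")
        s2 = float(np.var(y, ddof=1))
        return VarianceComponents(0.0, s2, 0.0, float(ll[0]), converged=False)

    i = int(np.argmax(ll))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, len(grid) - 1)])
    # golden-section on log(lambda)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, dd_ = b - invphi * (b - a), a + invphi * (b - a)
    fc = _profile_reml(np.exp(c), d, yt, xt, n)
    fd = _profile_reml(np.exp(dd_), d, yt, xt, n)
    for _ in range(60):
        if fc > fd:
            b, dd_, fd = dd_, c, fc
            c = b - invphi * (b - a)
            fc = _profile_reml(np.exp(c), d, yt, xt, n)
        else:
            a, c, fc = c, dd_, fd
            dd_ = a + invphi * (b - a)
            fd = _profile_reml(np.exp(dd_), d, yt, xt, n)
    lam = float(np.exp((a + b) / 2.0))
    loglik = _profile_reml(lam, d, yt, xt, n)

    # boundary handling: an optimum pinned at the grid edge means ~0 or ~1
    at_lower = i == 0 and ll[0] >= loglik - 1e-10
    if at_lower:
        lam, loglik = 0.0, float(ll[0])

    v = lam * d + 1.0
    xwx = np.sum(xt * xt / v)
    mu = np.sum(xt * yt / v) / xwx
    rss = np.sum((yt - xt * mu) ** 2 / v)
    sigma_e2 = float(rss / (n - 1))
    sigma_g2 = float(lam * sigma_e2)
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if (sigma_g2 + sigma_e2) > 0 else 0.0
    return VarianceComponents(sigma_g2, sigma_e2, float(h2), float(loglik), converged=True)
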