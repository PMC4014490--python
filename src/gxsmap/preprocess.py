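"""Phenotype normalization, covariate regression, relatedness adjustment and
redundant-SNP pruning.

The processing order follows the analysis narrative: Box-Cox normalization,
then regression of significant covariates, then whitening against the kinship
covariance.  Pruning keeps one representative per cluster of near-identical
(>= 99% concordant) SNPs within each chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._common import (CovariateError, DegenerateInputError, MatrixError,
                      ParameterError, standardize)
from .heritability import EIG_CLIP_TOL, _as_kinship_array, reml_h2

BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


@dataclass
class TransformRecord:
    """Record of a Box-Cox normalization: power ``lam`` (0 means log) and the
    ``shift`` added beforehand to make all values strictly positive."""

    lam: float
    shift: float
    applied: bool


def boxcox_transform(y: np.ndarray):
    """Box-Cox normalize and standardize a phenotype.

    The power is chosen by maximizing the profile log-likelihood over the
    fixed grid -2..2 by 0.1; values are shifted by 1 - min(y) first when any
    are non-positive.  Returns (transformed standardized vector,
    TransformRecord).
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)] if np.isnan(y).any() else y
    if len(y) < 10:
        raise ParameterError("need at least 10 finite values")
    if y.std() == 0:
        raise DegenerateInputError("constant phenotype")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
    ys = y + shift
    llf = np.array([stats.boxcox_llf(lam, ys) for lam in BOXCOX_GRID])
    lam = float(BOXCOX_GRID[int(np.argmax(llf))])
    z = np.log(ys) if lam == 0.0 else (ys**lam - 1.0) / lam
    return standardize(z), TransformRecord(lam=lam, shift=shift, applied=True)


def regress_covariates(y: np.ndarray, covariates, alpha: float = 0.05, names=None):
    """Regress significant covariates out of ``y``.

    Each covariate is screened marginally (simple regression t-test); those
    with p < ``alpha`` are retained and jointly regressed out; the residual is
    re-standardized.  Returns (residual vector, list of retained labels).
    """
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = list(names) if names is not None else [f"cov{i}" for i in range(C.shape[1])]
    if C.shape[0] != len(y):
        raise ParameterError("covariate rows do not align with phenotype")

    keep = []
    for j in range(C.shape[1]):
        x = C[:, j]
        if x.std() == 0:
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            keep.append(j)
    if not keep:
        return standardize(y), []

    X = np.column_stack([np.ones(len(y)), C[:, keep]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [names[j] for j in keep]
        raise CovariateError(f"retained covariates are rank deficient: {bad}", columns=bad)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return standardize(resid), [names[j] for j in keep]


def adjust_relatedness(y: np.ndarray, K):
    """Whiten a phenotype against its estimated kinship covariance.

    Variance components of y ~ mu + g + e (cov(g) = sg^2 K, cov(e) = se^2 I)
    are estimated by REML, and y is rotated by (sg^2 K + se^2 I)^(-1/2), then
    re-standardized.  With K = I (or an unidentifiable flat likelihood) this
    is the identity up to standardization.  Kinship eigenvalues down to
    -1e-8 are tolerated and clipped at zero.
    """
    y = np.asarray(y, dtype=float)
    Km = _as_kinship_array(K)
    if Km.shape != (len(y), len(y)):
        raise ParameterError("kinship dimensions do not match phenotype")
    if not np.allclose(Km, Km.T, atol=1e-10):
        raise MatrixError("kinship matrix is not symmetric")
    d, U = np.linalg.eigh((Km + Km.T) / 2.0)
    if d.min() < -EIG_CLIP_TOL * max(1.0, d.max()):
        raise MatrixError(f"kinship eigenvalue {d.min():.3g} below tolerance")
    d = np.clip(d, 0.0, None)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vc = reml_h2(y, Km)
    if not vc.converged or vc.sigma_g2 <= 0:
        return standardize(y)
    w = 1.0 / np.sqrt(vc.sigma_g2 * d + vc.sigma_e2)
    y_adj = U @ (w * (U.T @ y))
    return standardize(y_adj)


def prune_concordant_snps(G: np.ndarray, marker_map: pd.DataFrame,
                          threshold: float = 0.99) -> list[int]:
    """Cluster near-identical SNPs within each chromosome and keep one per
    cluster.

    Markers are scanned left to right in map order; a marker joins the first
    existing cluster whose representative (the cluster's leftmost member)
    matches its genotype codes in at least ``threshold`` of non-missing
    individuals.  Missing genotypes (negative or NaN codes) are ignored
    pairwise.  Returns retained (representative) column indices in map order.
    """
    G = np.asarray(G)
    if G.size == 0:
        raise ParameterError("empty genotype matrix")
    if not (0.5 < threshold <= 1.0):
        raise ParameterError("threshold must be in (0.5, 1]")
    if len(marker_map) != G.shape[1]:
        raise ParameterError("marker map does not align with genotype columns")

    Gf = G.astype(float)
    valid = np.isfinite(Gf) & (Gf >= 0)
    retained: list[int] = []
    for c in marker_map["chrom"].unique():
        idx = np.flatnonzero((marker_map["chrom"] == c).to_numpy())
        reps: list[int] = []
        for j in idx:
            placed = False
            for r in reps:
                both = valid[:, j] & valid[:, r]
                if not both.any():
                    continue
                conc = np.mean(Gf[both, j] == Gf[both, r])
                if conc >= threshold:
                    placed = True
                    break
            if not placed:
                reps.append(j)
        retained.extend(reps)
    return sorted(retained)
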