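"""Downstream comparison statistics and summaries.

Permutation-based false-discovery calibration for interaction calls,
cross-mapper QTL matching (sparse-partitioning calls vs RMIP peaks),
classification of GxS QTL against single-sex scans, Wilcoxon rank-sum
comparisons, sex main-effect variance, Pearson correlation with its t test,
and posterior-probability histograms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from ._common import DegenerateInputError, ParameterError, child_seeds
from .rmip import RMIPResult
from .sparse_partitioning import (MCMCConfig, PredictorSet, mcmc_run,
                                  posterior_summaries)


@dataclass
class MatchReport:
    matched: list = field(default_factory=list)       # (call, peak) pairs
    unmatched_calls: list = field(default_factory=list)
    unmatched_peaks: list = field(default_factory=list)
    window_rule: str = ""


@dataclass
class CorrelationReport:
    r: float
    t_stat: float
    df: int
    p: float
    n: int


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(phenotypes: list, predictors: PredictorSet, config: MCMCConfig,
                    threshold: float = 0.2, seed: int = 0):
    """Expected interaction false positives at a posterior threshold.

    Each phenotype's values are permuted once (destroying all genotype- and
    sex-phenotype association while keeping the predictor structure), the
    mapper is rerun, and interaction (pairwise) probabilities at or above the
    threshold are counted and summed over phenotypes.  Returns
    ``(expected_false_positives, per_phenotype_max)``.
    """
    if len(phenotypes) < 1:
        raise ParameterError("need at least one phenotype")
    seeds = child_seeds(seed, 2 * len(phenotypes))
    count = 0
    per_max = []
    for i, y in enumerate(phenotypes):
        rng = np.random.default_rng(seeds[2 * i])
        yp = rng.permutation(np.asarray(y, dtype=float))
        import dataclasses

        cfg = dataclasses.replace(config, seed=seeds[2 * i + 1])
        run = mcmc_run(yp, predictors, cfg)
        summ = posterior_summaries(run)
        probs = list(summ.pairwise.values())
        per_max.append(max(probs) if probs else 0.0)
        count += sum(1 for p in probs if p >= threshold)
    return count, per_max


# ---------------------------------------------------------------------------
# QTL matching
# ---------------------------------------------------------------------------

def match_qtl(sp_calls: list, rmip_result: RMIPResult, window_mb: float = 2.0) -> MatchReport:
    """Match mapper calls to RMIP peaks: same chromosome and position inside
    the peak's 95% CI widened by ``window_mb`` on each side.  Assignment is
    greedy nearest-first and each peak is used at most once."""
    peaks = list(rmip_result.peaks)
    cand = []
    for ci, call in enumerate(sp_calls):
        for pi, pk in enumerate(peaks):
            if str(call.chrom) != str(pk.chrom):
                continue
            lo, hi = pk.ci_low - window_mb, pk.ci_high + window_mb
            if lo <= call.mbp <= hi:
                cand.append((abs(call.mbp - pk.mbp), ci, pi))
    cand.sort()
    used_c, used_p = set(), set()
    report = MatchReport(window_rule=f"ci+/-{window_mb}Mb")
    for _, ci, pi in cand:
        if ci in used_c or pi in used_p:
            continue
        used_c.add(ci)
        used_p.add(pi)
        report.matched.append((sp_calls[ci], peaks[pi]))
    report.unmatched_calls = [c for i, c in enumerate(sp_calls) if i not in used_c]
    report.unmatched_peaks = [p for i, p in enumerate(peaks) if i not in used_p]
    return report


def match_gxs_single_sex(gxs_calls: list, male_scan: RMIPResult,
                         female_scan: RMIPResult, window_mb: float = 5.0,
                         rmip_threshold: float = 0.25) -> list[str]:
    """Classify each GxS call by whether an above-threshold single-sex peak
    lies within ``window_mb``: 'male-only', 'female-only', 'both' or
    'neither'."""
    def hit(scan: RMIPResult, call) -> bool:
        return any(str(pk.chrom) == str(call.chrom)
                   and abs(pk.mbp - call.mbp) <= window_mb
                   and pk.rmip >= rmip_threshold
                   for pk in scan.peaks)

    out = []
    for call in gxs_calls:
        m, f = hit(male_scan, call), hit(female_scan, call)
        out.append("both" if m and f else "male-only" if m
                   else "female-only" if f else "neither")
    return out


# ---------------------------------------------------------------------------
# statistical kernels
# ---------------------------------------------------------------------------

def rank_sum_compare(values_a, values_b):
    """Wilcoxon rank-sum test: W = sum of mid-ranks of group a in the pooled
    ranking; two-sided p by exact enumeration when n_a + n_b <= 12, else by
    normal approximation with tie correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, nb = len(a), len(b)
    N = na + nb
    W = float(ranks[:na].sum())

    if N <= 12:
        sums = [sum(c) for c in itertools.combinations(ranks, na)]
        mean_w = na * (N + 1) / 2.0
        eps = 1e-9
        lo = sum(1 for s in sums if s <= W + eps) / comb(N, na)
        hi = sum(1 for s in sums if s >= W - eps) / comb(N, na)
        p = min(1.0, 2.0 * min(lo, hi))
        return W, p

    mean_w = na * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0))
    var_w = na * nb / 12.0 * ((N + 1.0) - tie_term)
    if var_w <= 0:
        return W, 1.0
    z = (W - mean_w) / np.sqrt(var_w)
    return W, float(2.0 * stats.norm.sf(abs(z)))


def sex_effect_variance(y, sex) -> float:
    """Percent of phenotypic variance explained by sex as a main effect
    (R-squared of the simple linear regression of y on sex, times 100)."""
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex)
    if len(np.unique(sex)) < 2:
        raise ParameterError("both sexes must be present")
    r = np.corrcoef(y, sex.astype(float))[0, 1]
    return float(100.0 * r * r)


def correlate_with_t(x, y) -> CorrelationReport:
    """Pearson correlation with its t statistic (df = n - 2) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    denom = max(1.0 - r * r, 1e-300)
    t = r * np.sqrt((n - 2) / denom)
    return CorrelationReport(r=float(r), t_stat=float(t), df=n - 2, p=float(p), n=n)


def probability_histogram(values, floor: float = 0.05, threshold: float = 0.2,
                          bin_width: float = 0.05):
    """Histogram of posterior probabilities over [floor, 1], values below the
    floor discarded.  Returns (bin_edges, counts, threshold)."""
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ParameterError("values must lie in [0, 1]")
    v = v[v >= floor]
    n_bins = int(np.ceil((1.0 - floor) / bin_width - 1e-9))
    edges = floor + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)
    counts, _ = np.histogram(v, bins=edges)
    return edges, counts, threshold
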