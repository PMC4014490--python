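"""Cross-validated GxS variance decomposition.

How much phenotypic variance do gene-by-sex interactions explain?  The data
are split into k (default 10) even tranches; for each tranche the
sparse-partitioning chain is trained on the other k-1 and its model-averaged
posterior-mean prediction is scored on the held-out tranche.  This is done
under two configurations that differ only in whether sex may enter
interaction groups (interaction_mode "all") or only act marginally
(interaction_mode "snp_only"; SNP-SNP interactions stay allowed in both).
The percent variance explained is pooled over folds,
pve = 100 * (1 - SSE/SST), with SST measured against the training-fold mean;
it can be negative when the model predicts worse than the mean.  The GxS
contribution is the difference pve_with - pve_without.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._common import ParameterError, child_seeds
from .sparse_partitioning import (MCMCConfig, MCMCRun, PredictorSet, fit_state,
                                  mcmc_run)


@dataclass
class FoldRecord:
    fold: int
    test_mse: float
    test_variance: float


@dataclass
class CVVarianceResult:
    phenotype: str
    pve_with: float
    pve_without: float
    folds_with: list = field(default_factory=list)
    folds_without: list = field(default_factory=list)

    @property
    def difference(self) -> float:
        return self.pve_with - self.pve_without


def cv_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random partition of n individuals into k folds with sizes differing by
    at most one; deterministic under the seed."""
    if k <= 1:
        raise ParameterError("k must be >= 2")
    if n < k:
        raise ParameterError("n must be >= k")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    rng.shuffle(folds)
    return folds


def predict_from_chain(run: MCMCRun, y_train: np.ndarray,
                       predictors_train: PredictorSet,
                       predictors_new: PredictorSet,
                       config: MCMCConfig | None = None) -> np.ndarray:
    """Posterior-mean model-averaged prediction for new individuals.

    Each retained state is refit on the training data (its conjugate
    posterior-mean level effects) and evaluated on the new individuals; the
    prediction is the average over retained states.  Joint genotype levels
    unseen in training fall back to the state's intercept.
    """
    config = config or run.config
    if predictors_new.n_snps != predictors_train.n_snps:
        raise ParameterError("new predictors do not match the training schema")
    retained = run.states[config.burn_in:]
    counts = Counter(st.groups for st in retained)
    n_new = len(predictors_new.sex)
    pred = np.zeros(n_new)
    for groups, cnt in counts.items():
        st = retained[0].__class__(groups)
        fit = fit_state(st, y_train, predictors_train, config.tau2)
        pred += cnt * fit.predict(predictors_new)
    return pred / len(retained)


def cv_variance_explained(y: np.ndarray, predictors: PredictorSet,
                          config_with: MCMCConfig, config_without: MCMCConfig,
                          k: int = 10, seed: int = 0,
                          phenotype: str = "phenotype") -> CVVarianceResult:
    """Out-of-sample percent variance explained under GxS-permitted vs
    GxS-prohibited configurations, and their difference.

    The two configs must be identical except for ``interaction_mode``.
    """
    a = dataclasses.replace(config_with, interaction_mode="all")
    b = dataclasses.replace(config_without, interaction_mode="all")
    if a != b:
        raise ParameterError("configs must differ only in interaction_mode")
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = cv_folds(n, k, seed)
    # same per-fold chain seeds for both configurations, so exchanging the two
    # configs exactly exchanges the two pve values
    fold_seeds = child_seeds(seed, k)

    results = {}
    for tag, cfg, seeds in (("with", config_with, fold_seeds),
                            ("without", config_without, fold_seeds)):
        sse = sst = 0.0
        records = []
        for f in range(k):
            test = folds == f
            train = ~test
            if y[test].var() == 0:
                import warnings

                warnings.warn(f"fold {f} has zero test variance; skipped")
                records.append(FoldRecord(f, float("nan"), 0.0))
                continue
            ptr = PredictorSet(predictors.genotypes[train], predictors.sex[train],
                               predictors.snp_ids)
            pte = PredictorSet(predictors.genotypes[test], predictors.sex[test],
                               predictors.snp_ids)
            cfg_f = dataclasses.replace(cfg, seed=seeds[f])
            run = mcmc_run(y[train], ptr, cfg_f)
            pred = predict_from_chain(run, y[train], ptr, pte, cfg_f)
            err = y[test] - pred
            base = y[test] - y[train].mean()
            sse += float(err @ err)
            sst += float(base @ base)
            records.append(FoldRecord(f, float(np.mean(err**2)),
                                      float(np.var(y[test]))))
        results[tag] = (100.0 * (1.0 - sse / sst), records)

    return CVVarianceResult(
        phenotype=phenotype,
        pve_with=results["with"][0],
        pve_without=results["without"][0],
        folds_with=results["with"][1],
        folds_without=results["without"][1],
    )
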