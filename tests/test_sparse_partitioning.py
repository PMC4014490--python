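"""The sparse-partitioning mapper: closed-form evidence, MCMC correctness
against exact enumeration, posterior summaries and QTL calling."""

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import gxsmap as gx
from gxsmap.sparse_partitioning import (SEX, ModelState, _n_partitions,
                                        log_state_prior)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    n, p = 200, 5
    G = rng.integers(0, 3, (n, p))
    sex = rng.integers(0, 2, n)
    preds = gx.PredictorSet(G, sex)
    y = 0.9 * G[:, 0] + 0.8 * G[:, 1] * sex + rng.normal(0, 1, n)
    return gx.standardize(y), preds


def numeric_null_evidence(y):
    """Oracle: the intercept-only evidence by 1-D numeric integration of the
    scale parameter (flat intercept integrated analytically)."""
    y = np.asarray(y, float)
    n = len(y)
    yc = y - y.mean()
    R = yc @ yc

    def integrand(log_s2):
        s2 = np.exp(log_s2)
        # (2 pi s2)^{-(n-1)/2} n^{-1/2} exp(-R/(2 s2)) * (1/s2) * s2  (log measure)
        return np.exp(-(n - 1) / 2 * np.log(2 * np.pi * s2) - 0.5 * np.log(n)
                      - R / (2 * s2) + 400.0)  # offset for numeric range

    val, _ = integrate.quad(integrand, -10, 10, limit=200)
    return np.log(val) - 400.0


class TestEvidence:
    def test_null_evidence_matches_numeric_integration(self, rng):
        y = rng.normal(0, 1, 100)
        got = gx.log_marginal_likelihood(ModelState(), y, gx.PredictorSet(
            rng.integers(0, 3, (100, 2)), rng.integers(0, 2, 100)))
        assert got == pytest.approx(numeric_null_evidence(y), abs=1e-6)

    def test_single_level_predictor_is_no_op(self, toy):
        y, preds = toy
        # an all-heterozygous SNP spans one joint level; its centred indicator
        # is the zero column, so the analytic evidence penalty is exactly zero
        G2 = preds.genotypes.copy()
        G2[:, 4] = 1
        preds2 = gx.PredictorSet(G2, preds.sex)
        base = gx.log_marginal_likelihood(ModelState(((0,),)), y, preds2)
        with_const = gx.log_marginal_likelihood(ModelState(((0,), (4,))), y, preds2)
        assert with_const == pytest.approx(base, abs=1e-9)

    def test_group_order_invariance(self, toy):
        y, preds = toy
        a = gx.log_marginal_likelihood(ModelState(((0,), (1, SEX))), y, preds)
        b = gx.log_marginal_likelihood(ModelState(((1, SEX), (0,))), y, preds)
        assert a == b


class TestStatePrior:
    @pytest.mark.parametrize("k,expected", [(0, 1), (1, 1), (2, 2), (3, 5), (4, 14)])
    def test_partition_counts_match_enumeration(self, k, expected):
        # oracle: direct enumeration of partitions with blocks <= 3
        cfg = gx.MCMCConfig(interaction_mode="all")
        from gxsmap.sparse_partitioning import _legal_partitions

        assert _n_partitions(k, 2) == expected
        assert sum(1 for _ in _legal_partitions(list(range(k)), cfg)) == expected

    def test_three_way_cap_reduces_count(self):
        assert _n_partitions(9, 2) < _n_partitions(9, 3)

    def test_prior_normalizes_over_groupings(self, toy):
        _, preds = toy
        cfg = gx.MCMCConfig()
        lp1 = log_state_prior(ModelState(((0,), (1,))), preds, cfg)
        lp2 = log_state_prior(ModelState(((0, 1),)), preds, cfg)
        assert lp1 == pytest.approx(lp2)  # same included set, uniform grouping


class TestModelState:
    def test_constraint_validation(self):
        cfg = gx.MCMCConfig(interaction_mode="snp_only")
        with pytest.raises(gx.ParameterError):
            ModelState(((SEX, 0),)).validate(cfg)
        ModelState(((SEX,), (0, 1))).validate(cfg)
        with pytest.raises(gx.ParameterError):
            ModelState(((0, 1, 2), (3, 4, 5), (6, 7, 8),)).validate(gx.MCMCConfig())
        with pytest.raises(gx.ParameterError):
            ModelState(((0, 1),)).validate(gx.MCMCConfig(interaction_mode="none"))

    def test_config_validation(self):
        with pytest.raises(gx.ParameterError):
            gx.MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(gx.ParameterError):
            gx.MCMCConfig(interaction_mode="pairs")


class TestMCMC:
    def test_default_schedule_retains_1500(self):
        cfg = gx.MCMCConfig()
        assert (cfg.iterations, cfg.burn_in, cfg.retained) == (2000, 500, 1500)

    def test_matches_enumeration_oracle(self, toy):
        y, preds = toy
        cfg = gx.MCMCConfig(iterations=20000, burn_in=2000, seed=1)
        exact = gx.enumerate_posterior(y, preds, cfg)
        summ = gx.posterior_summaries(gx.mcmc_run(y, preds, cfg))
        devs = [abs(summ.inclusion.get(k, 0) - v) for k, v in exact.inclusion.items()]
        devs += [abs(summ.pairwise.get(k, 0) - v) for k, v in exact.pairwise.items()]
        assert max(devs) <= 0.05

    def test_denominator_law(self, toy):
        y, preds = toy
        cfg = gx.MCMCConfig(iterations=1200, burn_in=300, seed=2)
        summ = gx.posterior_summaries(gx.mcmc_run(y, preds, cfg))
        assert summ.retained_samples == 900
        for prob in list(summ.inclusion.values()) + list(summ.pairwise.values()):
            assert (prob * 900) == pytest.approx(round(prob * 900), abs=1e-9)

    def test_null_data_low_inclusion(self):
        # near study-scale n: best-of-100 chance associations stay below the
        # 0.2 calling threshold in nearly all replicates
        rng = np.random.default_rng(3)
        n = 800
        G = rng.integers(0, 3, (n, 100))
        sex = rng.integers(0, 2, n)
        preds = gx.PredictorSet(G, sex)
        ok = 0
        for seed in range(6):
            y = np.random.default_rng(100 + seed).normal(0, 1, n)
            summ = gx.posterior_summaries(gx.mcmc_run(
                gx.standardize(y), preds,
                gx.MCMCConfig(iterations=1000, burn_in=250, seed=seed)))
            if all(v < 0.2 for v in summ.inclusion.values()):
                ok += 1
        assert ok >= 5

    def test_snp_only_mode_never_pairs_sex(self, toy):
        y, preds = toy
        cfg = gx.MCMCConfig(iterations=4000, burn_in=500,
                            interaction_mode="snp_only", seed=4)
        summ = gx.posterior_summaries(gx.mcmc_run(y, preds, cfg))
        assert all(SEX not in pair for pair in summ.pairwise)

    def test_detailed_balance_on_frozen_instance(self):
        # with 3 predictors the chain's empirical state frequencies must match
        # the enumerated posterior; a broken reversal would bias them
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, (60, 2))
        preds = gx.PredictorSet(G, rng.integers(0, 2, 60))
        y = gx.standardize(rng.normal(0, 1, 60))
        cfg = gx.MCMCConfig(iterations=25000, burn_in=2500, seed=6)
        run = gx.mcmc_run(y, preds, cfg)
        freq = Counter(st.groups for st in run.states[cfg.burn_in:])
        total = cfg.retained
        exact = {}
        from gxsmap.sparse_partitioning import (_legal_partitions,
                                                log_marginal_likelihood)
        import itertools

        ids = preds.all_ids
        for k in range(len(ids) + 1):
            for sub in itertools.combinations(ids, k):
                for part in _legal_partitions(list(sub), cfg):
                    st = ModelState(part)
                    exact[st.groups] = (log_marginal_likelihood(st, y, preds, cfg.tau2)
                                        + log_state_prior(st, preds, cfg))
        mx = max(exact.values())
        z = sum(np.exp(v - mx) for v in exact.values())
        for g, lw in exact.items():
            p_exact = np.exp(lw - mx) / z
            p_emp = freq.get(g, 0) / total
            assert abs(p_emp - p_exact) <= 0.03

    def test_force_sex_keeps_sex_in_every_state(self, toy):
        y, preds = toy
        cfg = gx.MCMCConfig(iterations=800, burn_in=100, force_sex=True, seed=7)
        run = gx.mcmc_run(y, preds, cfg)
        assert all(SEX in st.predictors for st in run.states)

    def test_needs_two_predictors(self, rng):
        preds = gx.PredictorSet(np.empty((50, 0), dtype=int), rng.integers(0, 2, 50))
        with pytest.raises(gx.ParameterError):
            gx.mcmc_run(rng.normal(0, 1, 50), preds, gx.MCMCConfig())

    def test_determinism(self, toy):
        y, preds = toy
        cfg = gx.MCMCConfig(iterations=500, burn_in=100, seed=8)
        a = gx.mcmc_run(y, preds, cfg)
        b = gx.mcmc_run(y, preds, cfg)
        assert [s.groups for s in a.states] == [s.groups for s in b.states]


class TestSummariesAndCalls:
    def test_summary_definitions_from_handmade_chain(self):
        cfg = gx.MCMCConfig(iterations=2000, burn_in=500)
        on = ModelState(((0,), (1, SEX)))
        off = ModelState()
        chain = [off] * 500 + [on] * 750 + [off] * 750
        summ = gx.posterior_summaries(chain, cfg)
        assert summ.retained_samples == 1500
        assert summ.inclusion[0] == 0.5
        assert summ.pairwise[(SEX, 1)] == 0.5
        assert summ.inclusion.get(2, 0.0) == 0.0

    def test_pairwise_bounded_by_inclusion(self, toy):
        y, preds = toy
        summ = gx.posterior_summaries(gx.mcmc_run(
            y, preds, gx.MCMCConfig(iterations=3000, burn_in=500, seed=9)))
        for (a, b), v in summ.pairwise.items():
            assert v <= min(summ.inclusion[a], summ.inclusion[b]) + 1e-12

    def _map(self, p=5):
        return pd.DataFrame({"marker": [f"s{j}" for j in range(p)],
                             "chrom": [1] * p, "mbp": np.arange(p) * 10.0})

    def test_gxs_call_reported_at_its_posterior(self):
        summ = gx.PosteriorSummary(inclusion={2: 0.55, SEX: 0.6},
                                   pairwise={(SEX, 2): 0.53},
                                   retained_samples=1500)
        calls = gx.call_qtl(summ, self._map(), maf=np.full(5, 0.25))
        gxs = [c for c in calls if c.call_class == "GxS"]
        assert len(gxs) == 1 and gxs[0].posterior == 0.53 and gxs[0].partner == "SEX"

    def test_threshold_boundary_excludes(self):
        summ = gx.PosteriorSummary(inclusion={0: 0.19, 1: 0.19}, pairwise={},
                                   retained_samples=1500)
        assert gx.call_qtl(summ, self._map(), np.full(5, 0.3), threshold=0.2) == []

    def test_sex_never_called_as_main(self):
        summ = gx.PosteriorSummary(inclusion={SEX: 0.9, 3: 0.4},
                                   pairwise={(3, 4): 0.25},
                                   retained_samples=1500)
        calls = gx.call_qtl(summ, self._map(), np.full(5, 0.3))
        assert {c.call_class for c in calls} == {"main", "GxG"}
        assert all(c.snp != "SEX" for c in calls)

    def test_unknown_marker_errors(self):
        summ = gx.PosteriorSummary(inclusion={99: 0.5}, pairwise={},
                                   retained_samples=1500)
        with pytest.raises(gx.ParameterError):
            gx.call_qtl(summ, self._map(), np.full(5, 0.3))

    def test_planted_effects_recovered_with_few_spurious(self):
        # oracle: the generator's truth record
        founders = gx.simulate_founders(20, seed=30)
        pop = gx.simulate_hs_population(founders, 400, generations=8, seed=31)
        spurious = hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            spec = gx.PhenotypeSpec(beta_sex=0.5, main_qtl=[(3, 0.5), (11, 0.5)],
                                    gxs_qtl=[(17, 0.6)], sigma_e=1.0, seed=seed)
            y, _ = gx.simulate_phenotype(pop, spec)
            preds = gx.PredictorSet(pop.genotypes, pop.sex)
            summ = gx.posterior_summaries(gx.mcmc_run(
                gx.standardize(y), preds,
                gx.MCMCConfig(iterations=1500, burn_in=400, seed=seed)))
            maf = np.minimum(pop.genotypes.mean(0) / 2, 1 - pop.genotypes.mean(0) / 2)
            calls = gx.call_qtl(summ, pop.marker_map, maf)
            mains = {c.snp for c in calls if c.call_class == "main"}
            hits += len(mains & {"m3", "m11", "m17"})
            spurious += len([c for c in calls if c.call_class != "main"
                             and c.snp != "m17"])
        assert hits >= 2 * n_seeds          # both planted mains found nearly always
        assert spurious <= n_seeds          # rare spurious interaction calls
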