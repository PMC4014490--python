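"""Sparse-partitioning Bayesian mapper for main, gene-by-sex and
gene-by-gene effects.

A model is a sparse partition of a small set of selected predictors (SNPs,
coded as 3-level factors, plus sex) into disjoint groups of one to three
members; co-grouped predictors interact, i.e. the group contributes one mean
per observed joint level of its members.  A Metropolis-Hastings chain walks
model space; the posterior probability that a predictor is associated with the
phenotype is the fraction of retained samples containing it, and the posterior
probability that two predictors interact is the fraction in which they share a
group.

Likelihood: group-level means carry independent N(0, tau^2 sigma^2) priors,
the intercept is flat, and sigma^2 carries the scale-free prior 1/sigma^2, so
the marginal likelihood of any model is available in closed form.  That
conjugacy makes exhaustive enumeration of all legal partitions tractable for
small predictor counts, which the test-suite uses as an exact oracle for the
chain.

Default search constraints: at most 10 predictors per model and at most two
three-way interaction groups; 2000 MCMC iterations with the first 500
discarded, so each posterior probability is a fraction of 1500.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from ._common import ParameterError

SEX = -1  # distinguished predictor id for sex

_MOVE_WEIGHTS = {"add": 0.3, "remove": 0.3, "move": 0.2, "swap": 0.2}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _canonical(groups) -> tuple:
    return tuple(sorted(tuple(sorted(g)) for g in groups if len(g)))


@dataclass(frozen=True)
class ModelState:
    """A sparse partition of selected predictor ids into interaction groups."""

    groups: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "groups", _canonical(self.groups))

    @property
    def predictors(self) -> tuple:
        return tuple(sorted(p for g in self.groups for p in g))

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def n_three_way(self) -> int:
        return sum(1 for g in self.groups if len(g) == 3)

    def validate(self, config: "MCMCConfig"):
        preds = [p for g in self.groups for p in g]
        if len(preds) != len(set(preds)):
            raise ParameterError("groups are not disjoint")
        if any(not (1 <= len(g) <= 3) for g in self.groups):
            raise ParameterError("group sizes must be 1-3")
        if self.n_predictors > config.max_predictors:
            raise ParameterError("too many predictors in model")
        if self.n_three_way > config.max_three_way:
            raise ParameterError("too many three-way groups")
        if config.interaction_mode == "none" and any(len(g) > 1 for g in self.groups):
            raise ParameterError("interaction_mode=none forbids multi-predictor groups")
        if config.interaction_mode == "snp_only" and any(
            SEX in g and len(g) > 1 for g in self.groups
        ):
            raise ParameterError("interaction_mode=snp_only forbids sex in interactions")


@dataclass
class MCMCConfig:
    iterations: int = 2000
    burn_in: int = 500
    max_predictors: int = 10
    max_three_way: int = 2
    interaction_mode: str = "all"  # all | snp_only | none
    tau2: float = 0.2
    expected_model_size: float = 2.0
    force_sex: bool = False
    moves_per_iteration: int | None = None  # default: one sweep = #predictors
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ParameterError("burn_in must be < iterations")
        if self.interaction_mode not in ("all", "snp_only", "none"):
            raise ParameterError(f"unknown interaction_mode {self.interaction_mode!r}")

    @property
    def retained(self) -> int:
        return self.iterations - self.burn_in


@dataclass
class PredictorSet:
    """SNP genotype columns (0/1/2 factors) plus the sex indicator."""

    genotypes: np.ndarray
    sex: np.ndarray
    snp_ids: list | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        self.sex = np.asarray(self.sex)
        if self.genotypes.shape[0] != len(self.sex):
            raise ParameterError("genotype rows do not align with sex vector")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(self.genotypes.shape[1])]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_predictors(self) -> int:
        return self.n_snps + 1

    @property
    def all_ids(self) -> list:
        return [SEX] + list(range(self.n_snps))

    def codes(self, pid) -> np.ndarray:
        return self.sex if pid == SEX else self.genotypes[:, pid]


@dataclass
class PosteriorSummary:
    """Per-predictor and per-pair posterior probabilities with the retained
    sample count as denominator (every probability is k/retained_samples)."""

    inclusion: dict
    pairwise: dict
    retained_samples: int
    chain_log: np.ndarray | None = None


@dataclass
class QTLCall:
    phenotype: str
    snp: str
    chrom: object
    mbp: float
    posterior: float
    maf: float
    call_class: str  # main | GxS | GxG
    partner: object = None


@dataclass
class MCMCRun:
    states: list
    log_evidence: np.ndarray
    config: MCMCConfig
    acceptance_rate: float = 0.0


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _group_design(group, predictors: PredictorSet):
    """One-hot indicators over the observed joint levels of a group.

    Returns (X raw indicator matrix, level codes array) with the joint code of
    each member combination in base 3."""
    code = np.zeros(len(predictors.sex), dtype=np.int64)
    for pos, pid in enumerate(sorted(group)):
        code = code * 3 + predictors.codes(pid).astype(np.int64)
    levels, inv = np.unique(code, return_inverse=True)
    X = np.zeros((len(code), len(levels)))
    X[np.arange(len(code)), inv] = 1.0
    return X, levels


def log_marginal_likelihood(state: ModelState, y: np.ndarray,
                            predictors: PredictorSet, tau2: float = 0.2) -> float:
    """Closed-form log integrated likelihood of ``y`` under a model state.

    Each group contributes one mean per observed joint level of its members
    (a joint level absent from the data simply contributes no column); level
    means have N(0, tau^2 sigma^2) priors, the intercept is flat, and
    sigma^2 is integrated under the scale-free prior 1/sigma^2.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    yty = float(yc @ yc)
    base = (gammaln((n - 1) / 2.0) - 0.5 * np.log(n)
            - ((n - 1) / 2.0) * np.log(2.0 * np.pi))
    if not state.groups:
        return base - ((n - 1) / 2.0) * np.log(max(yty, 1e-300) / 2.0)
    blocks = [_group_design(g, predictors)[0] for g in state.groups]
    X = np.hstack(blocks)
    q = X.shape[1]
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc + np.eye(q) / tau2
    c, low = cho_factor(S)
    b = Xc.T @ yc
    R = yty - float(b @ cho_solve((c, low), b))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return (base - (q / 2.0) * np.log(tau2) - 0.5 * logdet
            - ((n - 1) / 2.0) * np.log(max(R, 1e-300) / 2.0))


# ---------------------------------------------------------------------------
# state prior
# ---------------------------------------------------------------------------

def _n_partitions(k: int, max_three: int) -> int:
    """Number of set partitions of k labeled items into blocks of size <= 3
    with at most ``max_three`` size-3 blocks."""
    if k == 0:
        return 1
    total = 0
    for t in range(min(max_three, k // 3) + 1):
        rem = k - 3 * t
        for d in range(rem // 2 + 1):
            s = rem - 2 * d
            total += factorial(k) // (6**t * factorial(t) * 2**d * factorial(d) * factorial(s))
    return total


def log_state_prior(state: ModelState, predictors: PredictorSet, config: MCMCConfig) -> float:
    """Independent-inclusion prior (rate = expected size / #predictors) times
    a uniform distribution over the legal groupings of the included set."""
    p_tot = predictors.n_predictors
    rho = min(config.expected_model_size / p_tot, 0.5)
    k = state.n_predictors
    lp = k * np.log(rho) + (p_tot - k) * np.log1p(-rho)
    if config.interaction_mode == "none":
        n_part = 1
    elif config.interaction_mode == "snp_only" and SEX in state.predictors:
        n_part = _n_partitions(k - 1, config.max_three_way)
    else:
        n_part = _n_partitions(k, config.max_three_way)
    return float(lp - np.log(n_part))


# ---------------------------------------------------------------------------
# Metropolis-Hastings moves
# ---------------------------------------------------------------------------

def _dest_legal(group, x, state: ModelState, config: MCMCConfig) -> bool:
    """Can predictor x legally join existing ``group`` (x not currently in it)?"""
    if len(group) >= 3:
        return False
    if config.interaction_mode == "none":
        return False
    if config.interaction_mode == "snp_only" and (x == SEX or SEX in group):
        return False
    if len(group) == 2:
        # would create a triple; other triples must leave room
        n_tri = sum(1 for g in state.groups if len(g) == 3 and x not in g)
        if n_tri >= config.max_three_way:
            return False
    return True


def _move_destinations(x, state: ModelState, config: MCMCConfig):
    """Legal relocation targets for included predictor x: other groups with
    room, plus a fresh singleton when x currently shares a group."""
    src = next(g for g in state.groups if x in g)
    dests = []
    for g in state.groups:
        if g is src or g == src:
            continue
        if _dest_legal(g, x, state, config):
            dests.append(g)
    if len(src) > 1:
        dests.append(None)  # new singleton
    return src, dests


def _apply_move(state: ModelState, x, src, dest) -> ModelState:
    groups = [list(g) for g in state.groups if g != src and g != dest]
    rem = [p for p in src if p != x]
    if rem:
        groups.append(rem)
    if dest is None:
        groups.append([x])
    else:
        groups.append(list(dest) + [x])
    return ModelState(tuple(map(tuple, groups)))


def mcmc_run(y: np.ndarray, predictors: PredictorSet, config: MCMCConfig) -> MCMCRun:
    """Metropolis-Hastings chain over model states.

    Moves: add an excluded predictor as a new singleton group; remove a
    predictor currently in a singleton group; move a predictor to another
    group or split it out to a singleton; swap an included predictor for an
    excluded one in place.  Remove is restricted to singletons so that every
    move has a single-move reverse (a grouped predictor leaves via
    split-then-remove), keeping the chain reversible.  Proposals are uniform
    over the legal targets of the drawn move type; a draw with no legal
    target leaves the chain in place.

    Each recorded iteration is a sweep of ``moves_per_iteration`` elementary
    Metropolis-Hastings moves (default: one per predictor), so the nominal
    2000-iteration schedule mixes adequately even with thousands of candidate
    SNPs; the state at the end of each sweep enters the chain.
    """
    y = np.asarray(y, dtype=float)
    if predictors.n_predictors < 2:
        raise ParameterError("need at least 2 predictors")
    rng = np.random.default_rng(config.seed)
    move_names = list(_MOVE_WEIGHTS)
    move_p = np.array([_MOVE_WEIGHTS[k] for k in move_names])
    move_p = move_p / move_p.sum()

    ev_cache: dict = {}
    pr_cache: dict = {}

    def ev(state: ModelState) -> float:
        v = ev_cache.get(state.groups)
        if v is None:
            v = log_marginal_likelihood(state, y, predictors, config.tau2)
            ev_cache[state.groups] = v
        return v

    def prior(state: ModelState) -> float:
        key = state.groups
        v = pr_cache.get(key)
        if v is None:
            v = log_state_prior(state, predictors, config)
            pr_cache[key] = v
        return v

    all_ids = predictors.all_ids
    state = ModelState(((SEX,),)) if config.force_sex else ModelState()
    states, trace = [], np.empty(config.iterations)
    n_accept = 0
    sweep = config.moves_per_iteration or predictors.n_predictors

    for it in range(config.iterations * sweep):
        included = set(state.predictors)
        excluded = [p for p in all_ids if p not in included]
        incl_list = sorted(included)
        move = move_names[rng.choice(len(move_names), p=move_p)]
        proposal = None

        if move == "add":
            if excluded and state.n_predictors < config.max_predictors:
                e = excluded[rng.integers(len(excluded))]
                new = ModelState(state.groups + ((e,),))
                lqf = -np.log(len(excluded))
                rem_after = _removable_singletons(new, config)
                lqr = -np.log(len(rem_after))
                proposal = (new, lqf, lqr)
        elif move == "remove":
            cands = _removable_singletons(state, config)
            if cands:
                x = cands[rng.integers(len(cands))]
                new = ModelState(tuple(g for g in state.groups if g != (x,)))
                lqf = -np.log(len(cands))
                n_excl_after = len(excluded) + 1
                if new.n_predictors < config.max_predictors:
                    lqr = -np.log(n_excl_after)
                    proposal = (new, lqf, lqr)
        elif move == "move":
            if incl_list:
                x = incl_list[rng.integers(len(incl_list))]
                if not (config.force_sex and x == SEX and config.interaction_mode != "all"):
                    src, dests = _move_destinations(x, state, config)
                    if dests:
                        d = dests[rng.integers(len(dests))]
                        new = _apply_move(state, x, src, d)
                        lqf = -np.log(len(incl_list)) - np.log(len(dests))
                        _, dests_rev = _move_destinations(x, new, config)
                        lqr = -np.log(len(incl_list)) - np.log(len(dests_rev))
                        proposal = (new, lqf, lqr)
        else:  # swap
            swap_incl = [p for p in incl_list if not (config.force_sex and p == SEX)]
            if swap_incl and excluded:
                x = swap_incl[rng.integers(len(swap_incl))]
                e = excluded[rng.integers(len(excluded))]
                src = next(g for g in state.groups if x in g)
                legal = True
                if len(src) > 1:
                    if config.interaction_mode == "snp_only" and e == SEX:
                        legal = False
                    if config.interaction_mode == "none":
                        legal = False
                if legal:
                    groups = [g for g in state.groups if g != src]
                    groups.append(tuple(p for p in src if p != x) + (e,))
                    new = ModelState(tuple(groups))
                    proposal = (new, 0.0, 0.0)  # symmetric

        if proposal is not None:
            new, lqf, lqr = proposal
            log_alpha = (ev(new) + prior(new) + lqr) - (ev(state) + prior(state) + lqf)
            if np.log(rng.random()) < log_alpha:
                state = new
                n_accept += 1
        if (it + 1) % sweep == 0:
            states.append(state)
            trace[(it + 1) // sweep - 1] = ev(state)

    return MCMCRun(states=states, log_evidence=trace, config=config,
                   acceptance_rate=n_accept / (config.iterations * sweep))


def _removable_singletons(state: ModelState, config: MCMCConfig):
    return [g[0] for g in state.groups
            if len(g) == 1 and not (config.force_sex and g[0] == SEX)]


# ---------------------------------------------------------------------------
# posterior summaries and QTL calls
# ---------------------------------------------------------------------------

def posterior_summaries(run, config: MCMCConfig | None = None) -> PosteriorSummary:
    """Tabulate inclusion and co-grouping frequencies over retained samples."""
    if isinstance(run, MCMCRun):
        chain, trace = run.states, run.log_evidence
        config = config or run.config
    else:
        chain, trace = list(run), None
    if config is None:
        raise ParameterError("config required when passing a bare chain")
    if len(chain) != config.iterations:
        raise ParameterError("chain length does not match config.iterations")
    retained = chain[config.burn_in:]
    denom = len(retained)
    incl: dict = {}
    pair: dict = {}
    for st in retained:
        for g in st.groups:
            for p in g:
                incl[p] = incl.get(p, 0) + 1
            for a, b in itertools.combinations(sorted(g), 2):
                pair[(a, b)] = pair.get((a, b), 0) + 1
    return PosteriorSummary(
        inclusion={k: v / denom for k, v in incl.items()},
        pairwise={k: v / denom for k, v in pair.items()},
        retained_samples=denom,
        chain_log=trace,
    )


def call_qtl(summary: PosteriorSummary, marker_map, maf, threshold: float = 0.2,
             phenotype: str = "phenotype", snp_ids=None) -> list[QTLCall]:
    """Threshold posterior probabilities into QTL calls.

    Main calls: predictors (excluding sex) with inclusion >= threshold.
    GxS calls: (SNP, sex) pairs with co-grouping >= threshold.
    GxG calls: SNP-SNP pairs with co-grouping >= threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("threshold must be in (0, 1]")
    maf = np.asarray(maf, dtype=float)

    def info(j):
        if j < 0 or j >= len(marker_map):
            raise ParameterError(f"unknown marker id {j}")
        row = marker_map.iloc[j]
        name = snp_ids[j] if snp_ids is not None else row["marker"]
        return name, row["chrom"], float(row["mbp"]), float(maf[j])

    calls = []
    for p, prob in sorted(summary.inclusion.items()):
        if p == SEX or prob < threshold:
            continue
        name, chrom, mbp, f = info(p)
        calls.append(QTLCall(phenotype, name, chrom, mbp, prob, f, "main"))
    for (a, b), prob in sorted(summary.pairwise.items()):
        if prob < threshold:
            continue
        if a == SEX or b == SEX:
            j = b if a == SEX else a
            name, chrom, mbp, f = info(j)
            calls.append(QTLCall(phenotype, name, chrom, mbp, prob, f, "GxS", partner="SEX"))
        else:
            na, ca, pa, fa = info(a)
            nb, *_ = info(b)
            calls.append(QTLCall(phenotype, na, ca, pa, prob, fa, "GxG", partner=nb))
    return calls


# ---------------------------------------------------------------------------
# exact enumeration (small predictor counts)
# ---------------------------------------------------------------------------

def _legal_partitions(items, config: MCMCConfig, n_three: int = 0):
    """Yield all partitions of ``items`` into groups of size <= 3 honouring
    the three-way cap and the interaction mode."""
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    max_mates = 0 if config.interaction_mode == "none" else 2
    if config.interaction_mode == "snp_only" and first == SEX:
        max_mates = 0
    for k in range(max_mates + 1):
        for mates in itertools.combinations(rest, k):
            if config.interaction_mode == "snp_only" and SEX in mates:
                continue
            tri = n_three + (1 if k == 2 else 0)
            if tri > config.max_three_way:
                continue
            block = (first,) + mates
            remaining = [x for x in rest if x not in mates]
            for sub in _legal_partitions(remaining, config, tri):
                yield (block,) + sub


def enumerate_posterior(y: np.ndarray, predictors: PredictorSet,
                        config: MCMCConfig) -> PosteriorSummary:
    """Exact posterior inclusion and pairwise probabilities by summing
    prior x evidence over every legal model state (feasible for small
    predictor counts; intended as a diagnostic and test oracle)."""
    y = np.asarray(y, dtype=float)
    ids = predictors.all_ids
    log_w, recs = [], []
    for k in range(min(config.max_predictors, len(ids)) + 1):
        for subset in itertools.combinations(ids, k):
            if config.force_sex and SEX not in subset:
                continue
            for part in _legal_partitions(subset, config):
                st = ModelState(part)
                lw = (log_marginal_likelihood(st, y, predictors, config.tau2)
                      + log_state_prior(st, predictors, config))
                log_w.append(lw)
                recs.append(st)
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    incl: dict = {}
    pair: dict = {}
    for st, wt in zip(recs, w):
        for g in st.groups:
            for p in g:
                incl[p] = incl.get(p, 0.0) + wt
            for a, b in itertools.combinations(sorted(g), 2):
                pair[(a, b)] = pair.get((a, b), 0.0) + wt
    return PosteriorSummary(inclusion=incl, pairwise=pair, retained_samples=0)


# ---------------------------------------------------------------------------
# per-state fit (used for cross-validated prediction)
# ---------------------------------------------------------------------------

@dataclass
class StateFit:
    """Posterior-mean fit of one model state on a training set."""

    state: ModelState
    mu: float
    betas: list = field(default_factory=list)  # (group, level codes, coefs)

    def predict(self, predictors: PredictorSet) -> np.ndarray:
        n = len(predictors.sex)
        pred = np.full(n, self.mu)
        for group, levels, coefs in self.betas:
            code = np.zeros(n, dtype=np.int64)
            for pid in sorted(group):
                code = code * 3 + predictors.codes(pid).astype(np.int64)
            # joint levels unseen in training contribute the intercept only
            pos = np.searchsorted(levels, code)
            pos_c = np.clip(pos, 0, len(levels) - 1)
            seen = levels[pos_c] == code
            pred += np.where(seen, coefs[pos_c], 0.0)
        return pred


def fit_state(state: ModelState, y: np.ndarray, predictors: PredictorSet,
              tau2: float = 0.2) -> StateFit:
    """Posterior-mean level effects of a state (ridge solution implied by the
    conjugate prior) plus the matching intercept."""
    y = np.asarray(y, dtype=float)
    if not state.groups:
        return StateFit(state=state, mu=float(y.mean()))
    blocks = [_group_design(g, predictors) for g in state.groups]
    X = np.hstack([b[0] for b in blocks])
    q = X.shape[1]
    colmeans = X.mean(axis=0)
    Xc = X - colmeans
    yc = y - y.mean()
    S = Xc.T @ Xc + np.eye(q) / tau2
    beta = np.linalg.solve(S, Xc.T @ yc)
    mu = float(y.mean() - colmeans @ beta)
    betas, off = [], 0
    for g, (Xg, levels) in zip(state.groups, blocks):
        w = Xg.shape[1]
        betas.append((g, levels, beta[off:off + w].copy()))
        off += w
    return StateFit(state=state, mu=mu, betas=betas)
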