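"""Synthetic heterogeneous-stock (HS) population generator.

An HS population descends from eight inbred founder strains through many
generations of pseudo-random mating, so each animal's genome is a fine-grained
mosaic of founder chromosomes.  This module simulates that structure with known
ground truth — founder alleles, per-haplotype founder of origin, sex, and
phenotypes built from configurable sex, additive, gene-by-sex (GxS),
gene-by-gene (GxG) and polygenic components — so every downstream mapping stage
can be validated against the generating truth without any external data.

All randomness flows from a single master seed through
:func:`gxsmap._common.child_seeds`, so identical seeds give bit-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import ParameterError, child_seeds

N_FOUNDERS = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Alleles of the eight inbred founders at each biallelic marker.

    ``alleles`` is an (8, m) 0/1 matrix; ``marker_map`` has columns
    ``marker`` (id), ``chrom`` and ``mbp`` with positions strictly increasing
    within a chromosome.
    """

    alleles: np.ndarray
    marker_map: pd.DataFrame

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def __post_init__(self):
        if self.alleles.shape[0] != N_FOUNDERS:
            raise ParameterError(f"founder panel must have {N_FOUNDERS} rows")


@dataclass
class HSPopulation:
    """A simulated HS cohort with full ancestry truth.

    ``haplotypes`` is an (n, m, 2) array of founder ids (0–7), one per
    inherited chromosome copy; ``genotypes`` the (n, m) 0/1/2 allele counts
    implied by the haplotypes and founder alleles; ``sex`` codes male as 1.
    """

    genotypes: np.ndarray
    haplotypes: np.ndarray
    sex: np.ndarray
    marker_map: pd.DataFrame
    founders: FounderPanel
    pedigree_depth: int
    _ancestry: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def ancestry(self) -> np.ndarray:
        """Founder-dosage tensor (n, m, 8); each (individual, marker) slice sums to 2."""
        if self._ancestry is None:
            self._ancestry = ancestry_from_haplotypes(self.haplotypes)
        return self._ancestry

    def ancestry_block(self, j: int) -> np.ndarray:
        """The (n, 8) founder-dosage block at marker ``j``."""
        return self.ancestry[:, j, :].astype(float)


@dataclass
class PhenotypeSpec:
    """Generative phenotype architecture.

    ``main_qtl``: list of (marker index, additive effect per allele copy).
    ``gxs_qtl``: list of (marker index, effect) or (marker index, effect, sex)
    where the additive effect applies only in the given sex (1 = male, the
    default).  ``gxg_qtl``: list of (marker a, marker b, 3x3 effect table
    indexed by the two genotypes).  The polygenic component has covariance
    proportional to the allelic-correlation kinship of the population and is
    scaled so its variance share relative to (polygenic + noise) equals
    ``h2_polygenic``.
    """

    mu: float = 0.0
    beta_sex: float = 0.0
    main_qtl: list = field(default_factory=list)
    gxs_qtl: list = field(default_factory=list)
    gxg_qtl: list = field(default_factory=list)
    h2_polygenic: float = 0.0
    sigma_e: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(
    m: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    chrom_sizes: list[float] | None = None,
    seed: int = 0,
) -> FounderPanel:
    """Draw founder alleles so the expected HS minor-allele frequency per
    marker is near a value drawn uniformly from [maf_low, maf_high].

    Each founder contributes 1/8 of the HS gene pool, so a marker carried by
    ``k`` founders has expected population frequency ``k/8``; ``k`` is the
    rounding of ``8p`` clipped to [1, 7], which also rules out monomorphic
    markers.  ``chrom_sizes`` are chromosome lengths in Mbp (default one
    100-Mbp chromosome); markers are spread over chromosomes proportionally
    to length, at uniform positions.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ParameterError("need 0 < maf_low <= maf_high <= 0.5")
    if chrom_sizes is None:
        chrom_sizes = [100.0]
    if any(s <= 0 for s in chrom_sizes):
        raise ParameterError("chromosome sizes must be positive")

    rng = np.random.default_rng(seed)

    # allocate markers to chromosomes proportional to size, >= 1 each if possible
    sizes = np.asarray(chrom_sizes, dtype=float)
    counts = np.floor(m * sizes / sizes.sum()).astype(int)
    while counts.sum() < m:
        counts[np.argmax(sizes / np.maximum(counts, 0.5))] += 1
    while counts.sum() > m:
        counts[np.argmax(counts)] -= 1

    chroms, positions = [], []
    for c, (nm, size) in enumerate(zip(counts, sizes), start=1):
        if nm == 0:
            continue
        pos = np.sort(rng.uniform(0.0, size, nm))
        # enforce strict increase (float ties are vanishingly rare but possible)
        for i in range(1, nm):
            if pos[i] <= pos[i - 1]:
                pos[i] = np.nextafter(pos[i - 1], np.inf)
        chroms.extend([c] * nm)
        positions.extend(pos)

    marker_map = pd.DataFrame(
        {"marker": [f"m{i}" for i in range(m)], "chrom": chroms, "mbp": positions}
    )

    p = rng.uniform(maf_low, maf_high, m)
    k = np.clip(np.rint(N_FOUNDERS * p).astype(int), 1, N_FOUNDERS - 1)
    alleles = np.zeros((N_FOUNDERS, m), dtype=np.int8)
    for j in range(m):
        carriers = rng.choice(N_FOUNDERS, size=k[j], replace=False)
        alleles[carriers, j] = 1
    return FounderPanel(alleles=alleles, marker_map=marker_map)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _odd_crossover_prob(marker_map: pd.DataFrame, recomb_per_mb: float) -> np.ndarray:
    """Per-interval probability that an odd number of crossovers separates
    adjacent markers (Poisson crossovers, rate per Mbp); free recombination at
    chromosome boundaries and at the first marker (random starting strand)."""
    m = len(marker_map)
    p = np.empty(m)
    p[0] = 0.5
    d = np.diff(marker_map["mbp"].to_numpy())
    new_chrom = np.diff(marker_map["chrom"].to_numpy()) != 0
    p[1:] = np.where(new_chrom, 0.5, 0.5 * (1.0 - np.exp(-2.0 * recomb_per_mb * np.abs(d))))
    return p


def _meiose(hap: np.ndarray, parents: np.ndarray, p_odd: np.ndarray, rng) -> np.ndarray:
    """Produce one gamete per row of ``parents`` from haplotype array
    ``hap`` (N, m, 2).  Strand switches where a Bernoulli(p_odd) draw fires;
    cumulative parity along markers gives the copied strand."""
    n_off, m = len(parents), hap.shape[1]
    toggles = rng.random((n_off, m)) < p_odd[None, :]
    strand = np.cumsum(toggles, axis=1) % 2
    ph = hap[parents]  # (n_off, m, 2)
    return np.where(strand == 0, ph[:, :, 0], ph[:, :, 1]).astype(np.int8)


def ancestry_from_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    """One-hot founder dosages (n, m, 8) from founder-id haplotypes (n, m, 2)."""
    n, m, _ = haplotypes.shape
    anc = np.zeros((n, m, N_FOUNDERS), dtype=np.uint8)
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    np.add.at(anc, (ii, jj, haplotypes[:, :, 0]), 1)
    np.add.at(anc, (ii, jj, haplotypes[:, :, 1]), 1)
    return anc


def simulate_hs_population(
    founders: FounderPanel,
    n: int,
    generations: int = 50,
    recomb_per_mb: float = 0.005,
    pct_male: float = 0.519,
    seed: int = 0,
    pop_size: int | None = None,
    ancestry_noise: float = 0.0,
) -> HSPopulation:
    """Breed an HS-like cohort by ``generations`` rounds of random mating.

    Generation 0 consists of ``pop_size`` (default ``n``) individuals whose
    two chromosome copies are whole, unrecombined founder chromosomes drawn
    uniformly; each later generation is bred by sampling two distinct parents
    per offspring and recombining their haplotypes with crossovers Poisson in
    map distance (``recomb_per_mb`` expected crossovers per Mbp per meiosis —
    the default 0.005 gives roughly the ~3 Mb mosaic resolution of a
    50-generation HS).  Sexes are i.i.d. Bernoulli(``pct_male``).

    ``ancestry_noise`` > 0 blends the true one-hot dosages with symmetric
    Dirichlet noise, emulating soft inferred founder probabilities:
    ``(1-eps)*truth + eps*2*Dirichlet(1,...,1)``.
    """
    if founders is None:
        raise ParameterError("founders is required")
    if n < 2:
        raise ParameterError("n must be >= 2")
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    if recomb_per_mb <= 0:
        raise ParameterError("recomb_per_mb must be > 0")

    m = founders.n_markers
    pop_size = max(pop_size or n, 4)
    seeds = child_seeds(seed, 4)
    rng = np.random.default_rng(seeds[0])
    p_odd = _odd_crossover_prob(founders.marker_map, recomb_per_mb)

    # generation 0: whole founder chromosomes
    hap = np.empty((pop_size, m, 2), dtype=np.int8)
    per_chrom = founders.marker_map["chrom"].to_numpy()
    for c in np.unique(per_chrom):
        mask = per_chrom == c
        draw = rng.integers(0, N_FOUNDERS, (pop_size, 2))
        hap[:, mask, 0] = draw[:, 0][:, None]
        hap[:, mask, 1] = draw[:, 1][:, None]

    for g in range(generations):
        n_off = n if g == generations - 1 else pop_size
        mothers = rng.integers(0, len(hap), n_off)
        shift = rng.integers(1, len(hap), n_off)
        fathers = (mothers + shift) % len(hap)  # distinct from mother
        gam_a = _meiose(hap, mothers, p_odd, rng)
        gam_b = _meiose(hap, fathers, p_odd, rng)
        hap = np.stack([gam_a, gam_b], axis=2)

    alleles_t = founders.alleles.T  # (m, 8)
    jj = np.arange(m)
    genotypes = (
        alleles_t[jj[None, :], hap[:, :, 0]] + alleles_t[jj[None, :], hap[:, :, 1]]
    ).astype(np.int8)

    sex_rng = np.random.default_rng(seeds[1])
    sex = (sex_rng.random(n) < pct_male).astype(np.int8)

    pop = HSPopulation(
        genotypes=genotypes,
        haplotypes=hap,
        sex=sex,
        marker_map=founders.marker_map.copy(),
        founders=founders,
        pedigree_depth=generations,
    )
    if ancestry_noise > 0.0:
        noise_rng = np.random.default_rng(seeds[2])
        hard = ancestry_from_haplotypes(hap).astype(float)
        dirich = noise_rng.dirichlet(np.ones(N_FOUNDERS), size=(n, m))
        pop._ancestry = (1.0 - ancestry_noise) * hard + ancestry_noise * 2.0 * dirich
    return pop


def add_redundant_snps(
    G: np.ndarray,
    marker_map: pd.DataFrame,
    fraction: float = 0.2,
    discord_rate: float = 0.01,
    seed: int = 0,
):
    """Genotyping-redundancy fixture: duplicate a ``fraction`` of marker
    columns next to their originals, flipping at most ``discord_rate`` of the
    duplicate's entries, so concordance-based pruning has planted work.

    Returns ``(G_aug, map_aug, dup_of)`` where ``dup_of[j]`` is the augmented
    column index of an inserted duplicate's source and -1 for original markers.
    Duplicates are genotype-level copies (noise emulates genotyping error), so
    they carry no ancestry record.
    """
    rng = np.random.default_rng(seed)
    n, m = G.shape
    n_dup = int(round(fraction * m))
    dup_src = np.sort(rng.choice(m, size=n_dup, replace=False)) if n_dup else np.array([], int)
    dup_set = set(dup_src.tolist())

    cols, rows_map, dup_of = [], [], []
    for j in range(m):
        cols.append(G[:, j])
        rows_map.append((marker_map["marker"].iat[j], marker_map["chrom"].iat[j],
                         marker_map["mbp"].iat[j]))
        dup_of.append(-1)
        if j in dup_set:
            src_aug = len(cols) - 1  # original's position in the augmented matrix
            dup = G[:, j].copy()
            # realized discordance stays at or below discord_rate by construction
            n_flip = int(rng.integers(0, int(discord_rate * n) + 1))
            if n_flip:
                idx = rng.choice(n, size=n_flip, replace=False)
                dup[idx] = (dup[idx] + rng.integers(1, 3, n_flip)) % 3
            cols.append(dup)
            nxt = marker_map["mbp"].iat[j + 1] if j + 1 < m and \
                marker_map["chrom"].iat[j + 1] == marker_map["chrom"].iat[j] else None
            pos = marker_map["mbp"].iat[j]
            newpos = (pos + nxt) / 2 if nxt is not None else pos + 1e-4
            rows_map.append((marker_map["marker"].iat[j] + "_dup",
                             marker_map["chrom"].iat[j], newpos))
            dup_of.append(src_aug)

    G_aug = np.column_stack(cols).astype(G.dtype)
    map_aug = pd.DataFrame(rows_map, columns=["marker", "chrom", "mbp"])
    return G_aug, map_aug, np.asarray(dup_of)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(pop: HSPopulation, spec: PhenotypeSpec):
    """Build a phenotype from the architecture in ``spec``.

    y = mu + beta_sex*sex + sum(additive) + sum(GxS, applied in one sex only)
      + sum(GxG joint-genotype terms) + polygenic + N(0, sigma_e^2) noise.

    Returns ``(y, truth)`` where ``truth`` records each component vector and
    its realized share of the total phenotypic variance.
    """
    if not (0.0 <= spec.h2_polygenic < 1.0):
        raise ParameterError("h2_polygenic must be in [0, 1)")
    if spec.sigma_e <= 0:
        raise ParameterError("sigma_e must be > 0")
    m = pop.n_markers
    for j, _ in spec.main_qtl:
        if not (0 <= j < m):
            raise ParameterError(f"main QTL index {j} out of range")
    for entry in spec.gxs_qtl:
        if not (0 <= entry[0] < m):
            raise ParameterError(f"GxS QTL index {entry[0]} out of range")
    for a, b, _ in spec.gxg_qtl:
        if not (0 <= a < m and 0 <= b < m):
            raise ParameterError("GxG QTL index out of range")

    n = pop.n_individuals
    seeds = child_seeds(spec.seed, 3)
    rng = np.random.default_rng(seeds[0])
    G = pop.genotypes.astype(float)
    sex = pop.sex.astype(float)

    comp = {}
    comp["sex"] = spec.beta_sex * sex
    main = np.zeros(n)
    for j, a in spec.main_qtl:
        main += a * G[:, j]
    comp["main"] = main
    gxs = np.zeros(n)
    for entry in spec.gxs_qtl:
        j, eff = entry[0], entry[1]
        which = entry[2] if len(entry) > 2 else 1
        gxs += eff * G[:, j] * (pop.sex == which)
    comp["gxs"] = gxs
    gxg = np.zeros(n)
    for a, b, table in spec.gxg_qtl:
        table = np.asarray(table, dtype=float)
        gxg += table[pop.genotypes[:, a], pop.genotypes[:, b]]
    comp["gxg"] = gxg

    if spec.h2_polygenic > 0.0:
        from .heritability import kinship_allelic_corr

        K = kinship_allelic_corr(pop.genotypes).K
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        u = L @ np.random.default_rng(seeds[1]).standard_normal(n)
        target_var = spec.sigma_e**2 * spec.h2_polygenic / (1.0 - spec.h2_polygenic)
        u = u * np.sqrt(target_var / max(u.var(), 1e-300))
        comp["polygenic"] = u
    else:
        comp["polygenic"] = np.zeros(n)

    comp["noise"] = np.random.default_rng(seeds[2]).normal(0.0, spec.sigma_e, n)

    y = spec.mu + sum(comp.values())
    total = y.var()
    truth = {
        "components": comp,
        "variance_share": {k: (v.var() / total if total > 0 else 0.0) for k, v in comp.items()},
        "total_variance": float(total),
        "spec": dataclasses.replace(spec),
    }
    return y, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(pop: HSPopulation, phenotypes: pd.DataFrame, outdir, manifest: dict | None = None):
    """Write genotypes (TSV, individuals x markers), the marker map (TSV),
    per-chromosome ancestry dosages (TSV), phenotypes+sex (CSV) and a YAML
    manifest into ``outdir``."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = pop.marker_map["marker"].tolist()
    pd.DataFrame(pop.genotypes, columns=ids).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    pop.marker_map.to_csv(outdir / "map.tsv", sep="\t", index=False)
    ph = phenotypes.copy()
    ph["sex"] = pop.sex
    ph.to_csv(outdir / "phenotypes.csv", index=False)
    anc = pop.ancestry
    for c in pop.marker_map["chrom"].unique():
        mask = (pop.marker_map["chrom"] == c).to_numpy()
        flat = anc[:, mask, :].reshape(pop.n_individuals, -1)
        cols = [f"{mid}_f{f}" for mid in pop.marker_map.loc[mask, "marker"] for f in range(N_FOUNDERS)]
        pd.DataFrame(flat, columns=cols).to_csv(outdir / f"ancestry_chr{c}.tsv", sep="\t", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest or {}, fh)
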