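"""Simulation of F2 family-pool genotypes, GBS read noise and QTL phenotypes.

An F2 family derives from intercrossing two F1 full sibs, themselves produced
by a pair cross of two diploid parents.  The allele frequency of a large pool
of F2 plants at a biallelic SNP is determined by the four founder allele
copies carried by the two F1 parents, so the pool "genotype" behaves like a
tetraploid dosage and takes values in quarters: {0, 0.25, 0.5, 0.75, 1}.

Genotyping-by-sequencing measures that pool frequency with binomial read
noise: with ``depth`` reads the observed frequency is
``Binomial(depth, true) / depth``, an unbiased but noisy estimate whose
variance q(1-q)/depth drives the depth-dependent bias studied downstream.

Two constructions of the true pool frequency are provided:

``independent``
    The four founder allele copies are independent Bernoulli(p) draws, i.e.
    pool frequency = Binomial(4, p)/4.  Per-SNP variance 0.25*p(1-p); the
    scaled genomic relationship matrix then has expected diagonal ~1.0 at
    infinite depth.  This is the default.

``f1_intercross``
    The two diploid parents carry alleles (a1,a2) and (b1,b2); each F1 sib
    inherits one allele from each parent, and the pool frequency is the mean
    of the four alleles of the two F1 sibs.  Allele copies are then positively
    correlated within a family, per-SNP variance 0.375*p(1-p), expected
    scaled diagonal ~1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

Depth = Union[int, Literal["infinite"]]

#: order of the per-dataset random sub-streams spawned from the root seed
SUBSTREAM_ORDER = ("frequencies", "pool_genotypes", "reads", "phenotypes")


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationScenario:
    """Settings for one simulated family-pool study.

    The genetic values are always standardized to variance 1, so the nuisance
    variances follow from the target heritabilities: with one replicate,
    sigma2_e = 1/h2 - 1 (= 3.0 at h2 = 0.25); with two replicates the
    uncorrelated family variance is sigma2_f = H2/h2 - 1 (= 0.5 at
    h2 = 0.25, H2 = 0.375) and the per-plot residual sigma2_e = 1/h2 - 1
    - sigma2_f (= 2.5).
    """

    n_families: int = 500
    n_snps: int = 1000
    n_qtl: int = 50
    depth: Depth = 5
    n_replicates: int = 1
    true_narrow_h2: float = 0.25
    true_broad_h2: float = 0.375
    seed: int = 0
    founder_model: str = "independent"

    def __post_init__(self):
        if self.n_families < 1 or self.n_snps < 1:
            raise ValidationError("n_families and n_snps must be positive")
        if not 0 < self.n_qtl <= self.n_snps:
            raise ValidationError("need 0 < n_qtl <= n_snps")
        if self.depth != "infinite" and (int(self.depth) != self.depth or self.depth < 1):
            raise ValidationError("depth must be a positive integer or 'infinite'")
        if not 0 < self.true_narrow_h2 <= self.true_broad_h2 < 1:
            raise ValidationError("need 0 < true_narrow_h2 <= true_broad_h2 < 1")
        if self.n_replicates not in (1, 2):
            raise ValidationError("n_replicates must be 1 or 2")
        if self.founder_model not in ("independent", "f1_intercross"):
            raise ValidationError(f"unknown founder_model {self.founder_model!r}")

    @property
    def var_y(self) -> float:
        """Total phenotypic variance implied by genetic variance 1."""
        return 1.0 / self.true_narrow_h2

    @property
    def sigma2_f(self) -> float:
        """Uncorrelated family variance (0 for single-replicate designs)."""
        if self.n_replicates == 1:
            return 0.0
        return self.true_broad_h2 * self.var_y - 1.0

    @property
    def sigma2_e(self) -> float:
        """Residual variance per observation."""
        return self.var_y - 1.0 - self.sigma2_f


@dataclass
class SimulatedDataset:
    """One realized dataset: truth, noisy observations and phenotypes."""

    scenario: SimulationScenario
    pop_freqs: np.ndarray           # (n_snps,)
    true_pool_freqs: np.ndarray     # (n_snps, n_families), multiples of 0.25
    obs_pool_freqs: np.ndarray      # (n_snps, n_families)
    qtl_indices: np.ndarray         # (n_qtl,)
    qtl_effects: np.ndarray         # (n_qtl,)
    genetic_values: np.ndarray      # (n_families,), empirical variance 1
    phenotypes: pd.DataFrame        # columns family, rep, trial, pop1, pop2, value
    family_ids: list = field(default_factory=list)
    snp_ids: list = field(default_factory=list)


def draw_population_frequencies(n_snps: int, seed) -> np.ndarray:
    """Per-SNP population allele frequencies, uniform on [0.05, 0.95]."""
    if n_snps < 0:
        raise ValidationError("n_snps must be non-negative")
    return _rng(seed).uniform(0.05, 0.95, size=n_snps)


def simulate_true_pool_frequencies(
    pop_freqs: np.ndarray,
    n_families: int,
    seed,
    founder_model: str = "independent",
) -> np.ndarray:
    """True F2 pool frequencies in quarters, SNPs x families.

    SNPs are treated as independent (no linkage / ancestral LD).
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if pop_freqs.size and (pop_freqs.min() < 0 or pop_freqs.max() > 1):
        raise ValidationError("population frequencies must lie in [0, 1]")
    if n_families < 0:
        raise ValidationError("n_families must be non-negative")
    rng = _rng(seed)
    p = pop_freqs[:, None]
    if founder_model == "independent":
        # four independent founder allele copies per family pool
        counts = rng.binomial(4, np.broadcast_to(p, (pop_freqs.size, n_families)))
        return counts / 4.0
    if founder_model == "f1_intercross":
        shape = (pop_freqs.size, n_families)
        a = (rng.random((2,) + shape) < p).astype(np.int8)   # parent 1 alleles a1, a2
        b = (rng.random((2,) + shape) < p).astype(np.int8)   # parent 2 alleles b1, b2
        # each F1 sib draws one allele from each parent; the F2 pool frequency
        # is the mean of the four alleles carried by the two F1 sibs
        ia = rng.integers(0, 2, size=(2,) + shape)
        ib = rng.integers(0, 2, size=(2,) + shape)
        x = np.take_along_axis(a, ia[:1], axis=0)[0] + np.take_along_axis(a, ia[1:], axis=0)[0]
        y = np.take_along_axis(b, ib[:1], axis=0)[0] + np.take_along_axis(b, ib[1:], axis=0)[0]
        return (x + y).astype(float) / 4.0
    raise ValidationError(f"unknown founder_model {founder_model!r}")


def sequence_pool_frequencies(true_pool_freqs: np.ndarray, depth: Depth, seed) -> np.ndarray:
    """GBS-observed frequencies: Binomial(depth, true)/depth per cell."""
    true_pool_freqs = np.asarray(true_pool_freqs, dtype=float)
    if depth == "infinite":
        return true_pool_freqs.copy()
    if int(depth) != depth or depth < 1:
        raise ValidationError("depth must be a positive integer or 'infinite'")
    return _rng(seed).binomial(int(depth), true_pool_freqs) / float(depth)


def simulate_phenotypes(
    true_pool_freqs: np.ndarray, scenario: SimulationScenario, seed
):
    """QTL phenotypes on the family pools.

    QTL are drawn uniformly without replacement among the SNPs; effects are
    standard normal; the resulting genetic values are standardized to
    empirical variance exactly 1 across families.  One replicate gives
    ``y = g + e``; two replicates add an iid family effect:
    ``y = g + f + e`` per plot.  The overall mean is 0 (any constant is
    absorbed by the fixed mean in REML).

    Returns ``(qtl_indices, qtl_effects, genetic_values, phenotypes)``.
    """
    n_snps, n_families = true_pool_freqs.shape
    if scenario.n_qtl > n_snps:
        raise ValidationError("n_qtl exceeds the number of SNPs")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_qtl, rng_eff, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    qtl = np.sort(rng_qtl.choice(n_snps, size=scenario.n_qtl, replace=False))
    effects = rng_eff.standard_normal(scenario.n_qtl)
    raw = effects @ true_pool_freqs[qtl]          # (n_families,)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise DegenerateDataError(
            "raw genetic values have zero variance; cannot standardize"
        )
    g = (raw - raw.mean()) / sd

    rows = []
    if scenario.n_replicates == 1:
        e = rng_noise.normal(0.0, np.sqrt(scenario.sigma2_e), n_families)
        for j in range(n_families):
            rows.append((j, 1, g[j] + e[j]))
    else:
        f = rng_noise.normal(0.0, np.sqrt(scenario.sigma2_f), n_families)
        e = rng_noise.normal(0.0, np.sqrt(scenario.sigma2_e), (n_families, 2))
        for j in range(n_families):
            for r in range(2):
                rows.append((j, r + 1, g[j] + f[j] + e[j, r]))
    pheno = pd.DataFrame(rows, columns=["family", "rep", "value"])
    pheno.insert(2, "trial", pd.NA)
    pheno.insert(3, "pop1", pd.NA)
    pheno.insert(4, "pop2", pd.NA)
    return qtl, effects, g, pheno


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Run the full generator with documented sub-stream order.

    The root seed is split into independent streams in the order
    frequencies -> pool genotypes -> reads -> phenotypes (which itself splits
    into QTL -> effects -> noise), so any stage can be regenerated
    independently.
    """
    ss = np.random.SeedSequence(scenario.seed)
    s_freq, s_pool, s_reads, s_phen = ss.spawn(4)
    pop = draw_population_frequencies(scenario.n_snps, np.random.default_rng(s_freq))
    true_f = simulate_true_pool_frequencies(
        pop, scenario.n_families, np.random.default_rng(s_pool), scenario.founder_model
    )
    obs_f = sequence_pool_frequencies(true_f, scenario.depth, np.random.default_rng(s_reads))
    qtl, eff, g, pheno = simulate_phenotypes(true_f, scenario, s_phen)
    fam_ids = [f"F{j + 1:04d}" for j in range(scenario.n_families)]
    snp_ids = [f"snp{i + 1:05d}" for i in range(scenario.n_snps)]
    pheno = pheno.copy()
    pheno["family"] = [fam_ids[j] for j in pheno["family"]]
    return SimulatedDataset(
        scenario=scenario,
        pop_freqs=pop,
        true_pool_freqs=true_f,
        obs_pool_freqs=obs_f,
        qtl_indices=qtl,
        qtl_effects=eff,
        genetic_values=g,
        phenotypes=pheno,
        family_ids=fam_ids,
        snp_ids=snp_ids,
    )


def simulate_empirical_dataset(
    n_families: int = 120,
    n_snps: int = 400,
    n_qtl: int = 40,
    mean_depth_range=(2.0, 70.0),
    n_trials: int = 4,
    n_parent_pops: int = 8,
    sigma2_p: float = 0.1,
    sigma2_f: float = 0.5,
    sigma2_e: float = 2.5,
    seed: int = 0,
    founder_model: str = "independent",
):
    """A field-trial-shaped synthetic dataset for the empirical-style pipeline.

    Unlike the scenario generator this one produces per-cell Poisson read
    depths spanning the depth bins, missing cells (depth 0), trial blocks
    assigned round-robin, two parent-population labels per family and two
    replicate plots.  Returns ``(PoolFrequencyMatrix, phenotypes, truth)``
    where ``truth`` records the simulated variance components.
    """
    from .snp_filters import PoolFrequencyMatrix

    ss = np.random.SeedSequence(seed)
    s_pop, s_pool, s_depth, s_reads, s_phen, s_misc = ss.spawn(6)
    pop = draw_population_frequencies(n_snps, np.random.default_rng(s_pop))
    true_f = simulate_true_pool_frequencies(
        pop, n_families, np.random.default_rng(s_pool), founder_model
    )
    rng_d = np.random.default_rng(s_depth)
    mean_depth = rng_d.uniform(*mean_depth_range, size=n_snps)
    depths = rng_d.poisson(mean_depth[:, None], size=(n_snps, n_families))
    rng_r = np.random.default_rng(s_reads)
    counts = rng_r.binomial(depths, true_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(depths > 0, counts / np.maximum(depths, 1), np.nan)
    missing = depths == 0

    scen = SimulationScenario(
        n_families=n_families, n_snps=n_snps, n_qtl=n_qtl, depth="infinite",
        n_replicates=2, seed=seed, founder_model=founder_model,
    )
    qtl, eff, g, _ = simulate_phenotypes(true_f, scen, s_phen)

    rng = np.random.default_rng(s_misc)
    pops = rng.integers(0, n_parent_pops, size=(n_families, 2))
    pop_eff = rng.normal(0.0, np.sqrt(sigma2_p), n_parent_pops)
    fam_eff = rng.normal(0.0, np.sqrt(sigma2_f), n_families)
    trial_eff = rng.normal(0.0, 1.0, n_trials)
    fam_ids = [f"F{j + 1:04d}" for j in range(n_families)]
    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]

    rows = []
    plot = 0
    for j in range(n_families):
        for r in (1, 2):
            t = plot % n_trials  # round-robin assignment of plots to trials
            e = rng.normal(0.0, np.sqrt(sigma2_e))
            val = trial_eff[t] + g[j] + fam_eff[j] + pop_eff[pops[j, 0]] + pop_eff[pops[j, 1]] + e
            rows.append((fam_ids[j], r, f"T{t + 1}", f"P{pops[j, 0] + 1}", f"P{pops[j, 1] + 1}", val))
            plot += 1
    pheno = pd.DataFrame(rows, columns=["family", "rep", "trial", "pop1", "pop2", "value"])

    matrix = PoolFrequencyMatrix(
        values=np.where(missing, 0.0, np.nan_to_num(obs)),
        missing=missing,
        snp_ids=snp_ids,
        family_ids=fam_ids,
        depths=depths.astype(float),
    )
    truth = {
        "sigma2_g": 1.0,
        "sigma2_f": sigma2_f,
        "sigma2_p": sigma2_p,
        "sigma2_e": sigma2_e,
        "qtl_indices": qtl.tolist(),
    }
    return matrix, pheno, truth
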