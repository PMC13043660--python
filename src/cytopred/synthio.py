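"""Synthetic cohort generator.

Emulates the statistical structure of a deeply phenotyped healthy cohort:
LD-block genotypes drawn from small haplotype pools (post-QC panel,
MAF >= 0.05), seasonally sampled collection dates, baseline covariates
(age, sex, BMI, immune cell counts, sex hormones, CMV serostatus) and
log2-scale stimulated-cytokine traits with either a genetics-dominant
("TCR-like") or environment-dominant ("TLR-like") variance partition.
Every planted effect is recorded in a Truth object so downstream stages
can be tested against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, InvalidConfigError

logger = logging.getLogger(__name__)

ARCHETYPES = ("TCR_LIKE", "TLR_LIKE", "NULL")

#: covariate columns emitted by simulate_covariates, in order
COVARIATE_COLUMNS = [
    "age", "sex", "bmi", "day_of_year",
    "neutrophils", "monocytes", "lymphocytes", "eosinophils", "basophils",
    "oestradiol", "progesterone", "testosterone",
    "cmv",
]

_CELL_COUNTS = {
    # (mean of log, sd of log); units 10^3 cells/ul, lognormal
    "neutrophils": (np.log(3.5), 0.30),
    "monocytes": (np.log(0.5), 0.30),
    "lymphocytes": (np.log(2.0), 0.25),
    "eosinophils": (np.log(0.15), 0.50),
    "basophils": (np.log(0.04), 0.40),
}

_HORMONES = {
    # hormone: (log-mean female, log-mean male, log-sd)
    "oestradiol": (np.log(80.0), np.log(25.0), 0.5),
    "progesterone": (np.log(3.0), np.log(0.3), 0.7),
    "testosterone": (np.log(0.35), np.log(5.0), 0.35),
}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the desk-scale study conditions."""

    n_individuals: int = 400
    n_blocks: int = 50
    block_size: int = 40
    haplotype_pool_size: int = 8
    maf_range: tuple = (0.05, 0.5)
    archetype: str = "NULL"
    n_causal: int = 0
    h2_genetic: float = 0.0
    env_effects: dict = field(default_factory=dict)
    noise_sd: Optional[float] = None
    missing_rate: float = 0.0
    n_traits: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 0 or self.n_blocks <= 0 or self.block_size <= 0:
            raise InvalidConfigError("dimensions must be positive")
        if self.haplotype_pool_size < 2:
            raise InvalidConfigError("haplotype_pool_size must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.archetype not in ARCHETYPES:
            raise InvalidConfigError(f"unknown archetype {self.archetype!r}")
        if self.n_causal > self.n_blocks * self.block_size:
            raise InvalidConfigError("n_causal exceeds panel size")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.h2_genetic < 1.0:
            raise InvalidConfigError("h2_genetic must be in [0, 1)")
        env_var = self._env_variance_budget()
        if self.h2_genetic + env_var > 1.0 + 1e-9:
            raise InvalidConfigError(
                "h2_genetic plus environmental variance budget exceeds 1"
            )

    def _env_variance_budget(self) -> float:
        """Approximate trait-variance fraction claimed by the env effects."""
        e = self.env_effects
        frac = (e.get("seasonal_a", 0.0) ** 2 + e.get("seasonal_b", 0.0) ** 2) / 2.0
        for key in ("age", "monocytes"):
            frac += e.get(key, 0.0) ** 2  # standardized covariates
        frac += e.get("cmv", 0.0) ** 2 * 0.35 * 0.65  # raw Bernoulli(0.35)
        frac += e.get("sex", 0.0) ** 2 * 0.25  # raw Bernoulli(0.5)
        frac += e.get("testosterone", 0.0) ** 2
        return frac

    # -- archetype factories: the canonical variance partitions ---------

    @classmethod
    def tcr_like(cls, n_individuals=400, seed=0, **overrides) -> "SimConfig":
        """Genetics-dominant trait: few moderate-effect loci, modest age/CMV."""
        kw = dict(
            n_individuals=n_individuals,
            archetype="TCR_LIKE",
            n_causal=5,
            h2_genetic=0.25,
            env_effects={
                "age": np.sqrt(0.05),
                "cmv": np.sqrt(0.03 / (0.35 * 0.65)),
                "sex": np.sqrt(0.02 / 0.25),
            },
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def tlr_like(cls, n_individuals=400, seed=0, **overrides) -> "SimConfig":
        """Environment-dominant trait: strong seasonality and monocyte effects,
        near-null polygenic background."""
        kw = dict(
            n_individuals=n_individuals,
            archetype="TLR_LIKE",
            n_causal=50,
            h2_genetic=0.02,
            env_effects={
                "seasonal_a": 0.63,   # (a^2+b^2)/2 ~= 0.25 seasonal fraction
                "seasonal_b": 0.32,
                "monocytes": np.sqrt(0.15),
                "age": 0.10,
                "sex": np.sqrt(0.02 / 0.25),
            },
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def null(cls, n_individuals=400, seed=0, **overrides) -> "SimConfig":
        """Pure-noise trait: zero heritability, zero environmental effects."""
        kw = dict(n_individuals=n_individuals, archetype="NULL", n_causal=0,
                  h2_genetic=0.0, env_effects={}, noise_sd=1.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TraitTruth:
    """Planted generative record for one cytokine trait."""

    causal_variant_ids: list
    causal_betas: list
    env_betas: dict
    intercept: float
    noise_sd: float
    realized_variance_fractions: dict
    covariate_scaling: dict  # covariate -> (mean, sd) used for standardization

    def to_dict(self) -> dict:
        return {
            "causal_variant_ids": list(self.causal_variant_ids),
            "causal_betas": [float(b) for b in self.causal_betas],
            "env_betas": {k: float(v) for k, v in self.env_betas.items()},
            "intercept": float(self.intercept),
            "noise_sd": float(self.noise_sd),
            "realized_variance_fractions": {
                k: float(v) for k, v in self.realized_variance_fractions.items()
            },
            "covariate_scaling": {
                k: [float(m), float(s)] for k, (m, s) in self.covariate_scaling.items()
            },
        }


@dataclass
class Truth:
    traits: dict  # trait name -> TraitTruth

    def to_dict(self) -> dict:
        return {name: t.to_dict() for name, t in self.traits.items()}


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # indexed by individual_id
    cytokines: pd.DataFrame   # log2 scale, indexed by individual_id
    truth: Truth


def _seed_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimConfig, individual_seed: Optional[int] = None
                       ) -> GenotypeMatrix:
    """Draw an LD-block dosage panel.

    Each block carries a pool of ``haplotype_pool_size`` haplotypes; an
    individual's block dosage is the sum of two independent pool draws, so
    variants sharing a haplotype pattern are in perfect LD while blocks are
    statistically independent. Positions place each block within < 250 kb
    and consecutive blocks > 1 Mb apart. The haplotype pools depend only on
    ``config.seed``; pass ``individual_seed`` to draw a fresh cohort from
    the same pools (used for replication cohorts).
    """
    pool_rng, draw_rng = _seed_streams(config.seed, 2)
    if individual_seed is not None:
        draw_rng = np.random.default_rng(individual_seed)

    n, b, m, h = (config.n_individuals, config.n_blocks, config.block_size,
                  config.haplotype_pool_size)
    lo, hi = config.maf_range
    dosages = np.empty((n, b * m))
    chroms, positions, ids = [], [], []
    spacing = 5_000  # bp between variants inside a block
    for blk in range(b):
        # per-variant allele frequencies, polymorphic within the pool
        freqs = pool_rng.uniform(lo, hi, size=m)
        pool = pool_rng.random((h, m)) < freqs
        col_means = pool.mean(axis=0)
        for j in np.flatnonzero((col_means == 0) | (col_means == 1)):
            flip = pool_rng.integers(h)
            pool[flip, j] = ~pool[flip, j]
        hap1 = draw_rng.integers(h, size=n)
        hap2 = draw_rng.integers(h, size=n)
        dosages[:, blk * m:(blk + 1) * m] = (
            pool[hap1].astype(float) + pool[hap2].astype(float)
        )
        start = 1 + blk * 1_500_000
        positions.extend(start + spacing * np.arange(m))
        chroms.extend(["1"] * m)
        ids.extend([f"rs{blk:03d}_{v:03d}" for v in range(m)])

    variants = pd.DataFrame({
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=int),
        "id": ids,
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(dosages=dosages, variants=variants)


def simulate_covariates(config: SimConfig, rng: Optional[np.random.Generator] = None
                        ) -> pd.DataFrame:
    """Baseline covariate table: demographics, sampling date, immune cell
    counts, sex hormones and CMV serostatus."""
    if rng is None:
        (rng,) = _seed_streams(config.seed + 1, 1)
    n = config.n_individuals
    data = {}
    data["age"] = rng.integers(20, 61, size=n)
    data["sex"] = rng.integers(0, 2, size=n)  # 0 female, 1 male
    a, b = (17 - 23.5) / 2.5, (32 - 23.5) / 2.5
    data["bmi"] = stats.truncnorm.ppf(rng.random(n), a, b, loc=23.5, scale=2.5)
    data["day_of_year"] = rng.integers(1, 366, size=n)
    for name, (mu, sd) in _CELL_COUNTS.items():
        data[name] = np.exp(rng.normal(mu, sd, size=n))
    sex = data["sex"]
    for name, (mu_f, mu_m, sd) in _HORMONES.items():
        mu = np.where(sex == 1, mu_m, mu_f)
        data[name] = np.exp(rng.normal(mu, sd, size=n))
    data["cmv"] = (rng.random(n) < 0.35).astype(int)
    idx = pd.Index([f"ind_{i}" for i in range(n)], name="individual_id")
    return pd.DataFrame(data, index=idx)[COVARIATE_COLUMNS]


def _seasonal_terms(doy: np.ndarray):
    angle = 2.0 * np.pi * np.asarray(doy, dtype=float) / 365.0
    return np.sin(angle), np.cos(angle)


def _env_components(covariates: pd.DataFrame, env_betas: dict, scaling: dict):
    """Build named environmental trait components from coefficients.

    Continuous covariates (age, monocytes, testosterone) enter standardized
    using the means/sds in ``scaling``; binary covariates (cmv, sex) enter
    raw; seasonality enters through sin/cos of the collection day.
    """
    n = len(covariates)
    s1, s2 = _seasonal_terms(covariates["day_of_year"].to_numpy())
    comps = {}
    comps["seasonality"] = (env_betas.get("seasonal_a", 0.0) * s1
                            + env_betas.get("seasonal_b", 0.0) * s2)
    for cov in ("age", "monocytes", "testosterone"):
        beta = env_betas.get(cov, 0.0)
        if beta:
            mean, sd = scaling[cov]
            comps[cov] = beta * (covariates[cov].to_numpy() - mean) / sd
        else:
            comps[cov] = np.zeros(n)
    comps["cmv"] = env_betas.get("cmv", 0.0) * covariates["cmv"].to_numpy(float)
    comps["sex"] = env_betas.get("sex", 0.0) * covariates["sex"].to_numpy(float)
    return comps


def simulate_cytokines(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                       config: SimConfig) -> tuple:
    """Generate the log2-scale cytokine panel and its Truth record.

    Per trait: intercept + sum(beta_j g_j) + env components + Gaussian
    noise. Causal betas are rescaled so that the planted-SNP component
    contributes exactly ``h2_genetic`` of unit total variance.
    """
    (rng,) = _seed_streams(config.seed + 2, 1)
    n = config.n_individuals
    if genotypes.n_individuals != n or len(covariates) != n:
        raise InvalidConfigError("genotype/covariate sizes disagree with config")

    scaling = {}
    for cov in ("age", "monocytes", "testosterone"):
        x = covariates[cov].to_numpy(float)
        scaling[cov] = (float(x.mean()), float(x.std() if x.std() > 0 else 1.0))

    env_budget = config._env_variance_budget()
    noise_sd = config.noise_sd
    if noise_sd is None:
        noise_sd = float(np.sqrt(max(1.0 - config.h2_genetic - env_budget, 0.05)))

    panel = {}
    truths = {}
    for t in range(config.n_traits):
        name = f"cyto_{config.archetype.lower()}_{t + 1}"
        intercept = 8.0  # plausible log2 pg/ml baseline
        if config.n_causal > 0 and config.h2_genetic > 0:
            causal_idx = rng.choice(genotypes.n_variants, size=config.n_causal,
                                    replace=False)
            raw_beta = rng.normal(size=config.n_causal)
            g = genotypes.dosages[:, causal_idx]
            comp = g @ raw_beta
            v = comp.var()
            if v <= 1e-10:
                raise InvalidConfigError(
                    "requested h2_genetic unattainable: causal set has zero variance")
            betas = raw_beta * np.sqrt(config.h2_genetic / v)
            genetic = g @ betas
            causal_ids = genotypes.variants["id"].iloc[causal_idx].tolist()
        else:
            betas = np.array([])
            genetic = np.zeros(n)
            causal_ids = []

        env = _env_components(covariates, config.env_effects, scaling)
        env_total = sum(env.values())
        noise = rng.normal(0.0, noise_sd, size=n)
        y = intercept + genetic + env_total + noise
        panel[name] = y

        total_var = y.var()
        fractions = {"genetic": float(genetic.var() / total_var),
                     "noise": float(noise.var() / total_var)}
        for key, comp in env.items():
            fractions[key] = float(np.var(comp) / total_var)
        truths[name] = TraitTruth(
            causal_variant_ids=causal_ids,
            causal_betas=list(betas),
            env_betas=dict(config.env_effects),
            intercept=intercept,
            noise_sd=noise_sd,
            realized_variance_fractions=fractions,
            covariate_scaling=scaling,
        )

    idx = covariates.index
    return pd.DataFrame(panel, index=idx), Truth(traits=truths)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full cohort draw: genotypes, covariates, cytokines (+missingness)."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    genotypes.individual_ids = covariates.index.to_numpy()
    cytokines, truth = simulate_cytokines(genotypes, covariates, config)
    if config.missing_rate > 0:
        cytokines, _ = inject_missingness(cytokines, config.missing_rate,
                                          seed=config.seed + 3)
    return SyntheticCohort(genotypes=genotypes, covariates=covariates,
                           cytokines=cytokines, truth=truth)


def inject_missingness(panel: pd.DataFrame, rate: float, seed: int) -> tuple:
    """MCAR mask: each cell independently missing with probability ``rate``.

    Returns (masked panel, boolean mask DataFrame; True = masked)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.shape) < rate
    mask_df = pd.DataFrame(mask, index=panel.index, columns=panel.columns)
    return panel.mask(mask_df), mask_df


def simulate_replication_cohort(config: SimConfig, truth: Truth,
                                intercept_shift: float, seed: int
                                ) -> SyntheticCohort:
    """Second cohort sharing the training cohort's generative coefficients.

    Genotypes are drawn from the same haplotype pools (same variants, same
    LD structure) but for new individuals; the trait equals the training
    generative value plus ``intercept_shift`` on the log2 scale, emulating
    a stimulus-concentration offset between cohorts. Rank-based evaluation
    is unaffected by the shift.
    """
    genotypes = simulate_genotypes(config, individual_seed=seed)
    rng_cov, rng_noise = _seed_streams(seed + 1, 2)
    covariates = simulate_covariates(config, rng=rng_cov)
    covariates.index = pd.Index(
        [f"rep_{i}" for i in range(config.n_individuals)], name="individual_id")
    genotypes.individual_ids = covariates.index.to_numpy()

    vidx = genotypes.variant_index()
    panel = {}
    for name, tt in truth.traits.items():
        cols = [vidx[v] for v in tt.causal_variant_ids]
        genetic = (genotypes.dosages[:, cols] @ np.asarray(tt.causal_betas)
                   if cols else np.zeros(config.n_individuals))
        env = _env_components(covariates, tt.env_betas, tt.covariate_scaling)
        noise = rng_noise.normal(0.0, tt.noise_sd, size=config.n_individuals)
        panel[name] = (tt.intercept + intercept_shift + genetic
                       + sum(env.values()) + noise)
    cytokines = pd.DataFrame(panel, index=covariates.index)
    return SyntheticCohort(genotypes=genotypes, covariates=covariates,
                           cytokines=cytokines, truth=truth)
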