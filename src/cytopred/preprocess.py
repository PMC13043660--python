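"""Variant QC, covariate transforms, seasonal encoding, normalization and
residualization.

QC thresholds default to the standard array-genotyping rules: variants
with call rate <= 0.95, MAF < 0.05, or an exact Hardy-Weinberg test
p < 0.001 are removed. Seasonality is encoded as a point on the unit
circle, s1 = sin(2*pi*doy/365), s2 = cos(2*pi*doy/365), so one full
revolution corresponds to a one-year cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, ndtri

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcParams:
    """Thresholds for the three variant filters.

    ``max_missing`` realizes the "call rate <= 0.95 removed" rule: variants
    with missingness >= 1 - 0.95 are dropped. MAF rule is a strict "< 0.05"
    (a variant at exactly 0.05 is retained); HWE rule removes p < 0.001.
    """

    max_missing: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 0.001

    def __post_init__(self):
        for v in (self.max_missing, self.maf_min, self.hwe_p_min):
            if not 0.0 < v < 1.0:
                raise ValueError("QC thresholds must lie in (0, 1)")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_hwe: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def encode_seasonality(doy):
    """Map day-of-year (1..366; the leap day folds onto 365) to the unit
    circle. Accepts scalars or arrays; returns (s1, s2)."""
    doy = np.asarray(doy, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day of year must lie in [1, 366]")
    doy = np.where(doy > 365, 365.0, doy)
    angle = 2.0 * np.pi * doy / 365.0
    return np.sin(angle), np.cos(angle)


def compute_maf(dosages) -> float:
    """Minor allele frequency from a dosage vector (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all dosages missing; MAF undefined")
    p_hat = obs.mean() / 2.0
    return float(min(p_hat, 1.0 - p_hat))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the total sample size and the minor-allele count, the
    p-value sums the probabilities of all heterozygote counts whose
    conditional probability does not exceed that of the observed count
    (the conventional exact test, not mid-p).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one individual")
    n_alt = 2 * n_aa + n_Aa
    n_minor = min(n_alt, 2 * n - n_alt)

    # attainable heterozygote counts share the parity of the minor count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[(n_minor - hets) // 2 <= n]  # homozygote-minor feasibility
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    hets = hets[hom_major >= 0]
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor

    logp = (gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(hets + 1)
            - gammaln(hom_major + 1) + hets * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_het = n_Aa
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with totals")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def apply_variant_qc(genotypes: GenotypeMatrix, params: QcParams = None):
    """Apply the three variant filters; returns (filtered panel, QcReport).

    A variant failing several criteria is counted once per criterion but
    removed once. Dosages are rounded to hard genotype calls for the HWE
    counts. An empty output panel is a warning, not an error.
    """
    if params is None:
        params = QcParams()
    D = genotypes.dosages
    n_ind, n_var = D.shape
    missing_frac = np.isnan(D).mean(axis=0)
    fail_call = missing_frac >= params.max_missing

    fail_maf = np.zeros(n_var, dtype=bool)
    fail_hwe = np.zeros(n_var, dtype=bool)
    for j in range(n_var):
        col = D[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            fail_maf[j] = True
            continue
        p_hat = obs.mean() / 2.0
        fail_maf[j] = min(p_hat, 1 - p_hat) < params.maf_min
        g = np.clip(np.round(obs), 0, 2).astype(int)
        n_aa = int((g == 2).sum())
        n_Aa = int((g == 1).sum())
        n_AA = int((g == 0).sum())
        fail_hwe[j] = hwe_exact_test(n_AA, n_Aa, n_aa) < params.hwe_p_min

    keep = ~(fail_call | fail_maf | fail_hwe)
    report = QcReport(
        n_input=n_var,
        n_retained=int(keep.sum()),
        n_fail_call_rate=int(fail_call.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
    )
    if report.n_retained == 0:
        logger.warning("variant QC removed every variant")
    return genotypes.select_variants(keep), report


def genotype_pca(genotypes: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """First k principal-component scores of the column-standardized
    dosage matrix (missing dosages mean-imputed per variant).

    Scores are ordered by decreasing explained variance; the sign of each
    component is arbitrary (fixed so the largest-magnitude coordinate of
    each loading vector is positive, for reproducibility)."""
    D = genotypes.dosages.copy()
    col_mean = np.nanmean(D, axis=0)
    nan_idx = np.where(np.isnan(D))
    D[nan_idx] = np.take(col_mean, nan_idx[1])
    D -= D.mean(axis=0)
    sd = D.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("genotype_pca: dropping %d zero-variance variants",
                       int((~keep).sum()))
    D = D[:, keep] / sd[keep]
    rank = min(D.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            scores[:, j] *= -1.0
    return scores


def inverse_rank_normalize(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    y_i = Phi^{-1}((r_i - c) / (n + 1 - 2c)), ties get average ranks,
    missing entries pass through untouched.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    v = x[obs]
    if v.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(v == v[0]):
        raise ValueError("constant vector: ranks carry no information")
    ranks = stats.rankdata(v, method="average")
    out = x.copy()
    out[obs] = ndtri((ranks - c) / (v.size + 1 - 2 * c))
    return out


def residualize(trait, covariate_matrix) -> np.ndarray:
    """Least-squares residuals of trait on [intercept | covariates].

    Complete cases only (caller must align). Constant covariate columns
    are dropped; remaining rank deficiency raises with the collinear
    columns named.
    """
    y = np.asarray(trait, dtype=float)
    if isinstance(covariate_matrix, pd.DataFrame):
        names = list(covariate_matrix.columns)
        X = covariate_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(covariate_matrix, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("residualize requires complete cases")
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j - 1])
        raise ValueError(f"rank-deficient covariates; collinear: {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


@dataclass
class ScalerParams:
    """Per-variable train-set mean/sd; zero-variance variables dropped."""

    columns: list
    means: np.ndarray
    sds: np.ndarray
    dropped: list = field(default_factory=list)


def fit_scaler(train_table: pd.DataFrame) -> ScalerParams:
    if len(train_table) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    means = train_table.mean(axis=0)
    sds = train_table.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = list(train_table.columns[~keep])
    if dropped:
        logger.warning("fit_scaler: dropping zero-variance columns %s", dropped)
    cols = list(train_table.columns[keep])
    return ScalerParams(columns=cols, means=means[keep].to_numpy(),
                        sds=sds[keep].to_numpy(), dropped=dropped)


def apply_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """(x - mean_train) / sd_train using train parameters only."""
    sub = table[params.columns]
    return (sub - params.means) / params.sds
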