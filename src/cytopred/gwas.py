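"""Univariate and multivariate association testing on adjusted cytokine
traits, plus lead-SNP extraction and genomic-inflation diagnostics.

The univariate scan is per-variant simple linear regression of an already
residualized, inverse-rank-normalized trait on allele dosage. The
multivariate test associates one variant with a linear combination of the
traits in a "cytokine network" (the central trait plus every trait whose
absolute Pearson correlation with it exceeds a threshold) via canonical
correlation: for a single dosage vector, rho^2 equals the R^2 of
regressing the dosage on the trait matrix, Wilks' lambda = 1 - rho^2, and
p comes from the F approximation F = ((n-q-1)/q) * rho^2/(1-rho^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


def run_univariate_gwas(genotypes: GenotypeMatrix, adjusted_trait) -> pd.DataFrame:
    """Per-variant simple linear regression, two-sided p from t on n-2 df.

    The trait must already be residualized/normalized; this function does
    not re-adjust. Complete cases per variant; monomorphic variants (or
    n < 3) yield missing results with a warning.
    """
    y = np.asarray(adjusted_trait, dtype=float)
    G = genotypes.dosages
    if len(y) != G.shape[0]:
        raise ValueError("trait length does not match genotype rows")

    valid = ~np.isnan(G) & ~np.isnan(y)[:, None]
    n = valid.sum(axis=0).astype(float)
    Gz = np.where(valid, G, 0.0)
    Yz = np.where(valid, y[:, None], 0.0)
    Sx = Gz.sum(axis=0)
    Sy = Yz.sum(axis=0)
    Sxx = (Gz * Gz).sum(axis=0)
    Sxy = (Gz * Yz).sum(axis=0)
    Syy = (Yz * Yz).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        Sxx_c = Sxx - Sx * Sx / n
        Sxy_c = Sxy - Sx * Sy / n
        Syy_c = Syy - Sy * Sy / n
        ok = (n >= 3) & (Sxx_c > 1e-12)
        beta = np.where(ok, Sxy_c / Sxx_c, np.nan)
        sse = Syy_c - beta * Sxy_c
        sigma2 = np.where(ok, sse / (n - 2), np.nan)
        se = np.sqrt(sigma2 / Sxx_c)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(n - 2, 1))
        # exact fit: zero residual variance -> p underflows to 0
        exact = ok & (se == 0) & (np.abs(beta) > 0)
        p = np.where(exact, 0.0, p)
        tstat = np.where(exact, np.inf * np.sign(beta), tstat)
    p = np.where(ok & ((se > 0) | exact), p, np.nan)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("univariate GWAS: %d variant(s) monomorphic or n<3; "
                       "missing results emitted", n_bad)

    out = genotypes.variants.copy()
    out = out.rename(columns={"chrom": "CHR", "pos": "POS", "id": "ID"})
    out["A1"] = out.pop("alt")  # effect allele = ALT
    out = out.drop(columns=["ref"])
    out["BETA"] = beta
    out["SE"] = se
    out["STAT"] = tstat
    out["P"] = p
    out["N"] = n.astype(int)
    return out[["CHR", "POS", "ID", "A1", "BETA", "SE", "STAT", "P", "N"]]


@dataclass
class CytokineNetwork:
    central_trait: str
    members: list
    correlation_values: dict


def build_cytokine_network(trait_matrix: pd.DataFrame, central: str,
                           threshold: float = 0.2) -> CytokineNetwork:
    """Members = central trait plus every trait with |Pearson r| > threshold
    against it (pairwise-complete observations)."""
    if central not in trait_matrix.columns:
        raise ValueError(f"central trait {central!r} not in matrix")
    corr = trait_matrix.corr(method="pearson")[central]
    members = [central]
    values = {}
    for t in trait_matrix.columns:
        if t == central:
            continue
        r = corr[t]
        values[t] = float(r)
        if np.isfinite(r) and abs(r) > threshold:
            members.append(t)
    return CytokineNetwork(central_trait=central, members=members,
                           correlation_values=values)


def run_multivariate_gwas(genotypes: GenotypeMatrix,
                          network_trait_matrix: pd.DataFrame) -> pd.DataFrame:
    """Canonical-correlation test of each variant against q member traits.

    For one dosage vector g, rho^2 is the R^2 of the least-squares
    regression of g on the (centered) trait matrix; loadings are the
    coefficient vector scaled to unit norm with the largest-magnitude
    loading positive. Wilks' lambda = 1 - rho^2 and
    F = ((n-q-1)/q) * rho^2 / (1-rho^2) on (q, n-q-1) df.
    """
    Y_full = network_trait_matrix.to_numpy(dtype=float)
    q = Y_full.shape[1]
    G = genotypes.dosages
    n_total = G.shape[0]
    if Y_full.shape[0] != n_total:
        raise ValueError("trait matrix rows do not match genotype rows")

    records = []
    trait_ok = ~np.isnan(Y_full).any(axis=1)
    for j in range(G.shape[1]):
        g = G[:, j]
        mask = trait_ok & ~np.isnan(g)
        n = int(mask.sum())
        if q < 1 or q >= n - 1:
            raise ValueError(f"need 1 <= q < n-1 (q={q}, n={n})")
        gv = g[mask] - g[mask].mean()
        Yv = Y_full[mask] - Y_full[mask].mean(axis=0)
        sst = float(gv @ gv)
        if sst <= 1e-12:
            records.append((np.nan, np.nan, np.nan, np.nan, None, n))
            continue
        coef, *_ = np.linalg.lstsq(Yv, gv, rcond=None)
        fitted = Yv @ coef
        rho2 = float(fitted @ fitted) / sst
        rho2 = min(max(rho2, 0.0), 1.0)
        norm = np.linalg.norm(coef)
        loadings = coef / norm if norm > 0 else coef
        if loadings[np.argmax(np.abs(loadings))] < 0:
            loadings = -loadings
        wilks = 1.0 - rho2
        if wilks <= 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((n - q - 1) / q) * rho2 / wilks
            p = float(stats.f.sf(f_stat, q, n - q - 1))
        records.append((np.sqrt(rho2), wilks, f_stat, p, loadings, n))

    out = genotypes.variants.copy()
    out = out.rename(columns={"chrom": "CHR", "pos": "POS", "id": "ID"})
    out["A1"] = out.pop("alt")
    out = out.drop(columns=["ref"])
    out["RHO"] = [r[0] for r in records]
    out["WILKS"] = [r[1] for r in records]
    out["F"] = [r[2] for r in records]
    out["P"] = [r[3] for r in records]
    out["LOADINGS"] = [
        ";".join(f"{v:.6g}" for v in r[4]) if r[4] is not None else ""
        for r in records
    ]
    out["N"] = [r[5] for r in records]
    return out


def find_lead_snps(sumstats: pd.DataFrame, window_bp: int = 500_000,
                   threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Greedy lead-SNP extraction.

    Repeatedly take the smallest remaining p below threshold, emit it, and
    mask every variant within +-window_bp on the same chromosome. Ties on
    p break by (CHR, POS, ID) ascending; output is independent of input
    row order.
    """
    df = sumstats.dropna(subset=["P"])
    df = df[df["P"] < threshold]
    if df.empty:
        return sumstats.iloc[0:0].copy()
    df = df.sort_values(["P", "CHR", "POS", "ID"], kind="mergesort")
    leads = []
    masked = np.zeros(len(df), dtype=bool)
    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy()
    for i in range(len(df)):
        if masked[i]:
            continue
        leads.append(df.index[i])
        within = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        masked |= within
    out = df.loc[leads].sort_values(["CHR", "POS"], kind="mergesort")
    return out.reset_index(drop=True)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi-square (1 df,
    from 1 - p) divided by the null chi-square median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
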