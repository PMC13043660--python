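"""Apply external polygenic-score weight files to a cohort and test
PGS-cytokine associations against a permutation null.

Scores are weighted sums of effect-allele dosages. Alleles are matched
against the panel's REF/ALT; a weight whose effect allele equals REF
contributes via the flipped dosage (2 - d); anything else is skipped and
logged (strand flips are never guessed). Significance of a PGS-cytokine
Spearman correlation is judged against a null distribution built by
permuting the cytokine vector, with the +1 smoothing convention so the
empirical p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .formats import PgsWeightRecord, match_effect_allele

logger = logging.getLogger(__name__)


@dataclass
class PgsProfile:
    scores: np.ndarray
    n_matched: int
    n_flipped: int
    n_skipped: int
    individual_ids: np.ndarray = None

    @property
    def n_total(self) -> int:
        return self.n_matched + self.n_flipped + self.n_skipped


def apply_pgs(genotypes: GenotypeMatrix, weights) -> PgsProfile:
    """score_i = sum of weight x effect-allele dosage over matchable
    variants; missing dosages contribute the cohort mean dosage.

    Weight records are located by rsID first, then by chrom:pos key.
    Raises (listing the first 10 unmatched keys) if nothing matches.
    """
    vidx = genotypes.variant_index()
    pos_idx = {f"{c}:{p}": j for j, (c, p) in
               enumerate(zip(genotypes.variants["chrom"],
                             genotypes.variants["pos"]))}
    scores = np.zeros(genotypes.n_individuals)
    matched = flipped = skipped = 0
    unmatched_keys = []
    for rec in weights:
        j = vidx.get(rec.variant_key, pos_idx.get(rec.variant_key))
        if j is None:
            skipped += 1
            unmatched_keys.append(rec.variant_key)
            continue
        orient = match_effect_allele(genotypes.variants.at[j, "ref"],
                                     genotypes.variants.at[j, "alt"],
                                     rec.effect_allele)
        if orient is None:
            skipped += 1
            logger.warning("apply_pgs: allele mismatch for %s; skipped",
                           rec.variant_key)
            continue
        d = genotypes.dosages[:, j].copy()
        d[np.isnan(d)] = np.nanmean(genotypes.dosages[:, j])
        if orient == "ref":
            d = 2.0 - d
            flipped += 1
        else:
            matched += 1
        scores += rec.effect_weight * d
    if matched + flipped == 0:
        raise ValueError("apply_pgs: zero matchable variants; first unmatched "
                         f"keys: {unmatched_keys[:10]}")
    return PgsProfile(scores=scores, n_matched=matched, n_flipped=flipped,
                      n_skipped=skipped,
                      individual_ids=np.asarray(genotypes.individual_ids))


@dataclass
class PermAssocResult:
    rho_observed: float
    p_permutation: float
    significant: bool
    n_perm: int
    null_mean: float
    null_sd: float


def pgs_association_permutation(score, trait, n_perm: int = 1000,
                                seed: int = 0) -> PermAssocResult:
    """Two-sided permutation test of the PGS-trait Spearman correlation.

    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1); significance flag
    at 0.05. Constant inputs yield a missing result.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(trait, dtype=float)
    mask = ~np.isnan(s) & ~np.isnan(t)
    s, t = s[mask], t[mask]
    if s.size < 3 or np.all(s == s[0]) or np.all(t == t[0]):
        logger.warning("pgs_association_permutation: degenerate pair")
        return PermAssocResult(np.nan, np.nan, False, n_perm, np.nan, np.nan)

    sr = stats.rankdata(s).astype(float)
    tr = stats.rankdata(t).astype(float)
    sr -= sr.mean()
    tr -= tr.mean()
    denom = np.sqrt((sr ** 2).sum() * (tr ** 2).sum())
    rho_obs = float(sr @ tr / denom)

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(s.size) for _ in range(n_perm)])
    null = (tr[perm_idx] @ sr) / denom
    p = (1.0 + np.sum(np.abs(null) >= abs(rho_obs))) / (n_perm + 1.0)
    return PermAssocResult(rho_observed=rho_obs, p_permutation=float(p),
                           significant=p < 0.05, n_perm=n_perm,
                           null_mean=float(null.mean()),
                           null_sd=float(null.std()))


def pgs_association_matrix(profiles: dict, panel: pd.DataFrame,
                           n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Permutation association of every PGS against every cytokine trait."""
    streams = np.random.SeedSequence(seed).spawn(len(profiles) * panel.shape[1])
    rows = []
    i = 0
    for name, prof in profiles.items():
        for trait in panel.columns:
            sub_seed = int(streams[i].generate_state(1)[0] % (2 ** 31))
            i += 1
            res = pgs_association_permutation(prof.scores,
                                              panel[trait].to_numpy(),
                                              n_perm=n_perm, seed=sub_seed)
            rows.append({"pgs": name, "trait": trait,
                         "rho": res.rho_observed, "p": res.p_permutation,
                         "significant": res.significant})
    return pd.DataFrame(rows)


def pgs_as_features(profiles: dict, cohort_features: pd.DataFrame
                    ) -> pd.DataFrame:
    """Append one standardized column per PGS to a feature table.

    ``profiles`` maps name -> PgsProfile with scores aligned to the feature
    table's rows (same individuals, same order).
    """
    out = cohort_features.copy()
    for name, prof in profiles.items():
        s = pd.Series(np.asarray(prof.scores, dtype=float),
                      index=(prof.individual_ids if prof.individual_ids
                             is not None else out.index))
        orphans = out.index.difference(s.index)
        if len(orphans):
            raise ValueError(f"PGS {name!r}: individuals without scores: "
                             f"{list(orphans[:10])}")
        s = s.reindex(out.index)
        sd = s.std(ddof=0)
        out[f"pgs_{name}"] = (s - s.mean()) / sd if sd > 0 else 0.0
    return out
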