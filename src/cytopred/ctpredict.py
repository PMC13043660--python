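"""Clumping+thresholding feature selection, the C+T polygenic predictor,
and the nested cross-validated model benchmark with explicit leakage modes.

Genetic feature selection runs a univariate GWAS (on covariate-adjusted,
inverse-rank-normalized traits) followed by greedy LD clumping: variants
below the primary p threshold seed clumps in ascending-p order and absorb
unassigned variants below the secondary threshold that sit within the
window and exceed the r^2 threshold. In TRAIN_ONLY mode selection is
re-run inside each training split; FULL_COHORT mode deliberately selects
on the whole cohort (including test folds) to expose the resulting
performance inflation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor

from .core import GenotypeMatrix
from .formats import match_effect_allele
from .gwas import run_univariate_gwas
from .preprocess import (encode_seasonality, fit_scaler, apply_scaler,
                         inverse_rank_normalize, residualize)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("ct", "ols", "ridge", "en", "rf", "gbt", "ann")
FEATURE_SETS = ("genetic", "combined")
LEAKAGE_MODES = ("TRAIN_ONLY", "FULL_COHORT")

#: covariate predictors entering the COMBINED feature set
PREDICTOR_COVARIATES = [
    "age", "bmi", "sex", "cmv", "s1", "s2",
    "neutrophils", "monocytes", "lymphocytes", "eosinophils", "basophils",
    "oestradiol", "progesterone", "testosterone",
]

#: covariates regressed out of the trait before the in-fold selection GWAS
GWAS_ADJUST_COVARIATES = [
    "age", "sex", "bmi", "s1", "s2",
    "neutrophils", "monocytes", "lymphocytes", "eosinophils", "basophils",
]


@dataclass
class ClumpParams:
    """C+T selection thresholds (defaults: genome-scale convention)."""

    p1: float = 1e-5
    p2: float = 1e-2
    r2_min: float = 0.5
    window_kb: float = 250.0

    def __post_init__(self):
        if self.p1 > self.p2:
            raise ValueError("p1 must not exceed p2")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


#: thresholds rescaled for the default 5,000-variant synthetic panel so the
#: expected number of chance-passing variants matches the genome-scale
#: setting (5,000 x 1e-2 = 50 ~ 4.8M x 1e-5 = 48)
DESK_SCALE_CLUMP = ClumpParams(p1=1e-2, p2=5e-2)


@dataclass
class ClumpResult:
    index_ids: list
    members: dict  # index id -> list of clumped member ids (index excluded)


@dataclass
class CtScoreModel:
    """Index variants with training-GWAS effect weights."""

    variants: pd.DataFrame  # columns: id, effect_allele, beta
    members: dict = field(default_factory=dict)


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of x against each column of Y over
    pairwise-complete observations."""
    out = np.full(Y.shape[1], np.nan)
    for j in range(Y.shape[1]):
        mask = ~np.isnan(x) & ~np.isnan(Y[:, j])
        if mask.sum() < 2:
            continue
        xv, yv = x[mask], Y[mask, j]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            out[j] = 0.0
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        out[j] = r * r
    return out


def clump(sumstats: pd.DataFrame, ld_genotypes: GenotypeMatrix,
          params: ClumpParams = None) -> ClumpResult:
    """Greedy LD clumping of a summary-statistics table.

    Variants with p < p1 seed clumps in ascending-p order (ties broken by
    CHR, POS, ID); each index absorbs unassigned variants with p < p2 on
    the same chromosome within the window whose r^2 with the index (in the
    LD-source cohort) exceeds r2_min. Raises if an index variant has no
    genotypes in the LD source.
    """
    if params is None:
        params = ClumpParams()
    window = params.window_kb * 1_000
    cand = sumstats.dropna(subset=["P"])
    cand = cand[cand["P"] < params.p2]
    cand = cand.sort_values(["P", "CHR", "POS", "ID"], kind="mergesort")
    vidx = ld_genotypes.variant_index()

    assigned = set()
    index_ids, members = [], {}
    ids = cand["ID"].to_numpy()
    ps = cand["P"].to_numpy()
    chroms = cand["CHR"].to_numpy()
    poss = cand["POS"].to_numpy()
    for i in range(len(cand)):
        if ps[i] >= params.p1:
            break  # sorted: no further index candidates
        if ids[i] in assigned:
            continue
        idx_id = ids[i]
        if idx_id not in vidx:
            raise ValueError(f"LD source lacks genotypes for index variant {idx_id}")
        index_ids.append(idx_id)
        assigned.add(idx_id)
        in_window = ((chroms == chroms[i])
                     & (np.abs(poss - poss[i]) <= window)
                     & np.array([v not in assigned for v in ids]))
        cols = [vidx[v] for v in ids[in_window] if v in vidx]
        window_ids = [v for v in ids[in_window] if v in vidx]
        if not cols:
            members[idx_id] = []
            continue
        r2 = _pairwise_r2(ld_genotypes.dosages[:, vidx[idx_id]],
                          ld_genotypes.dosages[:, cols])
        clumped = [v for v, r in zip(window_ids, r2)
                   if np.isfinite(r) and r > params.r2_min]
        assigned.update(clumped)
        members[idx_id] = clumped
    return ClumpResult(index_ids=index_ids, members=members)


def build_ct_model(clump_result: ClumpResult, sumstats: pd.DataFrame
                   ) -> CtScoreModel:
    """Index variants carry their training-GWAS betas; clumped members are
    discarded (standard C+T)."""
    sub = sumstats.set_index("ID").loc[clump_result.index_ids]
    variants = pd.DataFrame({
        "id": clump_result.index_ids,
        "effect_allele": sub["A1"].to_numpy(),
        "beta": sub["BETA"].to_numpy(),
    })
    return CtScoreModel(variants=variants, members=dict(clump_result.members))


def ct_score(genotypes: GenotypeMatrix, model: CtScoreModel) -> np.ndarray:
    """score_i = sum over index variants of beta x effect-allele dosage.

    Alleles are matched against the scored panel's REF/ALT (mismatches are
    skipped and logged, never strand-guessed); a missing dosage contributes
    the variant's mean dosage in the scored cohort.
    """
    vidx = genotypes.variant_index()
    scores = np.zeros(genotypes.n_individuals)
    n_used = 0
    for _, row in model.variants.iterrows():
        j = vidx.get(row["id"])
        if j is None:
            logger.warning("ct_score: variant %s absent from panel", row["id"])
            continue
        ref = genotypes.variants.at[j, "ref"]
        alt = genotypes.variants.at[j, "alt"]
        orient = match_effect_allele(ref, alt, row["effect_allele"])
        if orient is None:
            logger.warning("ct_score: allele mismatch for %s; skipped", row["id"])
            continue
        d = genotypes.dosages[:, j].copy()
        mean_d = np.nanmean(d)
        d[np.isnan(d)] = mean_d
        if orient == "ref":
            d = 2.0 - d
        scores += row["beta"] * d
        n_used += 1
    if n_used == 0:
        raise ValueError("ct_score: zero matchable variants")
    return scores


@dataclass
class FoldPlan:
    folds: list  # k disjoint integer index arrays
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, fold: int):
        test = self.folds[fold]
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train), np.sort(test)


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random partition into k folds with sizes differing by at most 1."""
    if n < k:
        raise ValueError(f"cannot split n={n} into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return FoldPlan(folds=[np.sort(f) for f in np.array_split(perm, k)], seed=seed)


# --------------------------------------------------------------- model zoo

HYPER_GRIDS = {
    "ols": {},
    "ridge": {"alpha": [1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0, 100.0, 1000.0]},
    "en": {"alpha": [1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0, 100.0, 1000.0],
           "l1_ratio": [0.1, 0.3, 0.5, 0.7, 0.9]},
    "rf": {"max_depth": [2, 4, 6, 8, 12, None],
           "max_features": [1 / 3, 2 / 3, 1.0],
           "max_samples": [0.632, 0.8, None]},
    "gbt": {"n_estimators": [50, 100, 250],
            "learning_rate": [0.01, 0.05, 0.1],
            "max_depth": [2, 4, 6],
            "max_features": [1 / 3, 2 / 3, 1.0]},
    "ann": {"n_layers": [1, 2, 3],
            "width": [20, 50, 100, 200],
            "batch_size": [1, 32, 64],
            "learning_rate_init": [1e-4, 5e-3, 1e-3],
            "alpha": [0.0, 1e-4, 1e-6]},  # L2 penalty
}

DEFAULT_CONFIGS = {
    "ols": {},
    "ridge": {"alpha": 1.0},
    "en": {"alpha": 0.01, "l1_ratio": 0.5},
    "rf": {"max_depth": None, "max_features": 1 / 3, "max_samples": 0.8},
    "gbt": {"n_estimators": 100, "learning_rate": 0.05, "max_depth": 4,
            "max_features": 1 / 3},
    "ann": {"n_layers": 1, "width": 50, "batch_size": 32,
            "learning_rate_init": 1e-3, "alpha": 1e-4},
}


def build_estimator(model_kind: str, config: dict, seed: int = 0):
    if model_kind == "ols":
        return LinearRegression()
    if model_kind == "ridge":
        return Ridge(alpha=config["alpha"])
    if model_kind == "en":
        return ElasticNet(alpha=config["alpha"], l1_ratio=config["l1_ratio"],
                          max_iter=5000)
    if model_kind == "rf":
        return RandomForestRegressor(
            n_estimators=500, max_depth=config["max_depth"],
            max_features=config["max_features"], max_samples=config["max_samples"],
            bootstrap=True, random_state=seed, n_jobs=1)
    if model_kind == "gbt":
        return GradientBoostingRegressor(
            n_estimators=config["n_estimators"], learning_rate=config["learning_rate"],
            max_depth=config["max_depth"], max_features=config["max_features"],
            random_state=seed)
    if model_kind == "ann":
        return MLPRegressor(
            hidden_layer_sizes=tuple([config["width"]] * config["n_layers"]),
            batch_size=config["batch_size"],
            learning_rate_init=config["learning_rate_init"],
            alpha=config["alpha"], early_stopping=True, validation_fraction=0.1,
            n_iter_no_change=10, max_iter=500, random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def fit_predict(model_kind: str, config: dict, X_train, y_train, X_test,
                seed: int = 0):
    """Fit one learner and return out-of-sample predictions.

    Zero-column feature matrices fall back to intercept-only predictions.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if not (np.isfinite(X_train).all() and np.isfinite(X_test).all()):
        raise ValueError("non-finite feature values")
    if X_train.shape[1] == 0:
        return np.full(X_test.shape[0], y_train.mean())
    est = build_estimator(model_kind, config, seed=seed)
    est.fit(X_train, y_train)
    return est.predict(X_test)


def _enumerate_grid(grid: dict) -> list:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def random_search(model_kind: str, X, y, grid: dict = None, n_configs: int = 25,
                  inner_k: int = 5, seed: int = 0):
    """Randomized hyperparameter search via internal cross-validation.

    Samples up to ``n_configs`` distinct configurations from the grid (all
    of them when the grid is that small) and returns the one maximizing the
    mean inner-fold Spearman correlation on the training data.
    """
    from .evaluate import spearman_eval

    if grid is None:
        grid = HYPER_GRIDS[model_kind]
    configs = _enumerate_grid(grid)
    rng = np.random.default_rng(seed)
    if len(configs) > n_configs:
        chosen = rng.choice(len(configs), size=n_configs, replace=False)
        configs = [configs[i] for i in chosen]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plan = make_folds(len(y), k=inner_k, seed=seed)

    best_config, best_score = None, -np.inf
    for config in configs:
        rhos = []
        try:
            for f in range(plan.k):
                tr, te = plan.split(f)
                pred = fit_predict(model_kind, config, X[tr], y[tr], X[te],
                                   seed=seed)
                rho, _ = spearman_eval(pred, y[te])
                if np.isfinite(rho):
                    rhos.append(rho)
        except ValueError as exc:
            logger.warning("random_search: configuration %s skipped (%s)",
                           config, exc)
            continue
        score = np.mean(rhos) if rhos else -np.inf
        if score > best_score:
            best_score, best_config = score, config
    if best_config is None:
        raise ValueError("random_search: every configuration failed")
    return best_config, best_score


# ------------------------------------------------------------- benchmark

def covariate_features(covariates: pd.DataFrame) -> pd.DataFrame:
    """Predictor covariates with day-of-year replaced by the seasonal
    unit-circle encoding (s1, s2)."""
    s1, s2 = encode_seasonality(covariates["day_of_year"].to_numpy())
    feats = covariates.drop(columns=["day_of_year"]).copy()
    feats["s1"] = s1
    feats["s2"] = s2
    return feats[PREDICTOR_COVARIATES]


def select_genetic_features(genotypes: GenotypeMatrix, trait: np.ndarray,
                            covariates: pd.DataFrame,
                            clump_params: ClumpParams = None):
    """GWAS + clumping on one cohort; returns (CtScoreModel, sumstats).

    The trait is residualized on the standard adjustment covariates and
    inverse-rank normalized before the per-variant regression (two-stage
    adjustment).
    """
    feats = covariate_features(covariates)
    adj_cols = [c for c in GWAS_ADJUST_COVARIATES if c in feats.columns]
    resid = residualize(trait, feats[adj_cols])
    y_adj = inverse_rank_normalize(resid)
    sumstats = run_univariate_gwas(genotypes, y_adj)
    result = clump(sumstats, genotypes, clump_params)
    model = build_ct_model(result, sumstats)
    return model, sumstats


def _genetic_feature_frame(genotypes: GenotypeMatrix, variant_ids) -> pd.DataFrame:
    vidx = genotypes.variant_index()
    cols = {vid: genotypes.dosages[:, vidx[vid]] for vid in variant_ids
            if vid in vidx}
    return pd.DataFrame(cols, index=genotypes.individual_ids)


@dataclass
class BenchmarkReport:
    """Per-fold results of the cross-validated model comparison."""

    results: list            # dicts: fold, model, feature_set, rho, p, ...
    audit: list              # dicts: stage, fold, ids — leakage bookkeeping
    leakage_mode: str
    seed: int
    fold_plan: FoldPlan

    def performance(self) -> pd.DataFrame:
        return pd.DataFrame(self.results)

    def mean_rho(self, model: str, feature_set: str) -> float:
        df = self.performance()
        sel = df[(df["model"] == model) & (df["feature_set"] == feature_set)]
        return float(sel["rho"].mean())

    def category_importance(self, model: str, feature_set: str) -> pd.DataFrame:
        """Per-fold category importance table (folds x categories)."""
        df = self.performance()
        sel = df[(df["model"] == model) & (df["feature_set"] == feature_set)]
        rows = [r for r in sel["importance"] if r is not None]
        return pd.DataFrame(rows)


def run_benchmark(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                  trait: pd.Series, model_kinds=("ct", "rf"),
                  feature_sets=("genetic", "combined"),
                  leakage_mode: str = "TRAIN_ONLY",
                  fold_plan: Optional[FoldPlan] = None,
                  clump_params: ClumpParams = None, n_configs: int = 25,
                  search: bool = True, compute_importance: bool = False,
                  n_perm: int = 50, seed: int = 0) -> BenchmarkReport:
    """Cross-validated benchmark of the model zoo on one cytokine trait.

    TRAIN_ONLY re-runs the selection GWAS and clumping inside each
    training split; FULL_COHORT selects once on every individual
    (deliberate leakage). Complete-case individuals only; targets and
    features are z-scored with training-fold parameters. When
    ``compute_importance`` is set, permutation feature importance (with
    the SNPs category summed) is recorded for every fitted learner.
    """
    from .evaluate import permutation_importance, spearman_eval

    if leakage_mode not in LEAKAGE_MODES:
        raise ValueError(f"unknown leakage mode {leakage_mode!r}")
    complete = trait.notna().to_numpy()
    if complete.sum() < 20:
        raise ValueError("fewer than 20 complete cases")
    geno = genotypes.select_individuals(complete)
    cov = covariates.loc[complete]
    y_all = trait.to_numpy(dtype=float)[complete]
    ids_all = np.asarray(cov.index)
    n = len(y_all)
    if fold_plan is None:
        fold_plan = make_folds(n, k=5, seed=seed)

    cov_feats_all = covariate_features(cov)
    audit = []
    results = []

    full_model = None
    if leakage_mode == "FULL_COHORT":
        full_model, _ = select_genetic_features(geno, y_all, cov, clump_params)
        audit.append({"stage": "gwas_selection", "fold": None,
                      "ids": frozenset(ids_all)})

    for fold in range(fold_plan.k):
        tr, te = fold_plan.split(fold)
        if leakage_mode == "TRAIN_ONLY":
            sel_model, _ = select_genetic_features(
                geno.select_individuals(tr), y_all[tr], cov.iloc[tr],
                clump_params)
            audit.append({"stage": "gwas_selection", "fold": fold,
                          "ids": frozenset(ids_all[tr])})
        else:
            sel_model = full_model
        selected = list(sel_model.variants["id"])

        gen_all = _genetic_feature_frame(geno, selected)
        # mean-impute any missing dosages with training means
        if len(gen_all.columns) and gen_all.isna().any().any():
            train_means = gen_all.iloc[tr].mean()
            gen_all = gen_all.fillna(train_means)

        # train-fold scalers, applied to everything
        y_scaler = fit_scaler(pd.DataFrame({"y": y_all[tr]}))
        if y_scaler.dropped:
            y_tr_z = y_all[tr] - y_all[tr].mean()
            y_te_z = y_all[te] - y_all[tr].mean()
        else:
            y_tr_z = apply_scaler(pd.DataFrame({"y": y_all[tr]}), y_scaler)["y"].to_numpy()
            y_te_z = apply_scaler(pd.DataFrame({"y": y_all[te]}), y_scaler)["y"].to_numpy()

        feature_frames = {}
        if len(gen_all.columns):
            g_scaler = fit_scaler(gen_all.iloc[tr])
            gen_z = apply_scaler(gen_all, g_scaler)
        else:
            gen_z = gen_all
        c_scaler = fit_scaler(cov_feats_all.iloc[tr])
        cov_z = apply_scaler(cov_feats_all, c_scaler)
        feature_frames["genetic"] = gen_z
        feature_frames["combined"] = pd.concat([gen_z, cov_z], axis=1)

        audit.append({"stage": "model_fit", "fold": fold,
                      "ids": frozenset(ids_all[tr])})
        audit.append({"stage": "test_eval", "fold": fold,
                      "ids": frozenset(ids_all[te])})

        for kind in model_kinds:
            for fset in feature_sets:
                if kind == "ct" and fset != "genetic":
                    continue
                entry = {"fold": fold, "model": kind, "feature_set": fset,
                         "n_test": len(te), "n_variants": len(selected),
                         "config": None, "importance": None}
                if kind == "ct":
                    if not selected:
                        entry.update(rho=np.nan, p=np.nan)
                        results.append(entry)
                        continue
                    score = ct_score(geno, sel_model)
                    rho, pval = spearman_eval(score[te], y_all[te])
                    entry.update(rho=rho, p=pval)
                    results.append(entry)
                    continue

                X = feature_frames[fset]
                if X.shape[1] == 0:
                    entry.update(rho=np.nan, p=np.nan)
                    results.append(entry)
                    continue
                Xtr, Xte = X.iloc[tr], X.iloc[te]
                if search:
                    config, _ = random_search(kind, Xtr.to_numpy(), y_tr_z,
                                              n_configs=n_configs,
                                              seed=seed * 1000 + fold)
                else:
                    config = DEFAULT_CONFIGS[kind]
                est = build_estimator(kind, config, seed=seed * 1000 + fold)
                est.fit(Xtr.to_numpy(), y_tr_z)
                pred = est.predict(Xte.to_numpy())
                rho, pval = spearman_eval(pred, y_te_z)
                entry.update(rho=rho, p=pval, config=config)
                if compute_importance:
                    category_map = {c: "SNPs" for c in gen_z.columns}
                    category_map.update({"s1": "seasonality", "s2": "seasonality"})
                    imp = permutation_importance(
                        est, Xte, y_te_z, category_map=category_map,
                        n_perm=n_perm, seed=seed * 1000 + fold)
                    entry["importance"] = imp.category_scores
                results.append(entry)

    return BenchmarkReport(results=results, audit=audit,
                           leakage_mode=leakage_mode, seed=seed,
                           fold_plan=fold_plan)
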