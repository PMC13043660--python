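"""Rank-based evaluation, multi-model statistical comparison, permutation
feature importance, the data-leakage experiment and cross-cohort
validation.

Model quality is always Spearman correlation between predicted and
observed trait values on held-out data. Models are compared across traits
with Friedman's test followed by Conover post-hoc comparisons under Holm
correction; models whose pairwise comparisons are not rejected at alpha
form connected "indistinguishable" groups (the critical-difference-diagram
convention). Feature importance is the decrease in test-set Spearman when
one feature's test values are permuted, averaged over permutations, with
all selected variants summed into a single "SNPs" category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: covariates shared across cohorts for external validation (no hormones)
CROSS_COHORT_COVARIATES = [
    "age", "bmi", "sex", "cmv", "s1", "s2",
    "neutrophils", "monocytes", "lymphocytes", "eosinophils", "basophils",
]


def spearman_eval(predictions, observations):
    """Spearman rho with two-sided p (t approximation, average ranks on
    ties). Constant inputs yield (nan, nan) with a warning."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    mask = ~np.isnan(pred) & ~np.isnan(obs)
    pred, obs = pred[mask], obs[mask]
    if pred.size < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        logger.warning("spearman_eval: constant vector; result missing")
        return np.nan, np.nan
    rho, p = stats.spearmanr(pred, obs)
    return float(rho), float(p)


def _spearman_block(pred_blocks: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of pred_blocks against y (vectorized)."""
    pr = stats.rankdata(pred_blocks, axis=1).astype(float)
    yr = stats.rankdata(y).astype(float)
    pr -= pr.mean(axis=1, keepdims=True)
    yr -= yr.mean()
    denom = np.sqrt((pr ** 2).sum(axis=1) * (yr ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (pr @ yr) / denom
    return rhos


# ----------------------------------------------------- Friedman + Conover

@dataclass
class FriedmanConoverReport:
    friedman_stat: float
    friedman_p: float
    avg_ranks: pd.Series          # 1 = best average performance
    pairwise_p: pd.DataFrame      # Holm-adjusted Conover p-values
    groups: list                  # connected components of non-rejected pairs
    alpha: float
    dropped_traits: list = field(default_factory=list)


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def friedman_conover(perf: pd.DataFrame, alpha: float = 0.05
                     ) -> FriedmanConoverReport:
    """Friedman test over within-trait ranks plus Conover post-hoc.

    ``perf``: rows = model variants, columns = traits, entries = mean test
    Spearman. Columns containing missing entries are dropped with a
    warning. Pairs whose Holm-adjusted Conover p exceeds alpha are
    connected; groups are the connected components.
    """
    if perf.shape[0] < 3 or perf.shape[1] < 2:
        raise ValueError("need >= 3 models and >= 2 traits")
    dropped = list(perf.columns[perf.isna().any(axis=0)])
    if dropped:
        logger.warning("friedman_conover: dropping traits with missing "
                       "entries: %s", dropped)
        perf = perf.drop(columns=dropped)
    if perf.shape[1] < 2:
        raise ValueError("fewer than 2 complete traits remain")

    k, n = perf.shape  # k models, n traits (blocks)
    ranks = perf.rank(axis=0, ascending=False, method="average")
    avg_ranks = ranks.mean(axis=1)
    R = ranks.sum(axis=1).to_numpy()
    A = float((ranks.to_numpy() ** 2).sum())
    B = float((R ** 2).sum()) / n

    degenerate = np.isclose(A, B)
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        try:
            stat, _ = stats.friedmanchisquare(*[perf.iloc[i].to_numpy()
                                                for i in range(k)])
        except (ValueError, ZeroDivisionError):
            stat = 0.0
        if not np.isfinite(stat):
            stat = 0.0
        # Iman-Davenport F refinement of the chi-square approximation
        denom = n * (k - 1) - stat
        if stat <= 0:
            p = 1.0
        elif denom <= 0:
            p = 0.0
        else:
            f_stat = (n - 1) * stat / denom
            p = float(stats.f.sf(f_stat, k - 1, (n - 1) * (k - 1)))

    models = list(perf.index)
    pair_p = np.ones((k, k))
    if not degenerate:
        df = (n - 1) * (k - 1)
        denom = np.sqrt(2.0 * n * (A - B) / df)
        raw, pairs = [], []
        for i in range(k):
            for j in range(i + 1, k):
                t = abs(R[i] - R[j]) / denom
                raw.append(2.0 * stats.t.sf(t, df))
                pairs.append((i, j))
        adj = _holm(np.asarray(raw))
        for (i, j), pv in zip(pairs, adj):
            pair_p[i, j] = pair_p[j, i] = pv

    # connected components over non-rejected pairs
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if pair_p[i, j] > alpha:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(k):
        comps.setdefault(find(i), []).append(models[i])
    groups = sorted(comps.values(), key=lambda g: min(models.index(m) for m in g))

    return FriedmanConoverReport(
        friedman_stat=float(stat), friedman_p=float(p), avg_ranks=avg_ranks,
        pairwise_p=pd.DataFrame(pair_p, index=models, columns=models),
        groups=groups, alpha=alpha, dropped_traits=dropped)


def critical_difference_table(report: FriedmanConoverReport) -> pd.DataFrame:
    """Tabular form of a critical-difference diagram: one row per model
    with its average rank and the id of its indistinguishability group."""
    group_of = {}
    for gid, group in enumerate(report.groups):
        for model in group:
            group_of[model] = gid
    out = pd.DataFrame({
        "model": list(report.avg_ranks.index),
        "avg_rank": report.avg_ranks.to_numpy(),
        "group_id": [group_of[m] for m in report.avg_ranks.index],
    })
    return out.sort_values("avg_rank", kind="mergesort").reset_index(drop=True)


# ------------------------------------------------- permutation importance

@dataclass
class ImportanceReport:
    feature_scores: dict      # feature -> mean decrease in test Spearman
    category_scores: dict     # SNPs summed; other categories singleton
    baseline_rho: float
    n_perm: int


def permutation_importance(model, test_features: pd.DataFrame, test_targets,
                           category_map: dict = None, n_perm: int = 50,
                           seed: int = 0) -> ImportanceReport:
    """Permutation feature importance on a fixed test set.

    For each feature, its test column is permuted (seeded), the model
    re-predicts, and the drop from the baseline Spearman is averaged over
    ``n_perm`` permutations. Constant columns score exactly 0 (permuting
    them is the identity). Category scores sum the members of the "SNPs"
    category; every other feature is its own category unless mapped.
    """
    X = pd.DataFrame(test_features)
    y = np.asarray(test_targets, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("single-row test set")
    if category_map is None:
        category_map = {}
    Xmat = X.to_numpy(dtype=float)
    base_pred = model.predict(Xmat)
    rho0, _ = (np.nan, np.nan) if np.all(base_pred == base_pred[0]) \
        else spearman_eval(base_pred, y)

    streams = np.random.SeedSequence(seed).spawn(X.shape[1])
    feature_scores = {}
    # all permuted copies of all features are stacked into one prediction
    # call: tree-ensemble predict cost is dominated by per-call overhead
    active = []
    blocks = []
    for j, col in enumerate(X.columns):
        vals = Xmat[:, j]
        if np.all(vals == vals[0]):
            feature_scores[col] = 0.0  # permuting a constant is the identity
            continue
        rng = np.random.default_rng(streams[j])
        Xrep = np.tile(Xmat, (n_perm, 1))
        for p in range(n_perm):
            Xrep[p * n:(p + 1) * n, j] = vals[rng.permutation(n)]
        active.append(col)
        blocks.append(Xrep)
    if active:
        preds = model.predict(np.concatenate(blocks, axis=0))
        preds = preds.reshape(len(active), n_perm, n)
        for col, block in zip(active, preds):
            rhos = _spearman_block(block, y)
            feature_scores[col] = float(rho0 - np.nanmean(rhos))

    category_scores = {}
    for col, score in feature_scores.items():
        cat = category_map.get(col, col)
        category_scores[cat] = category_scores.get(cat, 0.0) + score
    return ImportanceReport(feature_scores=feature_scores,
                            category_scores=category_scores,
                            baseline_rho=rho0, n_perm=n_perm)


# ------------------------------------------------------ leakage experiment

@dataclass
class LeakageReport:
    train_only: object            # BenchmarkReport
    full_cohort: object           # BenchmarkReport
    delta_rho: pd.Series          # per-fold paired FULL - TRAIN rho
    delta_snp_importance: pd.Series

    @property
    def mean_delta_rho(self) -> float:
        return float(self.delta_rho.mean())


def leakage_experiment(genotypes, covariates, trait: pd.Series,
                       fold_plan=None, model_kind: str = "rf",
                       feature_set: str = "combined", clump_params=None,
                       search: bool = False, n_configs: int = 25,
                       n_perm: int = 50, seed: int = 0) -> LeakageReport:
    """Paired comparison of the proper (TRAIN_ONLY) and data-leaking
    (FULL_COHORT) selection protocols with matched folds, seeds and model.
    """
    from .ctpredict import make_folds, run_benchmark

    if fold_plan is None:
        n = int(trait.notna().sum())
        fold_plan = make_folds(n, k=5, seed=seed)
    common = dict(model_kinds=(model_kind,), feature_sets=(feature_set,),
                  fold_plan=fold_plan, clump_params=clump_params,
                  n_configs=n_configs, search=search, compute_importance=True,
                  n_perm=n_perm, seed=seed)
    rep_train = run_benchmark(genotypes, covariates, trait,
                              leakage_mode="TRAIN_ONLY", **common)
    rep_full = run_benchmark(genotypes, covariates, trait,
                             leakage_mode="FULL_COHORT", **common)

    def _per_fold(rep, key):
        df = rep.performance()
        sel = df[(df["model"] == model_kind) & (df["feature_set"] == feature_set)]
        sel = sel.set_index("fold")
        if key == "rho":
            return sel["rho"]
        return sel["importance"].map(
            lambda d: d.get("SNPs", np.nan) if d is not None else np.nan)

    delta_rho = _per_fold(rep_full, "rho") - _per_fold(rep_train, "rho")
    delta_imp = (_per_fold(rep_full, "imp") - _per_fold(rep_train, "imp"))
    return LeakageReport(train_only=rep_train, full_cohort=rep_full,
                         delta_rho=delta_rho, delta_snp_importance=delta_imp)


# --------------------------------------------------- cross-cohort transfer

def cross_cohort_validate(train_genotypes, train_covariates, train_trait,
                          test_genotypes, test_covariates, test_trait,
                          model_kind: str = "rf", config: dict = None,
                          clump_params=None, covariate_cols=None,
                          n_perm: int = 50, compute_importance: bool = False,
                          seed: int = 0):
    """Train on the full first cohort, predict the second, evaluate Spearman.

    Genetic features are selected on the training cohort and restricted to
    the variant intersection of the two panels; scalers are fitted on the
    training cohort only. Returns (rho, p, prediction table[, importance]).
    """
    from .ctpredict import (DEFAULT_CONFIGS, build_estimator,
                            covariate_features, select_genetic_features,
                            _genetic_feature_frame)

    if covariate_cols is None:
        covariate_cols = CROSS_COHORT_COVARIATES
    y_tr = np.asarray(train_trait, dtype=float)
    y_te = np.asarray(test_trait, dtype=float)
    ok_tr = ~np.isnan(y_tr)
    ok_te = ~np.isnan(y_te)
    geno_tr = train_genotypes.select_individuals(ok_tr)
    cov_tr = train_covariates.loc[ok_tr]
    y_tr = y_tr[ok_tr]
    geno_te = test_genotypes.select_individuals(ok_te)
    cov_te = test_covariates.loc[ok_te]
    y_te = y_te[ok_te]

    sel_model, _ = select_genetic_features(geno_tr, y_tr, cov_tr, clump_params)
    shared = [v for v in sel_model.variants["id"]
              if v in set(test_genotypes.variants["id"])]
    if not shared and len(sel_model.variants):
        logger.warning("cross_cohort_validate: empty shared-variant set; "
                       "proceeding with covariates only")

    from .preprocess import apply_scaler, fit_scaler

    gen_tr = _genetic_feature_frame(geno_tr, shared)
    gen_te = _genetic_feature_frame(geno_te, shared)
    cfeat_tr = covariate_features(cov_tr)[covariate_cols]
    cfeat_te = covariate_features(cov_te)[covariate_cols]

    frames_tr, frames_te = [cfeat_tr], [cfeat_te]
    if shared:
        g_scaler = fit_scaler(gen_tr)
        frames_tr.insert(0, apply_scaler(gen_tr, g_scaler))
        frames_te.insert(0, apply_scaler(gen_te, g_scaler))
    c_scaler = fit_scaler(cfeat_tr)
    frames_tr[-1] = apply_scaler(cfeat_tr, c_scaler)
    frames_te[-1] = apply_scaler(cfeat_te, c_scaler)
    X_tr = pd.concat(frames_tr, axis=1)
    X_te = pd.concat(frames_te, axis=1)

    y_scaler = fit_scaler(pd.DataFrame({"y": y_tr}))
    y_tr_z = apply_scaler(pd.DataFrame({"y": y_tr}), y_scaler)["y"].to_numpy()

    if config is None:
        config = DEFAULT_CONFIGS[model_kind]
    est = build_estimator(model_kind, config, seed=seed)
    est.fit(X_tr.to_numpy(), y_tr_z)
    pred = est.predict(X_te.to_numpy())
    rho, p = spearman_eval(pred, y_te)
    table = pd.DataFrame({"observed_log2": y_te, "predicted_z": pred},
                         index=cov_te.index)
    if compute_importance:
        category_map = {c: "SNPs" for c in gen_te.columns}
        category_map.update({"s1": "seasonality", "s2": "seasonality"})
        yte_z = apply_scaler(pd.DataFrame({"y": y_te}), y_scaler)["y"].to_numpy()
        imp = permutation_importance(est, X_te, yte_z,
                                     category_map=category_map,
                                     n_perm=n_perm, seed=seed)
        return rho, p, table, imp
    return rho, p, table
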