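import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from cytopred.ctpredict import (ClumpParams, CtScoreModel, DEFAULT_CONFIGS,
                                HYPER_GRIDS, build_ct_model, clump, ct_score,
                                fit_predict, make_folds, random_search,
                                run_benchmark)
from oracles import clump_oracle


def _sumstats(ids, chroms, positions, pvals):
    return pd.DataFrame({"CHR": chroms, "POS": positions, "ID": ids,
                         "A1": "G", "BETA": 0.2, "SE": 0.02, "STAT": 10.0,
                         "P": pvals, "N": 100})


def _correlated(base, r2, rng):
    """A dosage column with approximately the requested r^2 to base."""
    flip = rng.random(len(base)) > np.sqrt(r2) * 0.5 + 0.5
    out = base.copy()
    out[flip] = rng.binomial(2, 0.4, size=flip.sum())
    return out


class TestClump:
    def test_hand_traced_example(self):
        # v1 (p=1e-9) seeds; v2 (50 kb, high LD) and v4 (60 kb, high LD,
        # p=1e-3) join its clump; v3 (500 kb away) seeds its own.
        rng = np.random.default_rng(0)
        n = 2000
        v1 = rng.binomial(2, 0.4, size=n).astype(float)
        v2, v4 = v1.copy(), v1.copy()
        noise = rng.random(n) < 0.05
        v2[noise] = rng.binomial(2, 0.4, size=noise.sum())
        noise4 = rng.random(n) < 0.03
        v4[noise4] = rng.binomial(2, 0.4, size=noise4.sum())
        v3 = rng.binomial(2, 0.4, size=n).astype(float)
        d = np.column_stack([v1, v2, v3, v4])
        pos = [1_000_000, 1_050_000, 1_500_000, 1_060_000]
        g = make_genotypes(d)
        g.variants["pos"] = pos
        ss = _sumstats(["v0", "v1", "v2", "v3"], ["1"] * 4, pos,
                       [1e-9, 1e-6, 1e-6, 1e-3])
        res = clump(ss, g, ClumpParams())
        assert res.index_ids == ["v0", "v2"]
        assert set(res.members["v0"]) == {"v1", "v3"}
        assert res.members["v2"] == []

    def test_no_index_candidates(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        g = make_genotypes(d)
        ss = _sumstats(["v0", "v1", "v2"], ["1"] * 3,
                       g.variants["pos"].tolist(), [1e-4, 0.2, 0.9])
        res = clump(ss, g, ClumpParams())
        assert res.index_ids == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        params = ClumpParams(p1=0.05, p2=0.3, r2_min=0.5, window_kb=100)
        for _ in range(50):
            m = int(rng.integers(5, 50))
            n = 150
            base = rng.binomial(2, 0.4, size=(n, m)).astype(float)
            # induce LD between random pairs
            for _ in range(m // 3):
                i, j = rng.integers(m, size=2)
                base[:, j] = _correlated(base[:, i], 0.8, rng)
            pos = np.sort(rng.choice(500_000, size=m, replace=False)) + 1
            ids = np.array([f"v{i}" for i in range(m)])
            chroms = np.array(["1"] * m)
            pvals = 10.0 ** rng.uniform(-6, 0, size=m)
            g = make_genotypes(base)
            g.variants["pos"] = pos
            ss = _sumstats(ids, chroms, pos, pvals)
            res = clump(ss, g, params)
            expected = clump_oracle(ids, chroms, pos, pvals, base,
                                    params.p1, params.p2, params.r2_min,
                                    params.window_kb * 1000)
            assert sorted(res.index_ids) == expected

    def test_missing_ld_genotypes_for_index_raises(self):
        rng = np.random.default_rng(3)
        g = make_genotypes(rng.binomial(2, 0.4, size=(50, 1)).astype(float),
                           ids=["other"])
        ss = _sumstats(["vX"], ["1"], [1_000_000], [1e-9])
        with pytest.raises(ValueError, match="vX"):
            clump(ss, g, ClumpParams())

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ClumpParams(p1=1e-2, p2=1e-5)
        with pytest.raises(ValueError):
            ClumpParams(r2_min=0.0)


class TestCtScore:
    def test_single_variant_arithmetic(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0]]), ids=["v0"])
        model = CtScoreModel(variants=pd.DataFrame(
            {"id": ["v0"], "effect_allele": ["G"], "beta": [0.5]}))
        assert np.allclose(ct_score(g, model), [0.0, 0.5, 1.0])

    def test_zero_betas_give_zero_scores(self):
        g = make_genotypes(np.array([[0.0, 1.0], [2.0, 1.0]]))
        model = CtScoreModel(variants=pd.DataFrame(
            {"id": ["v0", "v1"], "effect_allele": ["G", "G"],
             "beta": [0.0, 0.0]}))
        assert np.allclose(ct_score(g, model), 0.0)

    def test_ref_effect_allele_flips_dosage(self):
        g = make_genotypes(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        model = CtScoreModel(variants=pd.DataFrame(
            {"id": ["v0", "v1"], "effect_allele": ["A", "G"],
             "beta": [1.0, 0.5]}))
        # v0 effect allele is REF: dosage 2-d; v1 is ALT
        expected = 1.0 * (2 - g.dosages[:, 0]) + 0.5 * g.dosages[:, 1]
        assert np.allclose(ct_score(g, model), expected)

    def test_missing_dosage_contributes_mean(self):
        g = make_genotypes(np.array([[0.0], [2.0], [np.nan]]), ids=["v0"])
        model = CtScoreModel(variants=pd.DataFrame(
            {"id": ["v0"], "effect_allele": ["G"], "beta": [1.0]}))
        assert np.allclose(ct_score(g, model), [0.0, 2.0, 1.0])

    def test_linearity_in_beta(self):
        rng = np.random.default_rng(4)
        g = make_genotypes(rng.binomial(2, 0.4, size=(30, 3)).astype(float))
        betas = rng.normal(size=3)
        mk = lambda b: CtScoreModel(variants=pd.DataFrame(
            {"id": [f"v{i}" for i in range(3)], "effect_allele": ["G"] * 3,
             "beta": b}))
        assert np.allclose(ct_score(g, mk(3.0 * betas)),
                           3.0 * ct_score(g, mk(betas)), atol=1e-12)

    def test_zero_matchable_raises(self):
        g = make_genotypes(np.array([[1.0]]), ids=["v0"])
        model = CtScoreModel(variants=pd.DataFrame(
            {"id": ["absent"], "effect_allele": ["G"], "beta": [1.0]}))
        with pytest.raises(ValueError):
            ct_score(g, model)


class TestFolds:
    def test_even_partition(self):
        plan = make_folds(10, k=5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [2] * 5

    def test_uneven_sizes(self):
        plan = make_folds(403, k=5, seed=1)
        assert sorted(len(f) for f in plan.folds) == [80, 80, 81, 81, 81]

    def test_disjoint_cover(self):
        plan = make_folds(57, k=5, seed=2)
        allidx = np.concatenate(plan.folds)
        assert sorted(allidx) == list(range(57))

    def test_train_test_split_disjoint(self):
        plan = make_folds(30, k=5, seed=3)
        tr, te = plan.split(2)
        assert set(tr) & set(te) == set()
        assert len(tr) + len(te) == 30

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(3, k=5, seed=0)


class TestRandomSearchAndFit:
    def test_single_configuration_returned(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=60)
        cfg, _ = random_search("ridge", X, y, grid={"alpha": [1.0]}, seed=0)
        assert cfg == {"alpha": 1.0}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        y = X @ np.array([1.0, -1, 0, 0.5]) + rng.normal(size=80)
        a = random_search("en", X, y, seed=3)
        b = random_search("en", X, y, seed=3)
        assert a == b

    def test_planted_linear_rejects_heavy_penalty(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 5))
            y = X @ np.array([1.0, -1, 0.5, 0, 0]) + 0.3 * rng.normal(size=100)
            cfg, _ = random_search("en", X, y, seed=seed)
            wins += cfg["alpha"] < 1000
        assert wins >= 9

    def test_sampled_configs_stay_in_grid(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        cfg, _ = random_search("gbt", X, y, n_configs=10, seed=1)
        for key, val in cfg.items():
            assert val in HYPER_GRIDS["gbt"][key]

    def test_ols_interpolates_noiseless_linear(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        beta = rng.normal(size=4)
        y = X @ beta
        Xte = rng.normal(size=(20, 4))
        pred = fit_predict("ols", {}, X, y, Xte)
        assert np.allclose(pred, Xte @ beta, atol=1e-6)

    def test_constant_target_predicts_constant(self):
        X = np.random.default_rng(9).normal(size=(30, 2))
        pred = fit_predict("rf", DEFAULT_CONFIGS["rf"], X, np.ones(30),
                           X[:5], seed=0)
        assert np.allclose(pred, 1.0, atol=1e-9)

    def test_nonfinite_features_raise(self):
        X = np.ones((10, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_predict("ols", {}, X, np.ones(10), X)

    def test_zero_column_fallback_is_intercept(self):
        X = np.empty((10, 0))
        pred = fit_predict("ols", {}, X, np.arange(10.0), np.empty((4, 0)))
        assert np.allclose(pred, 4.5)


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def bench_inputs(self, tcr_cohort):
        trait = tcr_cohort.cytokines.iloc[:, 0]
        return tcr_cohort.genotypes, tcr_cohort.covariates, trait

    def test_reports_are_reproducible(self, bench_inputs):
        geno, cov, trait = bench_inputs
        kw = dict(model_kinds=("ct", "ols"), feature_sets=("genetic",),
                  leakage_mode="TRAIN_ONLY", search=False, seed=5,
                  clump_params=ClumpParams(p1=1e-2, p2=5e-2))
        a = run_benchmark(geno, cov, trait, **kw).performance()
        b = run_benchmark(geno, cov, trait, **kw).performance()
        pd.testing.assert_frame_equal(a, b)

    def test_train_only_never_touches_test_ids_before_eval(self, bench_inputs):
        geno, cov, trait = bench_inputs
        rep = run_benchmark(geno, cov, trait, model_kinds=("ct",),
                            feature_sets=("genetic",),
                            leakage_mode="TRAIN_ONLY", search=False, seed=1,
                            clump_params=ClumpParams(p1=1e-2, p2=5e-2))
        test_ids = {e["fold"]: e["ids"] for e in rep.audit
                    if e["stage"] == "test_eval"}
        for entry in rep.audit:
            if entry["stage"] in ("gwas_selection", "model_fit"):
                assert entry["ids"] & test_ids[entry["fold"]] == frozenset()

    def test_full_cohort_selection_sees_everyone(self, bench_inputs):
        geno, cov, trait = bench_inputs
        rep = run_benchmark(geno, cov, trait, model_kinds=("ct",),
                            feature_sets=("genetic",),
                            leakage_mode="FULL_COHORT", search=False, seed=1,
                            clump_params=ClumpParams(p1=1e-2, p2=5e-2))
        sel = [e for e in rep.audit if e["stage"] == "gwas_selection"]
        assert len(sel) == 1
        assert len(sel[0]["ids"]) == int(trait.notna().sum())

    def test_too_few_complete_cases_raise(self, bench_inputs):
        geno, cov, trait = bench_inputs
        sparse = trait.copy()
        sparse.iloc[10:] = np.nan
        with pytest.raises(ValueError, match="complete"):
            run_benchmark(geno, cov, sparse)

    def test_empty_selection_yields_missing_genetic_results(self, null_cohort):
        trait = null_cohort.cytokines.iloc[:, 0]
        # paper-scale p1 on a tiny null panel: nothing passes
        rep = run_benchmark(null_cohort.genotypes, null_cohort.covariates,
                            trait, model_kinds=("ct", "ols"),
                            feature_sets=("genetic",), search=False, seed=2,
                            clump_params=ClumpParams())
        perf = rep.performance()
        assert perf["n_variants"].eq(0).all()
        assert perf["rho"].isna().all()
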