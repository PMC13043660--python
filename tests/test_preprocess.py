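import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotypes
from cytopred.preprocess import (QcParams, apply_scaler, apply_variant_qc,
                                 compute_maf, encode_seasonality, fit_scaler,
                                 genotype_pca, hwe_exact_test,
                                 inverse_rank_normalize, residualize)
from oracles import hwe_enumeration_oracle


class TestSeasonality:
    def test_full_revolution(self):
        s1, s2 = encode_seasonality(365)
        assert abs(s1) < 1e-12 and abs(s2 - 1.0) < 1e-12

    def test_quarter_circle(self):
        s1, s2 = encode_seasonality(365.0 / 4.0)
        assert s1 == pytest.approx(1.0, abs=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-12)

    def test_midyear_antipodal_to_new_year(self):
        for doy in (182, 183):
            _, s2 = encode_seasonality(doy)
            assert abs(s2 + 1.0) < 0.01

    def test_leap_day_folds_onto_365(self):
        assert encode_seasonality(366) == encode_seasonality(365)

    @given(st.integers(min_value=1, max_value=366))
    @settings(max_examples=50, deadline=None)
    def test_unit_circle(self, doy):
        s1, s2 = encode_seasonality(doy)
        assert abs(s1 ** 2 + s2 ** 2 - 1.0) < 1e-12

    @pytest.mark.parametrize("doy", [0, 367, -5])
    def test_out_of_range(self, doy):
        with pytest.raises(ValueError):
            encode_seasonality(doy)


class TestMaf:
    def test_hand_example(self):
        assert compute_maf([0, 1, 2, 2]) == pytest.approx(0.375)

    def test_monomorphic(self):
        assert compute_maf([0, 0, 0]) == 0.0

    def test_missing_ignored(self):
        assert compute_maf([0, 1, np.nan, 2, 2]) == pytest.approx(0.375)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            compute_maf([np.nan, np.nan])

    def test_binomial_consistency(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=10_000).astype(float)
        se = np.sqrt(0.3 * 0.7 / (2 * 10_000))
        assert abs(compute_maf(d) - 0.3) < 3 * se


class TestHweExact:
    def test_two_hets_of_two(self):
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(1, 201))
            counts = rng.multinomial(n, [0.4, 0.35, 0.25])
            p_impl = hwe_exact_test(*counts)
            p_oracle = hwe_enumeration_oracle(*counts)
            assert abs(p_impl - p_oracle) < 1e-12


class TestVariantQc:
    def _panel(self):
        rng = np.random.default_rng(5)
        n = 100
        cols, expect_fail = [], []
        good = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        for j in range(4):
            cols.append(good[:, j])
            expect_fail.append(set())
        bad_call = rng.binomial(2, 0.3, size=n).astype(float)
        bad_call[:6] = np.nan  # 6% missing -> call rate 0.94
        cols.append(bad_call)
        expect_fail.append({"call"})
        rare = np.zeros(n)
        rare[:4] = 1.0  # MAF 0.02
        cols.append(rare)
        expect_fail.append({"maf"})
        boundary = np.zeros(n)
        boundary[:10] = 1.0  # MAF exactly 0.05: retained (strict <)
        cols.append(boundary)
        expect_fail.append(set())
        het_excess = np.ones(n)  # all heterozygous: extreme HWE failure
        cols.append(het_excess)
        expect_fail.append({"hwe"})
        return np.column_stack(cols), expect_fail

    def test_report_matches_hand_tally(self):
        dosages, expect = self._panel()
        g = make_genotypes(dosages)
        filtered, report = apply_variant_qc(g, QcParams())
        assert report.n_input == len(expect)
        assert report.n_fail_call_rate == sum("call" in e for e in expect)
        assert report.n_fail_maf == sum("maf" in e for e in expect)
        assert report.n_fail_hwe == sum("hwe" in e for e in expect)
        assert report.n_retained == sum(not e for e in expect)
        kept_ids = set(filtered.variants["id"])
        for j, e in enumerate(expect):
            assert (f"v{j}" in kept_ids) == (not e)

    def test_filters_commute(self):
        dosages, _ = self._panel()
        g = make_genotypes(dosages)
        combined, _ = apply_variant_qc(g, QcParams())
        # apply each rule in isolation and intersect the survivors
        loose = 1 - 1e-9
        only_call, _ = apply_variant_qc(g, QcParams(maf_min=1e-9,
                                                    hwe_p_min=1e-12))
        only_maf, _ = apply_variant_qc(g, QcParams(max_missing=loose,
                                                   hwe_p_min=1e-12))
        only_hwe, _ = apply_variant_qc(g, QcParams(max_missing=loose,
                                                   maf_min=1e-9))
        survivors = (set(only_call.variants["id"]) & set(only_maf.variants["id"])
                     & set(only_hwe.variants["id"]))
        assert survivors == set(combined.variants["id"])

    def test_maf_boundary_is_strict(self):
        d = np.zeros((100, 1))
        d[:10, 0] = 1.0  # MAF exactly 0.05
        g = make_genotypes(d)
        filtered, _ = apply_variant_qc(g, QcParams())
        assert filtered.n_variants == 1


class TestGenotypePca:
    def test_identical_individuals_get_identical_scores(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(30, 50)).astype(float)
        d[5] = d[3]
        scores = genotype_pca(make_genotypes(d), k=3)
        assert np.allclose(scores[5], scores[3], atol=1e-9)

    def test_components_orthogonal_and_variance_ordered(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(80, 60)).astype(float)
        scores = genotype_pca(make_genotypes(d), k=3)
        assert abs(np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]) < 1e-10
        variances = scores.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_k_above_rank_raises(self):
        d = np.tile([[0.0, 1.0], [1.0, 2.0]], (3, 1))
        with pytest.raises(ValueError):
            genotype_pca(make_genotypes(d), k=5)


class TestInverseRankNormalize:
    def test_middle_rank_maps_to_zero(self):
        out = inverse_rank_normalize([3.0, 1.0, 2.0])
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_blom_formula_on_sorted_input(self):
        from scipy.special import ndtri
        n = 17
        x = np.arange(n, dtype=float)
        out = inverse_rank_normalize(x)
        expected = ndtri((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        assert np.allclose(out, expected, atol=1e-12)

    def test_ties_get_equal_outputs(self):
        out = inverse_rank_normalize([1.0, 2.0, 2.0, 5.0])
        assert out[1] == out[2]

    def test_missing_passthrough_and_rank_preserving(self):
        out = inverse_rank_normalize([5.0, np.nan, 1.0, 3.0])
        assert np.isnan(out[1])
        assert out[2] < out[3] < out[0]

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            inverse_rank_normalize([2.0, 2.0, 2.0])


class TestResidualize:
    def test_trait_equal_to_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        resid = residualize(x, x[:, None])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_trait_unchanged(self):
        n = 40
        x = np.ones(n)
        x[: n // 2] = -1.0
        y = np.tile([1.0, -1.0], n // 2)  # orthogonal to x, mean 0
        resid = residualize(y, x[:, None])
        assert np.allclose(resid, y, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        X = rng.normal(size=(200, 8))
        resid = residualize(y, X)
        design = np.column_stack([np.ones(200), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(resid, y - design @ beta, atol=1e-10)
        # orthogonality to every covariate column
        assert np.all(np.abs(design.T @ resid) < 1e-8 * 200)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=100)
        X = rng.normal(size=(100, 4))
        once = residualize(y, X)
        twice = residualize(once, X)
        assert np.allclose(once, twice, atol=1e-10)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
        with pytest.raises(ValueError, match="[ab]"):
            residualize(rng.normal(size=50), X)


class TestScaler:
    def test_train_set_standardized(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(5, 3, size=(100, 3)), columns=list("abc"))
        params = fit_scaler(df)
        z = apply_scaler(df, params)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_test_value_at_train_mean_maps_to_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        params = fit_scaler(df)
        z = apply_scaler(pd.DataFrame({"a": [2.0]}), params)
        assert z.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_shifted_test_set(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        params = fit_scaler(df)
        z = apply_scaler(df + 5.0, params)
        assert z["a"].mean() == pytest.approx(5.0 / params.sds[0], abs=1e-6)

    def test_zero_variance_dropped(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        params = fit_scaler(df)
        assert params.dropped == ["a"]
        assert apply_scaler(df, params).columns.tolist() == ["b"]
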