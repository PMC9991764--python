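"""Tests of the method-comparison battery against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from dietna.agreement import (
    PairedSeries,
    bias_stats,
    bland_altman,
    classify_icc,
    compare_all,
    comparison_table,
    compare_method,
    correlations,
    icc,
    ks_normality,
    loa_from_bias,
    paired_series,
)

import oracles


def random_series(rng, n=30, scale=1000.0):
    ref = rng.normal(2800.0, scale, n)
    est = ref * rng.uniform(0.5, 1.2) + rng.normal(0.0, scale / 2, n)
    return PairedSeries(ref, est, np.array([f"p{i}" for i in range(n)]))


class TestBiasStats:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = PairedSeries(x, x.copy(), np.arange(4))
        bias_mean, bias_sd, p, test = bias_stats(s)
        assert bias_mean == 0.0 and bias_sd == 0.0 and p == 1.0

    def test_alternating_difference_sd(self):
        ref = np.array([100.0, -100.0, 100.0, -100.0]) + 2000.0
        s = PairedSeries(ref, np.full(4, 2000.0), np.arange(4))
        bias_mean, bias_sd, _, _ = bias_stats(s)
        assert bias_mean == pytest.approx(0.0)
        assert bias_sd == pytest.approx(115.47, abs=0.005)

    def test_t_test_matches_oracle(self):
        """Paired-t p agrees with the textbook formula on random fixtures."""
        rng = np.random.default_rng(101)
        for _ in range(20):
            s = random_series(rng)
            _, _, p, test = bias_stats(s)
            if test != "t":
                continue
            _, p_oracle = oracles.paired_t_oracle(s.reference, s.estimate)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_skewed_differences_route_wilcoxon(self):
        rng = np.random.default_rng(3)
        ref = np.full(200, 3000.0) + rng.exponential(800.0, 200)
        est = np.full(200, 3000.0)
        *_, test = bias_stats(PairedSeries(ref, est, np.arange(200)))
        assert test == "wilcoxon"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            PairedSeries([1.0, 2.0], [1.0, 2.0], ["a", "b"])


class TestCorrelations:
    def test_perfect_monotone(self):
        ref = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        s = PairedSeries(ref, 2 * ref, np.arange(5))
        r, _, rho, _ = correlations(s)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_reversed_order(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = PairedSeries(ref, ref[::-1].copy(), np.arange(5))
        _, _, rho, _ = correlations(s)
        assert rho == pytest.approx(-1.0)

    def test_oracle_agreement(self):
        """Pearson and tie-aware Spearman match brute-force oracles."""
        rng = np.random.default_rng(202)
        for i in range(50):
            s = random_series(rng, n=25)
            if i % 3 == 0:  # inject ties to exercise average ranks
                est = np.round(s.estimate, -2)
                s = PairedSeries(s.reference, est, s.participant_ids)
            r, rp, rho, rhop = correlations(s)
            r_o, rp_o = oracles.pearson_oracle(s.reference, s.estimate)
            rho_o, rhop_o = oracles.spearman_oracle(s.reference, s.estimate)
            assert r == pytest.approx(r_o, abs=1e-10)
            assert rp == pytest.approx(rp_o, abs=1e-10)
            assert rho == pytest.approx(rho_o, abs=1e-10)
            assert rhop == pytest.approx(rhop_o, abs=1e-10)

    def test_zero_variance_flagged(self):
        s = PairedSeries(np.full(5, 3.0), np.arange(5.0), np.arange(5))
        with pytest.warns(UserWarning, match="zero variance"):
            r, *_ = correlations(s)
        assert np.isnan(r)


class TestIcc:
    def test_identical_series_unity(self):
        x = np.linspace(1000.0, 4000.0, 10)
        s = PairedSeries(x, x.copy(), np.arange(10))
        value, *_ = icc(s)
        assert value == pytest.approx(1.0)

    def test_constant_offset_separates_forms(self):
        x = np.linspace(1000.0, 4000.0, 12)
        s = PairedSeries(x, x + 1500.0, np.arange(12))
        cons, *_ = icc(s, form="consistency")
        absol, *_ = icc(s, form="absolute_agreement")
        assert cons == pytest.approx(1.0)
        assert absol < cons

    def test_anova_oracle_agreement(self):
        """ICC recomputed from an independently coded ANOVA table."""
        rng = np.random.default_rng(303)
        for _ in range(20):
            s = random_series(rng, n=40)
            for form in ("absolute_agreement", "consistency"):
                value, lo, hi = icc(s, form=form)
                assert value == pytest.approx(
                    oracles.icc_oracle(s.reference, s.estimate, form), abs=1e-10
                )
                assert lo <= value <= hi

    def test_consistency_not_below_absolute(self):
        """Whenever a systematic between-method difference exists (the
        method mean square at least the residual one), absolute agreement
        is penalised for it and cannot exceed consistency."""
        from dietna.agreement import _icc_mean_squares

        rng = np.random.default_rng(404)
        for _ in range(20):
            s = random_series(rng, n=25)
            _, msc, mse, *_ = _icc_mean_squares(s)
            if msc >= mse:
                assert icc(s, "consistency")[0] >= icc(s, "absolute_agreement")[0] - 1e-12

    def test_pingouin_cross_check(self):
        """Independent library agrees on ICC(2,1)/ICC(3,1) and the CI."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(505)
        s = random_series(rng, n=35)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(s.n), 2),
                "rater": np.tile(["ref", "est"], s.n),
                "score": np.column_stack([s.reference, s.estimate]).ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        table = table.set_index("Type")
        value, lo, hi = icc(s, "absolute_agreement")
        assert value == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-10)
        # pingouin prints its CI rounded to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(table.loc["ICC(A,1)", "CI95"]), abs=6e-3)
        value_c, *_ = icc(s, "consistency")
        assert value_c == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-10)

    def test_degenerate_all_identical(self):
        s = PairedSeries(np.full(6, 5.0), np.full(6, 5.0), np.arange(6))
        value, lo, hi = icc(s)
        assert value == 1.0 and np.isnan(lo) and np.isnan(hi)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.66, "moderate"),
            (0.49, "poor"),
            (0.95, "excellent"),
            (0.5, "moderate"),
            (0.75, "good"),
            (0.9, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, label):
        assert classify_icc(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestBlandAltman:
    def test_published_loa_arithmetic(self):
        lo, hi = loa_from_bias(-290.2, 1336.2)
        assert round(lo, 1) == -2909.2
        assert round(hi, 1) == 2328.8

    def test_constant_difference(self):
        ref = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        s = PairedSeries(ref, ref - 500.0, np.arange(4))
        _, lo, hi, slope, _ = bland_altman(s)
        assert lo == pytest.approx(hi) == pytest.approx(500.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_normal_equations(self):
        rng = np.random.default_rng(606)
        for _ in range(20):
            s = random_series(rng, n=30)
            _, _, _, slope, p = bland_altman(s)
            m = (s.reference + s.estimate) / 2
            d = s.differences
            slope_o, p_o = oracles.ols_slope_oracle(m, d)
            assert slope == pytest.approx(slope_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)

    def test_loa_identity_on_stored_fields(self):
        rng = np.random.default_rng(707)
        comp = compare_method(random_series(rng), "m")
        assert comp.loa_lower == pytest.approx(comp.bias_mean - 1.96 * comp.bias_sd, rel=1e-12)
        assert comp.loa_upper == pytest.approx(comp.bias_mean + 1.96 * comp.bias_sd, rel=1e-12)


class TestKsNormality:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(808)
        assert ks_normality(rng.normal(0.0, 1.0, 5000)) > 0.05

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(809)
        assert ks_normality(rng.exponential(1.0, 5000)) < 0.05

    def test_constant_routes_nonparametric(self):
        assert ks_normality(np.full(10, 2.0)) == 0.0

    def test_tiny_sample_warns(self):
        with pytest.warns(UserWarning):
            assert ks_normality([1.0, 2.0, 3.0]) == 0.0


def _toy_estimates(rng, n=40, methods=("m1", "m2")):
    pids = [f"p{i}" for i in range(n)]
    ref = rng.normal(2800.0, 900.0, n)
    frames = [pd.DataFrame({"participant_id": pids, "method_id": "u24", "na_mg_per_day": ref})]
    for j, m in enumerate(methods):
        est = ref * 0.8 + rng.normal(0.0, 400.0, n)
        keep = slice(0, n - 10 * j)  # differing availability per method
        frames.append(
            pd.DataFrame(
                {"participant_id": pids, "method_id": m, "na_mg_per_day": est}
            ).iloc[keep]
        )
    return pd.concat(frames, ignore_index=True)


class TestCompareAll:
    def test_per_method_sample_sizes(self):
        rng = np.random.default_rng(909)
        estimates = _toy_estimates(rng)
        results = {c.method_id: c for c in compare_all(estimates)}
        assert results["m1"].n == 40 and results["m2"].n == 30

    def test_missing_reference_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["a", "b", "c"], "method_id": "m1", "na_mg_per_day": 1.0}
        )
        with pytest.raises(ValueError, match="u24"):
            compare_all(df)

    def test_sensitivity_noop_when_all_complete(self):
        rng = np.random.default_rng(910)
        estimates = _toy_estimates(rng)
        flags = pd.Series(True, index=estimates["participant_id"].unique())
        plain = comparison_table(compare_all(estimates, flags, sensitivity=False))
        sens = comparison_table(compare_all(estimates, flags, sensitivity=True))
        pd.testing.assert_frame_equal(plain, sens)

    def test_sensitivity_drops_incomplete(self):
        rng = np.random.default_rng(911)
        estimates = _toy_estimates(rng)
        flags = pd.Series(True, index=estimates["participant_id"].unique())
        flags.iloc[:5] = False
        results = {c.method_id: c for c in compare_all(estimates, flags, sensitivity=True)}
        assert results["m1"].n == 35

    def test_row_order_and_relabel_invariance(self):
        rng = np.random.default_rng(912)
        estimates = _toy_estimates(rng)
        shuffled = estimates.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            participant_id=shuffled["participant_id"].map(lambda s: f"XX-{s}")
        )
        base = comparison_table(compare_all(estimates)).drop(columns=["method_id"])
        other = comparison_table(compare_all(relabeled)).drop(columns=["method_id"])
        pd.testing.assert_frame_equal(
            base.sort_index(axis=1), other.sort_index(axis=1), check_exact=False, rtol=1e-12
        )

    def test_full_table_brute_force(self):
        """Every cell of one comparison row is recomputed independently."""
        rng = np.random.default_rng(913)
        estimates = _toy_estimates(rng, n=50, methods=("m1",))
        comp = compare_all(estimates)[0]
        s = paired_series(estimates, "m1")
        d = [r - e for r, e in zip(s.reference, s.estimate)]
        assert comp.n == len(d)
        assert comp.bias_mean == pytest.approx(oracles.mean(d), abs=1e-10)
        assert comp.bias_sd == pytest.approx(oracles.sample_sd(d), abs=1e-10)
        assert comp.mean_estimate == pytest.approx(oracles.mean(s.estimate), abs=1e-10)
        assert comp.sd_estimate == pytest.approx(oracles.sample_sd(s.estimate), abs=1e-10)
        r_o, rp_o = oracles.pearson_oracle(s.reference, s.estimate)
        rho_o, _ = oracles.spearman_oracle(s.reference, s.estimate)
        assert comp.pearson_r == pytest.approx(r_o, abs=1e-10)
        assert comp.pearson_p == pytest.approx(rp_o, abs=1e-10)
        assert comp.spearman_rho == pytest.approx(rho_o, abs=1e-10)
        assert comp.icc == pytest.approx(
            oracles.icc_oracle(s.reference, s.estimate, "absolute_agreement"), abs=1e-10
        )
        assert comp.loa_lower == pytest.approx(
            oracles.mean(d) - 1.96 * oracles.sample_sd(d), abs=1e-10
        )
        assert comp.loa_upper == pytest.approx(
            oracles.mean(d) + 1.96 * oracles.sample_sd(d), abs=1e-10
        )
        m = [(r + e) / 2 for r, e in zip(s.reference, s.estimate)]
        slope_o, p_o = oracles.ols_slope_oracle(m, d)
        assert comp.prop_bias_slope == pytest.approx(slope_o, abs=1e-10)
        assert comp.prop_bias_p == pytest.approx(p_o, abs=1e-10)
        if comp.paired_test == "t":
            _, p_t = oracles.paired_t_oracle(s.reference, s.estimate)
            assert comp.p_paired == pytest.approx(p_t, abs=1e-10)

    def test_overestimating_method_has_negative_bias(self):
        """Sign convention: bias = reference - estimate."""
        rng = np.random.default_rng(914)
        pids = [f"p{i}" for i in range(30)]
        ref = rng.normal(2800.0, 700.0, 30)
        est = ref * 1.4 + rng.normal(0, 100.0, 30)
        df = pd.concat(
            [
                pd.DataFrame({"participant_id": pids, "method_id": "u24", "na_mg_per_day": ref}),
                pd.DataFrame({"participant_id": pids, "method_id": "hi", "na_mg_per_day": est}),
            ],
            ignore_index=True,
        )
        assert compare_all(df)[0].bias_mean < 0
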