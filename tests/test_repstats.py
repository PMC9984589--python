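"""Normality gating, repeated-measures omnibus tests, post hoc and ICC."""

import numpy as np
import pytest

from segrepeat import (
    MetricMatrix,
    analyze_metric,
    friedman,
    icc,
    normality_gate,
    posthoc,
    rm_anova,
)


def _matrix(values, labels=None):
    return MetricMatrix(np.asarray(values, dtype=float), metric_name="m",
                        level_labels=labels or [])


class TestNormalityGate:
    def test_normal_columns_usually_pass(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.normal(0, 1, (50, 3)))
            hits += normality_gate(m) == "parametric"
        assert hits >= 90

    def test_heavy_tailed_columns_usually_fail(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            m = _matrix(rng.standard_t(1, (50, 3)))
            hits += normality_gate(m) == "nonparametric"
        assert hits >= 90

    def test_constant_column_forces_nonparametric(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (20, 3))
        x[:, 1] = 7.0
        assert normality_gate(_matrix(x)) == "nonparametric"


def _anova_oracle(x):
    """Brute-force within-subject ANOVA by explicit loops."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    ss_level = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_subj = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_level - ss_subj
    f = (ss_level / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return f


class TestRmAnova:
    def test_pure_subject_offsets_give_zero_f(self):
        offsets = np.array([1.0, 5.0, -2.0, 9.0])
        x = np.tile(offsets[:, None], (1, 3))
        f, p = rm_anova(_matrix(x))
        assert f == 0.0 and p == 1.0

    def test_hand_table_matches_loop_oracle(self):
        x = np.array([[3.0, 5.0, 9.0], [2.0, 4.0, 8.0], [4.0, 7.0, 9.0], [3.0, 6.0, 10.0]])
        f, p = rm_anova(_matrix(x))
        assert f == pytest.approx(_anova_oracle(x), abs=1e-9)
        assert 0 < p < 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (12, 4)) + np.array([0, 0.3, 0.6, 0.9])
        f, p = rm_anova(_matrix(x))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "level": np.tile(np.arange(4), 12),
            "y": x.ravel(),
        })
        res = pingouin.rm_anova(data=long, dv="y", within="level", subject="subject")
        assert f == pytest.approx(float(res["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(res["p_unc"].iloc[0]), rel=1e-6)

    def test_strong_level_effect_detected(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, (20, 5)) + 3.0 * np.arange(5)
        _, p = rm_anova(_matrix(x))
        assert p < 0.001

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (10, 4))
        f1, p1 = rm_anova(_matrix(x))
        perm = rng.permutation(10)
        f2, p2 = rm_anova(_matrix(x[perm]))
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestFriedman:
    def test_perfect_ranking_hand_value(self):
        # 3 subjects all ranking the 3 levels identically -> chi2_F = 6
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.2, 0.3]])
        stat, p = friedman(_matrix(x))
        assert stat == pytest.approx(6.0)

    def test_all_tied_is_degenerate_zero(self):
        x = np.full((5, 4), 2.5)
        stat, p = friedman(_matrix(x))
        assert stat == 0.0 and p == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (15, 5))
        s1, _ = friedman(_matrix(x))
        s2, _ = friedman(_matrix(x[rng.permutation(15)]))
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestPosthoc:
    def test_bonferroni_arithmetic_and_symmetry(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (25, 4)) + np.array([0, 0.1, 0.9, 1.5])
        m = _matrix(x)
        out = posthoc(m, "parametric")
        n_pairs = 6
        for i in range(4):
            assert np.isnan(out[i, i])
            for j in range(i + 1, 4):
                raw = stats.ttest_rel(x[:, i], x[:, j]).pvalue
                assert out[i, j] == pytest.approx(min(1.0, n_pairs * raw))
                assert out[i, j] == out[j, i]

    def test_family_size_override(self):
        # raw p scaled by the full 45-pair family even on a smaller matrix
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (30, 2)) + np.array([0.0, 1.0])
        from scipy import stats

        raw = stats.ttest_rel(x[:, 0], x[:, 1]).pvalue
        out = posthoc(_matrix(x), "parametric", n_comparisons=45)
        assert out[0, 1] == pytest.approx(min(1.0, 45 * raw))

    def test_identical_columns_give_p_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        out = posthoc(_matrix(x), "nonparametric")
        assert out[0, 1] == 1.0

    def test_adjusted_p_monotone_and_capped(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (40, 5))
        out = posthoc(_matrix(x), "parametric")
        vals = out[np.triu_indices(5, 1)]
        assert np.all((vals >= 0) & (vals <= 1))


def _icc_oracle(x, form):
    """Explicit ANOVA-table mean squares by loops (Shrout–Fleiss)."""
    n, k = x.shape
    grand = x.mean()
    bms = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    wms = sum((x[i, j] - x[i].mean()) ** 2 for i in range(n) for j in range(k)) / (n * (k - 1))
    jms = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ems = (sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
           - (n - 1) * bms - (k - 1) * jms) / ((n - 1) * (k - 1))
    if form == "ICC11":
        return (bms - wms) / (bms + (k - 1) * wms)
    return (bms - ems) / (bms + (k - 1) * ems)


class TestICC:
    def test_identical_raters_icc31_is_one(self):
        rng = np.random.default_rng(13)
        col = rng.normal(50, 10, 8)
        x = np.tile(col[:, None], (1, 3))
        rep = icc(x, "ICC31")
        assert rep.estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("form", ["ICC11", "ICC31"])
    def test_hand_matrix_matches_loop_oracle(self, form):
        x = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0],
                      [7.0, 1.0, 2.0], [10.0, 5.0, 6.0], [6.0, 2.0, 4.0]])
        rep = icc(x, form)
        assert rep.estimate == pytest.approx(_icc_oracle(x, form), abs=1e-12)
        assert rep.ci_lower <= rep.estimate <= rep.ci_upper

    @pytest.mark.parametrize("form,ptype", [("ICC11", "ICC(1,1)"), ("ICC31", "ICC(C,1)")])
    def test_matches_pingouin(self, form, ptype):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(14)
        x = rng.normal(0, 3, (10, 1)) + rng.normal(0, 1, (10, 3))
        rep = icc(x, form)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 3),
            "raters": np.tile(np.arange(3), 10),
            "ratings": x.ravel(),
        })
        res = pingouin.intraclass_corr(data=long, targets="targets", raters="raters",
                                       ratings="ratings")
        expected = float(res.loc[res.Type == ptype, "ICC"].iloc[0])
        assert rep.estimate == pytest.approx(expected, abs=1e-9)

    def test_negative_estimate_not_clamped(self):
        rng = np.random.default_rng(15)
        # no between-subject structure, pure noise -> estimate near/below 0
        found_negative = False
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, (8, 2))
            if icc(x, "ICC11").estimate < 0:
                found_negative = True
                break
        assert found_negative

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((3, 2)), "ICC11")
        with pytest.raises(ValueError):
            icc(np.ones((6, 1)), "ICC11")
        bad = np.ones((6, 3)); bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc(bad, "ICC11")


class TestAnalyzeChain:
    def test_parametric_chain_on_normal_data(self):
        rng = np.random.default_rng(30)
        x = rng.normal(10, 1, (30, 4)) + np.array([0, 0.5, 1.0, 1.5])
        report = analyze_metric(_matrix(x, labels=[10, 20, 30, 40]))
        assert report.omnibus_test in ("rm_anova", "friedman")
        assert report.omnibus_p < 0.01
        assert report.posthoc_p.shape == (4, 4)

    def test_incomplete_rows_dropped_listwise(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, (12, 3))
        x[2, 1] = np.nan
        m = _matrix(x).drop_incomplete_rows()
        assert m.n_subjects == 11
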