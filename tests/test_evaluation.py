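"""Metrics, kappa agreement, threshold schemes, correlations, KS diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from t1qc.core_io import LabelSet, QCFeatureTable, ToolRating
from t1qc.evaluation import (
    THRESHOLD_SCHEMES,
    ConfusionMetrics,
    ThresholdScheme,
    apply_cat12_threshold,
    apply_mriqc_threshold,
    cohens_kappa,
    confusion_metrics,
    correlate_measures,
    ks_site_comparison,
    percent_accept,
    performance_breakdown,
)


def _label_pair(true_seq, pred_seq):
    ids = [f"s{i}" for i in range(len(true_seq))]
    return (
        LabelSet(pd.Series(list(true_seq), index=ids)),
        LabelSet(pd.Series(list(pred_seq), index=ids), provenance="predicted"),
    )


def _from_counts(tp, fn, tn, fp):
    true = ["accept"] * (tp + fn) + ["reject"] * (tn + fp)
    pred = (
        ["accept"] * tp + ["reject"] * fn + ["reject"] * tn + ["accept"] * fp
    )
    return _label_pair(true, pred)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp",
        [(8, 2, 3, 1), (5, 0, 5, 0), (1, 4, 2, 3), (10, 1, 0, 2)],
    )
    def test_rates_match_direct_arithmetic(self, tp, fn, tn, fp):
        y, p = _from_counts(tp, fn, tn, fp)
        cm = confusion_metrics(y, p)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (tp, fn, tn, fp)
        assert cm.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp > 0:
            assert cm.specificity == pytest.approx(tn / (tn + fp))
            assert cm.balanced_accuracy == pytest.approx(
                (tp / (tp + fn) + tn / (tn + fp)) / 2
            )
            assert cm.fpr == pytest.approx(fp / (fp + tn))

    def test_hand_fixture(self):
        y, p = _from_counts(8, 2, 3, 1)
        cm = confusion_metrics(y, p)
        assert cm.sensitivity == pytest.approx(0.8)
        assert cm.specificity == pytest.approx(0.75)
        assert cm.balanced_accuracy == pytest.approx(0.775)
        assert cm.fpr == pytest.approx(0.25)

    def test_perfect_prediction(self):
        y, p = _from_counts(5, 0, 3, 0)
        cm = confusion_metrics(y, p)
        assert cm.sensitivity == cm.specificity == cm.balanced_accuracy == 1.0
        assert cm.fpr == 0.0

    def test_all_accept_truth_is_undefined_not_zero(self):
        y, p = _label_pair(["accept"] * 4, ["accept", "accept", "reject", "accept"])
        cm = confusion_metrics(y, p)
        assert np.isnan(cm.specificity)
        assert np.isnan(cm.balanced_accuracy)

    def test_row_order_invariance(self):
        y, p = _from_counts(6, 2, 4, 1)
        perm = np.random.default_rng(0).permutation(len(y))
        y2 = LabelSet(y.labels.iloc[perm])
        p2 = LabelSet(p.labels.iloc[perm], provenance="predicted")
        assert confusion_metrics(y2, p2) == confusion_metrics(y, p)

    def test_id_mismatch_error(self):
        a = LabelSet(pd.Series(["accept"], index=["x"]))
        b = LabelSet(pd.Series(["accept"], index=["y"]), provenance="predicted")
        with pytest.raises(ValueError, match="different scan ids"):
            confusion_metrics(a, b)


class TestPerformanceBreakdown:
    def test_identity_grouping_equals_global(self):
        y, p = _from_counts(6, 1, 2, 1)
        groups = pd.Series("all", index=y.scan_ids)
        out = performance_breakdown(y, p, groups)
        assert out.loc["all", "balanced_accuracy"] == pytest.approx(
            confusion_metrics(y, p).balanced_accuracy
        )

    def test_group_counts_are_additive(self):
        y, p = _from_counts(6, 2, 3, 1)
        groups = pd.Series(
            ["g1"] * 6 + ["g2"] * 6, index=y.scan_ids
        )
        out = performance_breakdown(y, p, groups)
        total = confusion_metrics(y, p)
        for c in ("tp", "tn", "fp", "fn"):
            assert out[c].sum() == getattr(total, c)

    def test_group_without_rejects_undefined(self):
        y, p = _label_pair(
            ["accept"] * 3 + ["reject"] * 2,
            ["accept"] * 3 + ["reject"] * 2,
        )
        groups = pd.Series(["a", "a", "a", "b", "b"], index=y.scan_ids)
        out = performance_breakdown(y, p, groups)
        assert np.isnan(out.loc["a", "balanced_accuracy"])


class TestCohensKappa:
    def test_identical_raters(self):
        a, b = _label_pair(["accept", "reject"] * 5, ["accept", "reject"] * 5)
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(1.0)
        assert res.percent_agreement == pytest.approx(100.0)

    def test_hand_computed_2x2(self):
        """Table [[20,5],[10,65]]: po=0.85, pe=0.60, kappa=0.625."""
        r1 = ["accept"] * 25 + ["reject"] * 75
        r2 = ["accept"] * 20 + ["reject"] * 5 + ["accept"] * 10 + ["reject"] * 65
        a, b = _label_pair(r1, r2)
        res = cohens_kappa(a, b)
        assert res.po == pytest.approx(0.85)
        assert res.pe == pytest.approx(0.60)
        assert res.kappa == pytest.approx(0.625)
        assert 0 < res.p_value < 1e-6  # strong agreement on n=100

    def test_constant_rater_gives_chance_kappa(self):
        a, b = _label_pair(
            ["accept"] * 3 + ["reject"] * 7, ["accept"] * 10
        )
        assert cohens_kappa(a, b).kappa == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        r1 = rng.choice(["accept", "reject"], 60)
        r2 = rng.choice(["accept", "reject"], 60)
        a, b = _label_pair(r1, r2)
        ab, ba = cohens_kappa(a, b), cohens_kappa(b, a)
        assert ab.kappa == pytest.approx(ba.kappa)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_exact_permutation_p(self):
        a, b = _label_pair(
            ["accept"] * 6 + ["reject"] * 4,
            ["accept"] * 5 + ["reject"] * 5,
        )
        exact = cohens_kappa(a, b, exact_p=True)
        assert 0 <= exact.p_value <= 1

    def test_degenerate_identical_constant_raters(self):
        a, b = _label_pair(["accept"] * 5, ["accept"] * 5)
        with pytest.raises(ZeroDivisionError):
            cohens_kappa(a, b)


def _ratings(probs=None, grades=None):
    n = len(probs) if probs is not None else len(grades)
    ids = [f"s{i}" for i in range(n)]
    return ToolRating(
        pd.DataFrame(
            {
                "mriqc_probability": probs if probs is not None else [0.1] * n,
                "cat12_grade": grades if grades is not None else ["B"] * n,
            },
            index=ids,
        )
    )


class TestThresholds:
    def test_mriqc_boundary_inclusive(self):
        labels = apply_mriqc_threshold(_ratings(probs=[0.5]), THRESHOLD_SCHEMES["default"])
        assert labels.labels.iloc[0] == "reject"

    def test_mriqc_lenient_accepts_mid_probability(self):
        labels = apply_mriqc_threshold(_ratings(probs=[0.55]), THRESHOLD_SCHEMES["lenient"])
        assert labels.labels.iloc[0] == "accept"

    def test_mriqc_strict_below_threshold(self):
        labels = apply_mriqc_threshold(_ratings(probs=[0.39]), THRESHOLD_SCHEMES["strict"])
        assert labels.labels.iloc[0] == "accept"

    @pytest.mark.parametrize(
        "grade,scheme,expected",
        [
            ("C-", "default", "reject"),
            ("C", "strict", "reject"),
            ("C-", "lenient", "accept"),  # C- sits above the D+ cut
            ("A+", "strict", "accept"),
            ("F", "lenient", "reject"),
        ],
    )
    def test_cat12_grade_rules(self, grade, scheme, expected):
        labels = apply_cat12_threshold(_ratings(grades=[grade]), THRESHOLD_SCHEMES[scheme])
        assert labels.labels.iloc[0] == expected

    def test_missing_rating_errors(self):
        with pytest.raises(ValueError, match="missing MRIQC"):
            apply_mriqc_threshold(_ratings(probs=[np.nan]), THRESHOLD_SCHEMES["default"])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_mriqc_threshold_monotonicity(self, probs):
        """Accept %% is non-decreasing from strict to default to lenient."""
        r = _ratings(probs=probs)
        pa = [
            percent_accept(apply_mriqc_threshold(r, THRESHOLD_SCHEMES[s]))
            for s in ("strict", "default", "lenient")
        ]
        assert pa[0] <= pa[1] <= pa[2]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=15), min_size=1, max_size=60))
    def test_cat12_threshold_monotonicity(self, grade_idx):
        from t1qc.schemas import CAT12_GRADES

        r = _ratings(grades=[CAT12_GRADES[i] for i in grade_idx])
        pa = [
            percent_accept(apply_cat12_threshold(r, THRESHOLD_SCHEMES[s]))
            for s in ("strict", "default", "lenient")
        ]
        assert pa[0] <= pa[1] <= pa[2]


class TestPercentAccept:
    def test_mixed_counts(self):
        labels = LabelSet(
            pd.Series(["accept"] * 9 + ["reject"], index=[f"s{i}" for i in range(10)])
        )
        assert percent_accept(labels) == pytest.approx(90.0)

    def test_all_accept(self):
        labels = LabelSet(pd.Series(["accept"] * 4, index=list("abcd")))
        assert percent_accept(labels) == 100.0

    def test_empty_error(self):
        labels = LabelSet(pd.Series([], dtype=str))
        with pytest.raises(ValueError, match="empty"):
            percent_accept(labels)

    def test_grouped(self):
        labels = LabelSet(
            pd.Series(["accept", "accept", "reject", "accept"], index=list("abcd"))
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        out = percent_accept(labels, groups)
        assert out["g1"] == 100.0 and out["g2"] == 50.0
        assert out["overall"] == 75.0


class TestCorrelateMeasures:
    @staticmethod
    def _tables(n=50, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        a = pd.DataFrame(rng.standard_normal((n, 3)), index=ids, columns=["m0", "m1", "m2"])
        b = pd.DataFrame(rng.standard_normal((n, 2)), index=ids, columns=["c0", "c1"])
        b["c0"] = a["m0"]  # planted duplicate across tables
        return QCFeatureTable(a), QCFeatureTable(b)

    def test_planted_duplicate_r_one(self):
        out = correlate_measures(*self._tables())
        assert out.r.loc["m0", "c0"] == pytest.approx(1.0)

    def test_matches_scipy_pearson(self):
        mr, ct = self._tables()
        out = correlate_measures(mr, ct)
        ref = stats.pearsonr(mr.features["m1"], ct.features["c1"])
        assert out.r.loc["m1", "c1"] == pytest.approx(ref.statistic)
        assert out.p.loc["m1", "c1"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_fisher_ci_closed_form(self):
        mr, ct = self._tables()
        out = correlate_measures(mr, ct)
        r = out.r.loc["m1", "c0"]
        half = 1.96 / np.sqrt(50 - 3)
        assert out.ci_low.loc["m1", "c0"] == pytest.approx(np.tanh(np.arctanh(r) - half), abs=1e-4)
        assert out.ci_high.loc["m1", "c0"] == pytest.approx(np.tanh(np.arctanh(r) + half), abs=1e-4)
        assert out.ci_low.loc["m1", "c0"] <= r <= out.ci_high.loc["m1", "c0"]

    def test_insufficient_pairs(self):
        mr, ct = self._tables(n=3)
        with pytest.raises(ValueError, match=">= 4"):
            correlate_measures(mr, ct)


class TestKSSiteComparison:
    @staticmethod
    def _table(values_by_site, feature="f0"):
        rows, sites = [], []
        for site, vals in values_by_site.items():
            rows.extend(vals)
            sites.extend([site] * len(vals))
        ids = [f"s{i}" for i in range(len(rows))]
        return QCFeatureTable(
            pd.DataFrame({feature: rows}, index=ids, dtype=float),
            pd.DataFrame({"site_id": sites}, index=ids),
        )

    def test_identical_samples_d_zero(self):
        vals = list(range(10))
        out = ks_site_comparison(self._table({"A": vals, "B": vals}))
        assert out.results["D"].iloc[0] == 0.0

    def test_disjoint_supports_d_one(self):
        out = ks_site_comparison(self._table({"A": [0, 1, 2], "B": [10, 11, 12]}))
        assert out.results["D"].iloc[0] == 1.0

    def test_brute_force_ecdf_gap(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(40)
        b = rng.standard_normal(35) + 0.5
        out = ks_site_comparison(self._table({"A": list(a), "B": list(b)}))
        grid = np.concatenate([a, b])
        gap = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert out.results["D"].iloc[0] == pytest.approx(gap)

    def test_bonferroni_m_rule(self, small_cohort):
        _, table, _, _ = small_cohort
        feats = table.feature_names[:80]
        out = ks_site_comparison(table.subset(table.scan_ids[:160]), features=feats)
        # 160 scans cover 2 sites -> one pair x 80 features
        assert out.m == 80
        raw, adj = out.results["p"], out.results["p_adj"]
        assert np.allclose(adj, np.minimum(1.0, raw * 80))

    def test_single_site_error(self):
        with pytest.raises(ValueError, match="at least 2 sites"):
            ks_site_comparison(self._table({"A": [1, 2, 3]}))
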