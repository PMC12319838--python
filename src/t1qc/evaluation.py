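"""Performance metrics, rater agreement, threshold schemes, and site diagnostics.

Conventions: the positive class is *accept* (TP = correctly predicted accept,
TN = correctly predicted reject), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), balanced accuracy = their mean, FPR = FP/(FP+TN). Any ratio with
a zero denominator is undefined and reported as NaN — never coerced to 0 —
and group means are computed over defined entries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ACCEPT, REJECT, LabelSet, QCFeatureTable, ToolRating
from .schemas import GRADE_INDEX, canonical_grade

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts and derived rates (positive class = accept)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def fpr(self) -> float:
        return self._ratio(self.fp, self.fp + self.tn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "fpr": self.fpr,
        }


def _aligned(a: LabelSet, b: LabelSet) -> tuple[np.ndarray, np.ndarray]:
    if set(a.scan_ids) != set(b.scan_ids):
        raise ValueError("label sets cover different scan ids")
    ids = a.scan_ids
    return (a.labels.loc[ids] == ACCEPT).to_numpy(), (b.labels.loc[ids] == ACCEPT).to_numpy()


def confusion_metrics(y_true: LabelSet, y_pred: LabelSet) -> ConfusionMetrics:
    """Confusion counts of predicted vs. true accept/reject labels."""
    t, p = _aligned(y_true, y_pred)
    return ConfusionMetrics(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def performance_breakdown(y_true: LabelSet, y_pred: LabelSet, groups: pd.Series) -> pd.DataFrame:
    """Per-group confusion metrics (rows indexed by group label).

    Undefined rates stay NaN; callers averaging across groups should use
    NaN-aware means, matching the exclusion of groups with an empty class.
    """
    ids = y_true.scan_ids
    missing = ids.difference(groups.index)
    if len(missing):
        raise KeyError(f"scan ids without a group label: {missing.tolist()[:5]}")
    rows = {}
    for g, members in groups.loc[ids].groupby(groups.loc[ids]).groups.items():
        cm = confusion_metrics(y_true.subset(members), y_pred.subset(members))
        rows[g] = cm.as_dict()
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's (unweighted) kappa for two binary raters."""

    kappa: float
    po: float
    pe: float
    p_value: float
    n: int

    @property
    def percent_agreement(self) -> float:
        return 100.0 * self.po


def _kappa_from_table(table: np.ndarray) -> tuple[float, float, float]:
    n = table.sum()
    po = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0:
        raise ZeroDivisionError("both raters constant and identical: kappa undefined")
    return (po - pe) / (1.0 - pe), float(po), pe


def cohens_kappa(r1: LabelSet, r2: LabelSet, exact_p: bool = False) -> AgreementResult:
    """Chance-corrected agreement between two accept/reject ratings.

    The p-value tests kappa = 0 using the large-sample normal approximation
    with the standard error under the independence null (the convention of
    IRR-style packages). ``exact_p=True`` instead enumerates the permutation
    null conditional on both raters' margins (hypergeometric), practical for
    small n.
    """
    a, b = _aligned(r1, r2)
    n = len(a)
    if n == 0:
        raise ValueError("empty label sets")
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ],
        dtype=float,
    )
    kappa, po, pe = _kappa_from_table(table)

    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    if exact_p:
        p_value = _exact_kappa_p(table.astype(int), kappa)
    else:
        var0 = (pe + pe**2 - float(((row * col) * (row + col)).sum())) / (n * (1.0 - pe) ** 2)
        if var0 <= 0:
            p_value = float("nan")
        else:
            z = kappa / np.sqrt(var0)
            p_value = float(2.0 * stats.norm.sf(abs(z)))
    return AgreementResult(kappa=float(kappa), po=po, pe=pe, p_value=p_value, n=n)


def _exact_kappa_p(table: np.ndarray, observed_kappa: float) -> float:
    """Permutation p-value conditional on margins: P(|kappa| >= |observed|)."""
    n = int(table.sum())
    r1 = int(table[0].sum())  # rater-1 accepts
    c1 = int(table[:, 0].sum())  # rater-2 accepts
    p = 0.0
    total = comb(n, c1)
    for a11 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        t = np.array(
            [[a11, r1 - a11], [c1 - a11, n - r1 - (c1 - a11)]], dtype=float
        )
        try:
            k, _, _ = _kappa_from_table(t)
        except ZeroDivisionError:
            continue
        if abs(k) >= abs(observed_kappa) - 1e-12:
            p += comb(r1, a11) * comb(n - r1, c1 - a11) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# tool-rating thresholds


@dataclass(frozen=True)
class ThresholdScheme:
    """Accept/reject thresholds for the two tools' ratings.

    MRIQC: reject iff probability >= threshold (strict 0.4, default 0.5,
    lenient 0.6 — a lower cut rejects more). CAT12: reject iff the letter
    grade is at or below the scheme grade on the A+..F scale (strict C,
    default C-, lenient D+).
    """

    mriqc: float = 0.5
    cat12: str = "C-"

    def __post_init__(self) -> None:
        if not 0 < self.mriqc < 1:
            raise ValueError("mriqc threshold must lie in (0, 1)")
        object.__setattr__(self, "cat12", canonical_grade(self.cat12))


THRESHOLD_SCHEMES = {
    "strict": ThresholdScheme(mriqc=0.4, cat12="C"),
    "default": ThresholdScheme(mriqc=0.5, cat12="C-"),
    "lenient": ThresholdScheme(mriqc=0.6, cat12="D+"),
}


def apply_mriqc_threshold(ratings: ToolRating, scheme: ThresholdScheme) -> LabelSet:
    """Binary labels from MRIQC probabilities: reject iff p >= threshold."""
    prob = ratings.mriqc_probability
    if prob.isna().any():
        missing = prob.index[prob.isna()].tolist()
        raise ValueError(f"missing MRIQC probability for scans {missing[:5]}")
    labels = np.where(prob.to_numpy() >= scheme.mriqc, REJECT, ACCEPT)
    return LabelSet(pd.Series(labels, index=prob.index), provenance="mriqc")


def apply_cat12_threshold(ratings: ToolRating, scheme: ThresholdScheme) -> LabelSet:
    """Binary labels from CAT12 grades: reject iff grade at or below the cut."""
    grades = ratings.cat12_grade
    if grades.isna().any():
        missing = grades.index[grades.isna()].tolist()
        raise ValueError(f"missing CAT12 grade for scans {missing[:5]}")
    cut = GRADE_INDEX[scheme.cat12]
    idx = grades.map(GRADE_INDEX).to_numpy()
    labels = np.where(idx >= cut, REJECT, ACCEPT)
    return LabelSet(pd.Series(labels, index=grades.index), provenance="cat12")


def percent_accept(labels: LabelSet, groups: pd.Series | None = None):
    """Percentage of scans labelled accept, overall or per group.

    Returns a float when ``groups`` is None, else a Series with an 'overall'
    entry appended.
    """
    if len(labels) == 0:
        raise ValueError("empty label set")
    overall = 100.0 * (labels.labels == ACCEPT).mean()
    if groups is None:
        return float(overall)
    out = {}
    for g, members in groups.loc[labels.scan_ids].groupby(
        groups.loc[labels.scan_ids]
    ).groups.items():
        if len(members) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = 100.0 * (labels.labels.loc[members] == ACCEPT).mean()
    series = pd.Series(out, name="percent_accept").sort_index()
    series.loc["overall"] = float(overall)
    return series


# ---------------------------------------------------------------------------
# cross-tool correlation


@dataclass
class CorrelationMatrix:
    """Pearson r (rows = MRIQC measures, cols = CAT12 measures) with p and 95% CI."""

    r: pd.DataFrame
    p: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n: int


def correlate_measures(mriqc: QCFeatureTable, cat12: QCFeatureTable) -> CorrelationMatrix:
    """Full cross-correlation matrix between the two tools' measures.

    Pearson r with a two-sided p-value and a Fisher-z 95% confidence interval
    ``tanh(atanh(r) +/- 1.96 / sqrt(n - 3))``. Requires >= 4 aligned scans.
    """
    ids = mriqc.scan_ids.intersection(cat12.scan_ids)
    if len(ids) < 4:
        raise ValueError(f"need >= 4 complete scan pairs, found {len(ids)}")
    A = mriqc.features.loc[ids]
    B = cat12.features.loc[ids]
    n = len(ids)

    Az = (A - A.mean()) / A.std(ddof=0).replace(0.0, np.nan)
    Bz = (B - B.mean()) / B.std(ddof=0).replace(0.0, np.nan)
    r = (Az.T.to_numpy() @ Bz.to_numpy()) / n
    r = np.clip(r, -1.0, 1.0)

    # two-sided p via the exact t distribution of r under the null
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)

    idx, cols = A.columns, B.columns
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        ci_low=pd.DataFrame(lo, index=idx, columns=cols),
        ci_high=pd.DataFrame(hi, index=idx, columns=cols),
        n=n,
    )


# ---------------------------------------------------------------------------
# site-distribution diagnostics


@dataclass
class DistributionComparison:
    """Two-sample KS results for every (feature, site pair) with Bonferroni p."""

    results: pd.DataFrame  # columns: feature, site_a, site_b, D, p, p_adj
    m: int

    def significant_counts(self, alpha: float = 0.05) -> pd.Series:
        """Number of features per site pair with adjusted p below alpha."""
        sig = self.results[self.results["p_adj"] < alpha]
        pairs = self.results.groupby(["site_a", "site_b"]).size().index
        counts = sig.groupby(["site_a", "site_b"]).size()
        return counts.reindex(pairs, fill_value=0)


def ks_site_comparison(
    table: QCFeatureTable,
    features: list[str] | None = None,
    sites: list[str] | None = None,
    exact_below: int = 25,
) -> DistributionComparison:
    """Two-sample Kolmogorov-Smirnov tests between all site pairs per feature.

    p-values use the asymptotic Kolmogorov distribution, switching to the
    exact method when both samples have fewer than ``exact_below``
    observations; the Bonferroni adjustment multiplies by the total number of
    comparisons m = n_features x n_site_pairs.
    """
    features = list(features) if features is not None else table.feature_names
    site_col = table.sites
    sites = list(sites) if sites is not None else sorted(site_col.unique())
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to compare")
    groups = {
        s: table.features.loc[site_col.index[site_col == s], features] for s in sites
    }
    for s, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 observations")

    rows = []
    for sa, sb in combinations(sites, 2):
        na, nb = len(groups[sa]), len(groups[sb])
        method = "exact" if (na < exact_below and nb < exact_below) else "asymp"
        for f in features:
            res = stats.ks_2samp(groups[sa][f], groups[sb][f], method=method)
            rows.append((f, sa, sb, float(res.statistic), float(res.pvalue)))
    frame = pd.DataFrame(rows, columns=["feature", "site_a", "site_b", "D", "p"])
    m = len(frame)
    frame["p_adj"] = (frame["p"] * m).clip(upper=1.0)
    return DistributionComparison(results=frame, m=m)
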