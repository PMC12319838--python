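"""Multi-method feature ranking and robust rank aggregation (RRA).

Four rankers are provided: two univariate (absolute two-sample t statistic
and AUC distance from chance) and two multivariate (ReliefF, which scores
features by how well they separate each scan from its nearest misses versus
nearest hits, and mRMR, greedy mutual-information relevance minus redundancy
on quantile-discretised features). The per-method rank lists are combined
with robust rank aggregation: for each feature the sorted normalised rank
vector is compared against the order statistics of uniform ranks, and the
aggregation score rho is the minimum Beta order-statistic probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import REJECT, LabelSet

RANK_METHODS = ("t_abs", "auc", "relieff", "mrmr")


@dataclass
class RankList:
    """A complete ranking of the feature set by one method (rank 1 = best)."""

    method: str
    ranking: list[str]
    scores: pd.Series

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.scores.index):
            raise ValueError("ranking must be a permutation of the scored features")

    @property
    def ranks(self) -> pd.Series:
        """Feature -> integer rank (1-based)."""
        return pd.Series(
            np.arange(1, len(self.ranking) + 1), index=self.ranking, name=self.method
        )


@dataclass
class RankAggregation:
    """Robust rank aggregation of several rank lists."""

    inputs: list[RankList]
    aggregated_ranking: list[str]
    rho: pd.Series
    adjusted_rho: pd.Series


def _as_reject_mask(y) -> np.ndarray:
    if isinstance(y, LabelSet):
        return (y.labels == REJECT).to_numpy()
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        return arr == REJECT
    return arr.astype(bool)


def _order(scores: pd.Series) -> list[str]:
    """Descending score, ties broken lexicographically by feature name."""
    frame = pd.DataFrame({"score": scores, "name": scores.index})
    frame = frame.sort_values(["score", "name"], ascending=[False, True], kind="stable")
    return frame["name"].tolist()


# ---------------------------------------------------------------------------
# individual rankers


def _t_abs_scores(X: np.ndarray, reject: np.ndarray) -> np.ndarray:
    t, _ = stats.ttest_ind(X[reject], X[~reject], axis=0, equal_var=True)
    return np.nan_to_num(np.abs(t), nan=0.0)


def _auc_scores(X: np.ndarray, reject: np.ndarray) -> np.ndarray:
    n1 = int(reject.sum())
    n0 = len(reject) - n1
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[reject].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return np.abs(auc - 0.5)


def _relieff_scores(X: np.ndarray, reject: np.ndarray, k: int) -> np.ndarray:
    """ReliefF weights with k nearest hits/misses, equal-influence weighting.

    Features are range-normalised so per-feature differences lie in [0, 1];
    neighbours are found with Manhattan distance on the normalised matrix.
    With k >= class sizes this degenerates to the all-neighbour estimator.
    """
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span < 1e-12] = 1.0
    Z = (X - X.min(axis=0)) / span

    from scipy.spatial.distance import cdist

    dist = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    weights = np.zeros(p)
    for i in range(n):
        same = reject == reject[i]
        same[i] = False
        other = ~same
        other[i] = False
        hit_idx = np.flatnonzero(same)
        miss_idx = np.flatnonzero(other)
        k_hit = min(k, len(hit_idx))
        k_miss = min(k, len(miss_idx))
        if k_hit == 0 or k_miss == 0:
            raise ValueError("relieff requires at least 2 rows in each class")
        hits = hit_idx[np.argsort(dist[i, hit_idx], kind="stable")[:k_hit]]
        misses = miss_idx[np.argsort(dist[i, miss_idx], kind="stable")[:k_miss]]
        weights += np.abs(Z[misses] - Z[i]).mean(axis=0)
        weights -= np.abs(Z[hits] - Z[i]).mean(axis=0)
    return weights / n


def _quantile_discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-feature quantile binning into at most n_bins levels."""
    out = np.empty(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) from the contingency table of two small-integer codes."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _mrmr_order(X: np.ndarray, reject: np.ndarray, names: list[str], n_bins: int):
    """Greedy mRMR (mutual-information difference) selection order and scores."""
    D = _quantile_discretize(X, n_bins)
    y = reject.astype(np.int64)
    p = X.shape[1]
    relevance = np.array([_mutual_information(D[:, j], y) for j in range(p)])

    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = _mutual_information(D[:, key[0]], D[:, key[1]])
        return mi_cache[key]

    selected: list[int] = []
    scores = np.empty(p)
    remaining = list(range(p))
    while remaining:
        if not selected:
            crit = {j: relevance[j] for j in remaining}
        else:
            crit = {
                j: relevance[j] - np.mean([pair_mi(j, s) for s in selected])
                for j in remaining
            }
        best = min(remaining, key=lambda j: (-crit[j], names[j]))
        scores[best] = crit[best]
        selected.append(best)
        remaining.remove(best)
    order = [names[j] for j in selected]
    return order, scores


# ---------------------------------------------------------------------------
# public API


def rank_features(
    X: pd.DataFrame,
    y,
    method: str,
    seed: int = 0,
    relieff_k: int = 10,
    mrmr_bins: int = 10,
) -> RankList:
    """Rank all features by relevance to the binary accept/reject target.

    ``method`` is one of ``t_abs`` (descending |two-sample t|), ``auc``
    (descending |AUC - 0.5|), ``relieff`` (k nearest hits/misses, k clipped
    to the available neighbours), or ``mrmr`` (greedy mutual-information
    difference on quantile-discretised features). All rankers are
    deterministic given the data; ties break lexicographically.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {RANK_METHODS}")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    reject = _as_reject_mask(y)
    if len(reject) != len(X):
        raise ValueError("X and y are not aligned")
    n_rej = int(reject.sum())
    if n_rej == 0 or n_rej == len(reject):
        raise ValueError("both classes must be present to rank features")

    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    if method == "t_abs":
        scores = pd.Series(_t_abs_scores(arr, reject), index=names)
        order = _order(scores)
    elif method == "auc":
        scores = pd.Series(_auc_scores(arr, reject), index=names)
        order = _order(scores)
    elif method == "relieff":
        scores = pd.Series(_relieff_scores(arr, reject, relieff_k), index=names)
        order = _order(scores)
    else:  # mrmr: greedy order is the ranking; scores are the greedy criteria
        order, raw = _mrmr_order(arr, reject, names, mrmr_bins)
        scores = pd.Series(raw, index=names)
    return RankList(method=method, ranking=order, scores=scores)


def aggregate_ranks(lists: list[RankList], n_features: int | None = None) -> RankAggregation:
    """Robust rank aggregation of m rank lists over a common feature set.

    For each feature with normalised ranks ``r = rank / n`` across the m
    lists (sorted ascending), ``rho = min_k P(Beta(k, m - k + 1) <= r_(k))``
    — the probability that the k-th smallest of m uniform ranks would be at
    least this extreme. Features are ordered by ascending rho; ties break by
    mean input rank, then feature name. ``adjusted_rho`` is the Bonferroni
    correction ``min(1, n_features * rho)``.
    """
    if not lists:
        raise ValueError("need at least one rank list")
    feature_set = set(lists[0].ranking)
    for rl in lists[1:]:
        if set(rl.ranking) != feature_set:
            raise ValueError("all rank lists must rank the same feature set")
    features = sorted(feature_set)
    n = n_features if n_features is not None else len(features)
    if n < len(features):
        raise ValueError("n_features smaller than the ranked feature set")
    m = len(lists)

    rank_matrix = pd.concat([rl.ranks for rl in lists], axis=1).loc[features]
    r = np.sort(rank_matrix.to_numpy(dtype=float) / n, axis=1)
    ks = np.arange(1, m + 1)
    beta_p = stats.beta.cdf(r, ks[None, :], (m - ks + 1)[None, :])
    rho = pd.Series(beta_p.min(axis=1), index=features, name="rho")
    rho = rho.clip(lower=np.finfo(float).tiny)  # rho in (0, 1]

    mean_rank = rank_matrix.mean(axis=1)
    order_frame = pd.DataFrame({"rho": rho, "mean_rank": mean_rank, "name": features})
    order_frame = order_frame.sort_values(["rho", "mean_rank", "name"], kind="stable")
    ranking = order_frame["name"].tolist()

    adjusted = (rho * n).clip(upper=1.0).rename("adjusted_rho")
    return RankAggregation(list(lists), ranking, rho, adjusted)
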