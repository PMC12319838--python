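"""Splitting and validation protocols for the QC classifier.

The training protocol is a repeated nested cross-validation: five outer
folds estimate generalisation, three inner folds select hyperparameters for
each candidate feature size, and the whole procedure is repeated over
iterations with fresh fold shuffles. Inside every training side the pipeline
re-fits the site-wise z-score normalisation and the multi-method feature
ranking, so no statistic used on evaluation rows is ever a function of those
rows. Fold rankings are pooled with robust rank aggregation into the final
feature ordering.

The additional experiments re-use the settings selected on the combined data
(hyperparameters, feature ranking, feature size): leave-one-site-out,
group-filtered train/test splits (field strength, manufacturer), and
incremental inclusion of a new cohort's scans into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import (
    grid_combinations,
    predict,
    smaller_model_key,
    train_classifier,
)
from .core_io import LabelSet, QCFeatureTable
from .evaluation import ConfusionMetrics, confusion_metrics
from .preprocess import NormalizationStats, apply_zscore, fit_sitewise_zscore
from .ranking import RANK_METHODS, RankList, aggregate_ranks, rank_features

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_SIZES = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 104)


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass
class SplitSpec:
    """Train/test partition of scan ids with the strata used to build it."""

    assignment: pd.Series  # scan_id -> 'train' | 'test'
    strata: pd.Series
    train_fraction: float
    seed: int

    @property
    def train_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "test"]


def stratified_split(
    table: QCFeatureTable,
    labels: LabelSet,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitSpec:
    """Stratified train/test split with largest-remainder rounding.

    Strata combine the label, the site, and the diagnosis group when
    available, so both partitions carry a fair share of each. Per-stratum
    train counts are ``floor(n_s * f)`` plus one extra for the strata with
    the largest fractional remainders until the overall target
    ``round(N * f)`` is met. Single-member strata go to train with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = labels.scan_ids
    strata = labels.labels.astype(str) + "|" + table.sites.loc[ids].astype(str)
    if "diagnosis_group" in table.meta.columns and table.meta["diagnosis_group"].notna().all():
        strata = strata + "|" + table.meta.loc[ids, "diagnosis_group"].astype(str)

    rng = np.random.default_rng(seed)
    n_total = len(ids)
    target_train = int(math.floor(n_total * train_fraction + 0.5))

    groups = {name: list(members) for name, members in strata.groupby(strata).groups.items()}
    singles = [name for name, members in groups.items() if len(members) == 1]
    for name in singles:
        logger.warning("stratum %r has a single member; assigned to train", name)

    quotas = {
        name: len(members) * train_fraction
        for name, members in groups.items()
        if name not in singles
    }
    floors = {name: int(math.floor(q)) for name, q in quotas.items()}
    extras = target_train - len(singles) - sum(floors.values())
    order = sorted(
        quotas,
        key=lambda name: (-(quotas[name] - floors[name]), -len(groups[name]), name),
    )
    take = dict(floors)
    i = 0
    while extras > 0 and i < len(order):
        name = order[i]
        if take[name] < len(groups[name]):
            take[name] += 1
            extras -= 1
        i += 1
    while extras < 0:
        # forced singletons overshot the target; trim the smallest remainders
        name = order[-1]
        order = order[:-1]
        if take[name] > 0:
            take[name] -= 1
            extras += 1

    assignment = pd.Series("test", index=ids, name="split")
    for name, members in groups.items():
        members = list(members)
        if name in singles:
            assignment.loc[members] = "train"
            continue
        chosen = rng.choice(len(members), size=take[name], replace=False)
        assignment.loc[[members[j] for j in chosen]] = "train"
    return SplitSpec(assignment=assignment, strata=strata, train_fraction=train_fraction, seed=seed)


# ---------------------------------------------------------------------------
# grids


@dataclass
class GridSpec:
    """Classifier kind, hyperparameter grid, and the feature-size sweep."""

    classifier: str = "rus"
    grid: dict | None = None
    feature_sizes: tuple[int, ...] = DEFAULT_FEATURE_SIZES
    ranking_methods: tuple[str, ...] = RANK_METHODS
    relieff_k: int = 10

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.feature_sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])) or min(sizes) < 1:
            raise ValueError("feature_sizes must be strictly increasing positive integers")
        self.feature_sizes = sizes
        self.combos = grid_combinations(self.classifier, self.grid)

    def validate_for(self, n_features: int) -> None:
        if max(self.feature_sizes) > n_features:
            raise ValueError(
                f"feature size {max(self.feature_sizes)} exceeds the {n_features} available features"
            )


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCVResult:
    """Per-(iteration, fold, feature size) outcomes of the nested CV."""

    records: pd.DataFrame
    fold_rank_lists: list[RankList]
    aggregated_ranking: list[str]
    rho: pd.Series
    mean_ba_per_size: pd.Series
    selected_feature_size: int
    selected_hyper_per_size: dict[int, object]
    grid: GridSpec
    seed: int
    n_iterations: int
    n_inner_fits: int = 0
    n_outer_fits: int = 0

    @property
    def selected_hyper(self):
        return self.selected_hyper_per_size[self.selected_feature_size]


def _fold_strata(labels: LabelSet, sites: pd.Series, n_splits: int) -> np.ndarray:
    """Label x site strata when every stratum can fill the folds, else label only."""
    y = labels.labels
    combined = y.astype(str) + "|" + sites.loc[y.index].astype(str)
    if combined.value_counts().min() >= n_splits:
        return combined.to_numpy()
    if y.value_counts().min() < n_splits:
        raise ValueError(
            f"a class has fewer members than the {n_splits} folds; cannot stratify"
        )
    return y.to_numpy()


def _balanced_accuracy(cm: ConfusionMetrics) -> float:
    return cm.balanced_accuracy


def _rank_fold(X: pd.DataFrame, y: LabelSet, grid: GridSpec, seed: int) -> tuple[list[str], RankList]:
    lists = [
        rank_features(X, y, method, seed=seed, relieff_k=grid.relieff_k)
        for method in grid.ranking_methods
    ]
    agg = aggregate_ranks(lists)
    # represent the fold's aggregated order as a rank list for later pooling
    fold_list = RankList(method="rra", ranking=agg.aggregated_ranking, scores=1.0 - agg.rho)
    return agg.aggregated_ranking, fold_list


def run_nested_cv(
    table: QCFeatureTable,
    labels: LabelSet,
    grid: GridSpec,
    n_iterations: int = 10,
    seed: int = 0,
    outer_folds: int = 5,
    inner_folds: int = 3,
) -> NestedCVResult:
    """Repeated nested cross-validation with a feature-size sweep.

    For each iteration (fold shuffle seeded with ``seed + iteration``) and
    outer fold: normalisation and feature ranking are fitted on the outer
    training side; the inner folds grid-search hyperparameters per feature
    size by mean inner balanced accuracy (ties prefer smaller models); the
    outer fold is then evaluated at every feature size with its selection.
    Fold rankings are pooled by robust rank aggregation; the selected feature
    size maximises mean outer balanced accuracy; the hyperparameters reported
    per size are the modal inner choice across folds and iterations.
    """
    grid.validate_for(len(table.feature_names))
    ids = labels.scan_ids
    table = table.subset(ids)
    records: list[dict] = []
    fold_lists: list[RankList] = []
    n_inner_fits = n_outer_fits = 0

    for it in range(n_iterations):
        it_seed = (seed + it) % 2**31
        strata = _fold_strata(labels, table.sites, outer_folds)
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=it_seed)
        for f, (tr, te) in enumerate(outer.split(np.zeros(len(ids)), strata)):
            tr_ids, te_ids = ids[tr], ids[te]
            y_tr, y_te = labels.subset(tr_ids), labels.subset(te_ids)

            stats = fit_sitewise_zscore(table, tr_ids)
            X_tr = apply_zscore(table.subset(tr_ids), stats, unseen_sites="pooled").features
            X_te = apply_zscore(table.subset(te_ids), stats, unseen_sites="pooled").features

            fold_ranking, fold_list = _rank_fold(X_tr, y_tr, grid, it_seed)
            fold_lists.append(fold_list)

            # ---- inner grid search ---------------------------------------
            inner_seed = (it_seed * 31 + f) % 2**31
            inner_strata = _fold_strata(y_tr, table.sites.loc[tr_ids], inner_folds)
            inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
            inner_ba = {
                (size, ci): [] for size in grid.feature_sizes for ci in range(len(grid.combos))
            }
            for g, (itr, ite) in enumerate(inner.split(np.zeros(len(tr_ids)), inner_strata)):
                itr_ids, ite_ids = tr_ids[itr], tr_ids[ite]
                iy_tr, iy_te = labels.subset(itr_ids), labels.subset(ite_ids)
                istats = fit_sitewise_zscore(table, itr_ids)
                iX_tr = apply_zscore(table.subset(itr_ids), istats, unseen_sites="pooled").features
                iX_te = apply_zscore(table.subset(ite_ids), istats, unseen_sites="pooled").features
                iranking, _ = _rank_fold(iX_tr, iy_tr, grid, inner_seed)
                for size in grid.feature_sizes:
                    feats = iranking[:size]
                    for ci, combo in enumerate(grid.combos):
                        fit_seed = (inner_seed + 7919 * g + 104729 * ci + size) % 2**31
                        model = train_classifier(
                            iX_tr[feats], iy_tr, grid.classifier, combo, seed=fit_seed
                        )
                        n_inner_fits += 1
                        _, pred = predict(model, iX_te[feats])
                        inner_ba[(size, ci)].append(
                            _balanced_accuracy(confusion_metrics(iy_te, pred))
                        )

            # ---- outer evaluation with the inner selection ---------------
            for size in grid.feature_sizes:
                means = {
                    ci: float(np.nanmean(inner_ba[(size, ci)]))
                    for ci in range(len(grid.combos))
                }
                best_ba = max(means.values())
                candidates = [ci for ci, v in means.items() if v >= best_ba - 1e-12]
                best_ci = min(
                    candidates,
                    key=lambda ci: smaller_model_key(grid.classifier, grid.combos[ci]),
                )
                combo = grid.combos[best_ci]
                feats = fold_ranking[:size]
                fit_seed = (it_seed + 7919 * f + size) % 2**31
                model = train_classifier(X_tr[feats], y_tr, grid.classifier, combo, seed=fit_seed)
                n_outer_fits += 1
                _, pred = predict(model, X_te[feats])
                cm = confusion_metrics(y_te, pred)
                records.append(
                    {
                        "iteration": it,
                        "fold": f,
                        "feature_size": size,
                        "combo_index": best_ci,
                        "hyper": repr(combo),
                        **cm.as_dict(),
                    }
                )

    rec = pd.DataFrame.from_records(records)
    mean_ba = rec.groupby("feature_size")["balanced_accuracy"].mean()
    best = mean_ba.max()
    selected_size = int(min(s for s, v in mean_ba.items() if v >= best - 1e-12))

    selected_hyper: dict[int, object] = {}
    for size in grid.feature_sizes:
        chosen = rec.loc[rec["feature_size"] == size, "combo_index"]
        counts = chosen.value_counts()
        top = counts[counts == counts.max()].index
        ci = min(top, key=lambda c: smaller_model_key(grid.classifier, grid.combos[int(c)]))
        selected_hyper[size] = grid.combos[int(ci)]

    agg = aggregate_ranks(fold_lists)
    return NestedCVResult(
        records=rec,
        fold_rank_lists=fold_lists,
        aggregated_ranking=agg.aggregated_ranking,
        rho=agg.rho,
        mean_ba_per_size=mean_ba,
        selected_feature_size=selected_size,
        selected_hyper_per_size=selected_hyper,
        grid=grid,
        seed=seed,
        n_iterations=n_iterations,
        n_inner_fits=n_inner_fits,
        n_outer_fits=n_outer_fits,
    )


# ---------------------------------------------------------------------------
# final model


@dataclass
class FinalModel:
    """Final classifier refit on all training rows at the best feature size."""

    model: object
    stats: NormalizationStats
    ranking: list[str]
    feature_size: int
    classifier: str
    per_size_holdout: pd.DataFrame
    holdout_metrics: ConfusionMetrics

    @property
    def features(self) -> list[str]:
        return self.ranking[: self.feature_size]


def train_final_model(
    table: QCFeatureTable,
    labels: LabelSet,
    split: SplitSpec,
    result: NestedCVResult,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> FinalModel:
    """Refit on all training data per feature size; keep the holdout argmax.

    Normalisation statistics come from the training rows only and are
    exported for deployment; the holdout rows are transformed with them
    (pooled statistics for any unseen site). Each feature size is refit with
    its selected hyperparameters and the final reported model is the size
    maximising holdout balanced accuracy (ties prefer the smaller size).
    """
    grid = grid or result.grid
    if set(grid.feature_sizes) - set(result.selected_hyper_per_size):
        raise ValueError("grid feature sizes do not match the nested-CV result")
    tr_ids, te_ids = split.train_ids, split.test_ids
    y_tr, y_te = labels.subset(tr_ids), labels.subset(te_ids)
    stats = fit_sitewise_zscore(table, tr_ids)
    X_tr = apply_zscore(table.subset(tr_ids), stats, unseen_sites="pooled").features
    X_te = apply_zscore(table.subset(te_ids), stats, unseen_sites="pooled").features

    rows, models, cms = [], {}, {}
    for size in grid.feature_sizes:
        combo = result.selected_hyper_per_size[size]
        feats = result.aggregated_ranking[:size]
        model = train_classifier(X_tr[feats], y_tr, grid.classifier, combo, seed=(seed + size) % 2**31)
        _, pred = predict(model, X_te[feats])
        cm = confusion_metrics(y_te, pred)
        models[size], cms[size] = model, cm
        rows.append({"feature_size": size, "hyper": repr(combo), **cm.as_dict()})
    per_size = pd.DataFrame(rows).set_index("feature_size")

    ba = per_size["balanced_accuracy"]
    best = ba.max()
    best_size = int(min(s for s, v in ba.items() if v >= best - 1e-12))
    return FinalModel(
        model=models[best_size],
        stats=stats,
        ranking=result.aggregated_ranking,
        feature_size=best_size,
        classifier=grid.classifier,
        per_size_holdout=per_size,
        holdout_metrics=cms[best_size],
    )


# ---------------------------------------------------------------------------
# inherited-settings experiments


@dataclass(frozen=True)
class InheritedSettings:
    """Settings carried over from the combined-data model to new experiments."""

    classifier: str
    hyper: object
    ranking: tuple[str, ...]
    feature_size: int

    @classmethod
    def from_final(cls, final: FinalModel) -> "InheritedSettings":
        hyper = getattr(final.model, "hyper")
        return cls(
            classifier=final.classifier,
            hyper=hyper,
            ranking=tuple(final.ranking),
            feature_size=final.feature_size,
        )

    @property
    def features(self) -> list[str]:
        return list(self.ranking[: self.feature_size])


def _fit_inherited(
    train_table: QCFeatureTable,
    train_labels: LabelSet,
    test_table: QCFeatureTable,
    test_labels: LabelSet,
    inherited: InheritedSettings,
    seed: int,
) -> ConfusionMetrics:
    """Refit with inherited settings; test rows use train (or pooled) statistics."""
    stats = fit_sitewise_zscore(train_table, train_table.scan_ids)
    X_tr = apply_zscore(train_table, stats, unseen_sites="pooled").features
    X_te = apply_zscore(test_table, stats, unseen_sites="pooled").features
    feats = inherited.features
    model = train_classifier(X_tr[feats], train_labels, inherited.classifier, inherited.hyper, seed=seed)
    _, pred = predict(model, X_te[feats])
    return confusion_metrics(test_labels, pred)


@dataclass
class LOSOResult:
    """Per-held-out-site metrics plus the mean/sd over defined sites."""

    per_site: pd.DataFrame
    mean_balanced_accuracy: float
    sd_balanced_accuracy: float


def run_leave_one_site_out(
    table: QCFeatureTable,
    labels: LabelSet,
    inherited: InheritedSettings,
    sites: list[str] | None = None,
    seed: int = 0,
) -> LOSOResult:
    """Hold out each site in turn; train on the rest with inherited settings.

    Normalisation statistics come from the training sites only; the held-out
    site is normalised with the pooled training statistics (the unseen-site
    rule). Sites whose test labels contain a single class have an undefined
    balanced accuracy and are excluded from the mean.
    """
    all_sites = table.sites
    site_list = sites if sites is not None else sorted(all_sites.unique())
    unknown = set(site_list) - set(all_sites.unique())
    if unknown:
        raise KeyError(f"site(s) absent from table: {sorted(unknown)}")
    if len(all_sites.unique()) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")

    rows = {}
    for s_idx, site in enumerate(site_list):
        te_ids = all_sites.index[all_sites == site]
        tr_ids = all_sites.index[all_sites != site]
        y_tr, y_te = labels.subset(tr_ids), labels.subset(te_ids)
        cm = _fit_inherited(
            table.subset(tr_ids), y_tr, table.subset(te_ids), y_te,
            inherited, seed=(seed + 1009 * s_idx) % 2**31,
        )
        tr_counts, te_counts = y_tr.counts(), y_te.counts()
        rows[site] = {
            "train_reject": tr_counts["reject"], "train_accept": tr_counts["accept"],
            "train_total": len(y_tr),
            "test_reject": te_counts["reject"], "test_accept": te_counts["accept"],
            "test_total": len(y_te),
            **cm.as_dict(),
        }
    per_site = pd.DataFrame.from_dict(rows, orient="index").loc[site_list]
    ba = per_site["balanced_accuracy"]
    defined = ba.dropna()
    return LOSOResult(
        per_site=per_site,
        mean_balanced_accuracy=float(defined.mean()) if len(defined) else float("nan"),
        sd_balanced_accuracy=float(defined.std(ddof=1)) if len(defined) > 1 else float("nan"),
    )


@dataclass
class GroupSplitResult:
    """Metrics of one group-filtered train/test experiment with breakdowns."""

    overall: ConfusionMetrics
    by_manufacturer: pd.DataFrame
    by_field_strength: pd.DataFrame
    train_n: int
    test_n: int


def _resolve_filter(table: QCFeatureTable, flt) -> pd.Index:
    if callable(flt):
        mask = flt(table.meta)
    elif isinstance(flt, str):
        mask = table.meta.eval(flt)
    else:
        mask = pd.Series(flt, index=table.scan_ids)
    mask = pd.Series(mask, index=table.scan_ids).astype(bool)
    return table.scan_ids[mask]


def run_group_split_experiment(
    table: QCFeatureTable,
    labels: LabelSet,
    train_filter,
    test_filter,
    inherited: InheritedSettings,
    seed: int = 0,
) -> GroupSplitResult:
    """Train on rows matching one metadata filter, test on another.

    Filters are metadata query strings (e.g. ``"field_strength == 3.0"``),
    callables on the metadata frame, or boolean masks. The training selection
    must contain both classes. Breakdowns report per-manufacturer and
    per-field-strength metrics on the test rows.
    """
    tr_ids = _resolve_filter(table, train_filter)
    te_ids = _resolve_filter(table, test_filter)
    if len(tr_ids.intersection(te_ids)):
        raise ValueError("train and test filters overlap")
    if len(tr_ids) == 0 or len(te_ids) == 0:
        raise ValueError("a filter selected no rows")
    y_tr, y_te = labels.subset(tr_ids), labels.subset(te_ids)
    if min(y_tr.counts().values()) == 0:
        raise ValueError("training filter selected a single class")
    cm = _fit_inherited(
        table.subset(tr_ids), y_tr, table.subset(te_ids), y_te, inherited, seed=seed
    )

    stats = fit_sitewise_zscore(table.subset(tr_ids), tr_ids)
    X_te = apply_zscore(table.subset(te_ids), stats, unseen_sites="pooled").features
    feats = inherited.features
    X_tr = apply_zscore(table.subset(tr_ids), stats, unseen_sites="pooled").features
    model = train_classifier(X_tr[feats], y_tr, inherited.classifier, inherited.hyper, seed=seed)
    _, pred = predict(model, X_te[feats])

    from .evaluation import performance_breakdown

    meta = table.meta.loc[te_ids]
    by_manu = performance_breakdown(y_te, pred, meta["manufacturer"])
    by_field = performance_breakdown(y_te, pred, meta["field_strength"].astype(str))
    return GroupSplitResult(
        overall=cm,
        by_manufacturer=by_manu,
        by_field_strength=by_field,
        train_n=len(tr_ids),
        test_n=len(te_ids),
    )


def _stratified_sample_counts(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class round-half-up sample sizes; >= 1 per class present when f > 0."""
    out = {}
    for label, n in counts.items():
        if n == 0:
            out[label] = 0
            continue
        k = int(math.floor(n * fraction + 0.5))
        out[label] = min(n, max(1, k))
    return out


def run_incremental_inclusion(
    main_table: QCFeatureTable,
    main_labels: LabelSet,
    new_table: QCFeatureTable,
    new_labels: LabelSet,
    fractions,
    inherited: InheritedSettings,
    seed: int = 0,
) -> pd.DataFrame:
    """Add stratified fractions of a new cohort to training; test on the rest.

    For each fraction f: a label-stratified sample of the new cohort (per
    class round-half-up, at least one row per class present when f > 0) joins
    the main training data, the classifier is retrained with the inherited
    settings, and the remaining new-cohort rows are evaluated. f = 0 applies
    the combined model directly. Seeded and deterministic.
    """
    overlap = main_table.scan_ids.intersection(new_table.scan_ids)
    if len(overlap):
        raise ValueError(f"cohorts share scan ids (e.g. {overlap[:3].tolist()})")
    rows = []
    for f in fractions:
        if not 0 <= f < 1:
            raise ValueError("fractions must lie in [0, 1)")
        rng = np.random.default_rng((seed + int(round(f * 1000))) % 2**31)
        if f == 0:
            included = pd.Index([], dtype=new_table.scan_ids.dtype)
        else:
            parts = []
            want = _stratified_sample_counts(new_labels.counts(), f)
            for label, k in want.items():
                members = new_labels.scan_ids[new_labels.labels == label]
                if k > 0:
                    chosen = rng.choice(len(members), size=k, replace=False)
                    parts.append(members[np.sort(chosen)])
            included = parts[0].append(parts[1:]) if parts else pd.Index([])
        held_out = new_table.scan_ids.difference(included)

        tr_feats = pd.concat([main_table.features, new_table.features.loc[included]])
        tr_meta = pd.concat([main_table.meta, new_table.meta.loc[included]])
        tr_table = QCFeatureTable(tr_feats, tr_meta)
        tr_labels = LabelSet(
            pd.concat([main_labels.labels, new_labels.labels.loc[included]]),
            provenance=main_labels.provenance,
        )
        y_te = new_labels.subset(held_out)
        cm = _fit_inherited(
            tr_table, tr_labels, new_table.subset(held_out), y_te,
            inherited, seed=(seed + int(round(f * 1000))) % 2**31,
        )
        rows.append(
            {
                "fraction": f,
                "n_included": len(included),
                "n_included_accept": int((new_labels.labels.loc[included] == "accept").sum()),
                "n_train": len(tr_labels),
                "n_test": len(held_out),
                **cm.as_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("fraction")
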