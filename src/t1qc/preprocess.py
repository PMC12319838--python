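"""Site-wise z-score normalisation with train-only statistics.

Multi-site QC features carry strong scanner/site location and scale effects;
normalising each feature within site removes the first-order batch effect.
To avoid leakage, means and standard deviations are estimated exclusively on
rows flagged as training and then applied unchanged to evaluation rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import QCFeatureTable

logger = logging.getLogger(__name__)

#: standard deviations below this are treated as zero-variance and guarded to 1
SIGMA_FLOOR = 1e-12


class UnseenSiteError(KeyError):
    """A row's site has no fitted statistics (caller must route, e.g. to pooled)."""


@dataclass
class NormalizationStats:
    """Per-(site, feature) mean/sd plus pooled all-training statistics.

    ``mean``/``std`` are site × feature frames; ``pooled_mean``/``pooled_std``
    are estimated on all training rows together and serve both as the
    fallback for sites with too few training rows and as the unseen-site rule
    (e.g. leave-one-site-out test sites).
    """

    mean: pd.DataFrame
    std: pd.DataFrame
    pooled_mean: pd.Series
    pooled_std: pd.Series
    fallback_sites: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return list(self.mean.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.mean.columns)


def _guard_sigma(std) -> object:
    return std.where(std >= SIGMA_FLOOR, 1.0).fillna(1.0)


def fit_sitewise_zscore(table: QCFeatureTable, train_ids) -> NormalizationStats:
    """Estimate per-site per-feature mean/sd from training rows only.

    Sites with fewer than 2 training rows fall back to the pooled
    all-training statistics (with a warning); zero-variance features are
    guarded to sd = 1 so constant features map to 0 after centering.
    Standard deviations use the n-1 (sample) convention.
    """
    train_ids = pd.Index(train_ids)
    feats = table.features.loc[train_ids]
    sites = table.sites.loc[train_ids]

    pooled_mean = feats.mean()
    pooled_std = _guard_sigma(feats.std(ddof=1))

    means, stds, fallback = {}, {}, []
    for site in table.sites.unique():
        sub = feats.loc[sites.index[sites == site]]
        if len(sub) < 2:
            logger.warning(
                "site %s has %d training row(s); using pooled training statistics",
                site, len(sub),
            )
            fallback.append(site)
            means[site] = pooled_mean
            stds[site] = pooled_std
        else:
            means[site] = sub.mean()
            stds[site] = _guard_sigma(sub.std(ddof=1))

    mean = pd.DataFrame(means).T.loc[:, feats.columns]
    std = pd.DataFrame(stds).T.loc[:, feats.columns]
    mean.index.name = std.index.name = "site_id"
    return NormalizationStats(mean, std, pooled_mean, pooled_std, fallback)


def apply_zscore(
    table: QCFeatureTable,
    stats: NormalizationStats,
    unseen_sites: str = "error",
) -> QCFeatureTable:
    """Transform features as (value - mu_site) / sigma_site using fitted stats.

    ``unseen_sites`` controls rows whose site has no fitted statistics:
    'error' raises :class:`UnseenSiteError`; 'pooled' applies the pooled
    training statistics (the leave-one-site-out rule).
    """
    if unseen_sites not in ("error", "pooled"):
        raise ValueError("unseen_sites must be 'error' or 'pooled'")
    feats = table.features
    missing_feats = [c for c in feats.columns if c not in stats.feature_names]
    if missing_feats:
        raise KeyError(f"features without fitted statistics: {missing_feats[:5]}")
    sites = table.sites
    unknown = sorted(set(sites.unique()) - set(stats.sites))
    if unknown and unseen_sites == "error":
        raise UnseenSiteError(
            f"no fitted statistics for site(s) {unknown}; "
            "route unseen sites explicitly (unseen_sites='pooled')"
        )
    known = sites.isin(stats.sites)
    mu = pd.DataFrame(index=feats.index, columns=feats.columns, dtype=float)
    sd = pd.DataFrame(index=feats.index, columns=feats.columns, dtype=float)
    if known.any():
        mu.loc[known] = stats.mean.loc[sites[known]].to_numpy()
        sd.loc[known] = stats.std.loc[sites[known]].to_numpy()
    if (~known).any():
        mu.loc[~known] = np.broadcast_to(
            stats.pooled_mean[feats.columns].to_numpy(), ((~known).sum(), feats.shape[1])
        )
        sd.loc[~known] = np.broadcast_to(
            stats.pooled_std[feats.columns].to_numpy(), ((~known).sum(), feats.shape[1])
        )
    normalized = (feats - mu) / sd
    return QCFeatureTable(normalized, table.meta.copy())
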