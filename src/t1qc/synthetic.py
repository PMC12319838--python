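"""Synthetic multi-site QC cohort generator.

Emulates the statistical structure the classification framework assumes in
real multi-site T1w QC tables: Gaussian feature marginals with per-site
additive location offsets and multiplicative scale factors (scanner/site
effects), a small reject prevalence, a planted subset of class-informative
features shifted in the reject class, and tool ratings (a reject probability
and a 16-level letter grade) monotonically coupled to a latent scan-quality
score. It does not attempt to simulate images, artefact physics, or the exact
marginals of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ACCEPT, REJECT, LabelSet, QCFeatureTable, ToolRating
from .schemas import CAT12_GRADES, CAT12_MEASURES, CAT12_PREFIX, MRIQC_METRICS, MRIQC_PREFIX


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions the framework targets: 6 sites of
    300 scans (N = 1800), ~7.2% reject prevalence, 104 features of which 20
    carry a one-standard-deviation reject shift, and moderate site effects.
    """

    n_sites: int = 6
    n_per_site: int | tuple[int, ...] = 300
    reject_fraction: float | tuple[float, ...] = 0.072
    n_features: int = 104
    n_informative: int = 20
    effect_size: float = 1.0
    site_shift_sd: float = 0.5
    site_scale_range: tuple[float, float] = (0.8, 1.25)
    #: class-conditional mean of the latent quality score q in the reject class
    #: (accept scans have q ~ N(0, 1); higher q = worse quality)
    latent_reject_shift: float = 2.0
    seed: int = 0
    #: parameters of the simulated tool ratings
    rating_slope: float = 2.0
    rating_noise_sd: float = 0.8
    grade_range: tuple[float, float] = (-2.0, 4.0)
    #: scan-id prefix (vary to keep ids distinct across generated cohorts)
    id_prefix: str = "sub-"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if np.isscalar(self.n_per_site):
            self.n_per_site = (int(self.n_per_site),) * self.n_sites
        self.n_per_site = tuple(int(n) for n in self.n_per_site)
        if len(self.n_per_site) != self.n_sites or min(self.n_per_site) < 1:
            raise ValueError("n_per_site must give a positive count per site")
        if np.isscalar(self.reject_fraction):
            self.reject_fraction = (float(self.reject_fraction),) * self.n_sites
        self.reject_fraction = tuple(float(f) for f in self.reject_fraction)
        if len(self.reject_fraction) != self.n_sites or not all(
            0.0 < f < 1.0 for f in self.reject_fraction
        ):
            raise ValueError("reject_fraction must lie in (0, 1) per site")
        if not (0 <= self.n_informative <= self.n_features):
            raise ValueError("n_informative must lie in [0, n_features]")
        lo, hi = self.site_scale_range
        if not (0 < lo <= hi):
            raise ValueError("site_scale_range must be a positive interval")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be non-negative")

    @property
    def feature_names(self) -> list[str]:
        """Feature names; the merged-schema names when n_features matches 104."""
        merged = [MRIQC_PREFIX + m for m in MRIQC_METRICS] + [
            CAT12_PREFIX + m for m in CAT12_MEASURES
        ]
        if self.n_features == len(merged):
            return merged
        return [f"feat_{j:03d}" for j in range(self.n_features)]

    @property
    def informative_features(self) -> list[str]:
        """The planted class-informative set: the first n_informative features."""
        return self.feature_names[: self.n_informative]


@dataclass
class LatentQuality:
    """Latent per-scan quality score q (higher = worse quality)."""

    q: pd.Series

    @property
    def scan_ids(self) -> pd.Index:
        return self.q.index


def generate_cohort(config: SyntheticConfig) -> tuple[QCFeatureTable, LabelSet, LatentQuality]:
    """Draw a multi-site cohort with planted site effects and reject shifts.

    Per site s and feature j the accept-class distribution is
    ``Normal(mu_j + delta_sj, (sigma_j * gamma_s)^2)`` with baseline
    ``mu_j = 0, sigma_j = 1``, site offsets ``delta_sj ~ Normal(0,
    site_shift_sd^2)`` and site scales ``gamma_s ~ Uniform(site_scale_range)``.
    Labels are Bernoulli draws at the configured per-site reject prevalence;
    reject scans have the informative features shifted by ``effect_size *
    sigma_j * gamma_s`` and a latent quality score drawn from the shifted
    class-conditional. Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_names
    n_inf = config.n_informative

    site_offsets = rng.normal(0.0, config.site_shift_sd, size=(config.n_sites, config.n_features))
    site_scales = rng.uniform(*config.site_scale_range, size=config.n_sites)

    frames, label_parts, q_parts, meta_parts = [], [], [], []
    counter = 0
    for s in range(config.n_sites):
        n = config.n_per_site[s]
        ids = [f"{config.id_prefix}{counter + i:05d}" for i in range(n)]
        counter += n
        y_reject = rng.random(n) < config.reject_fraction[s]
        X = rng.standard_normal((n, config.n_features)) * site_scales[s] + site_offsets[s]
        X[y_reject, :n_inf] += config.effect_size * site_scales[s]
        q = rng.standard_normal(n)
        q[y_reject] += config.latent_reject_shift
        frames.append(pd.DataFrame(X, index=ids, columns=names))
        label_parts.append(pd.Series(np.where(y_reject, REJECT, ACCEPT), index=ids))
        q_parts.append(pd.Series(q, index=ids))
        meta_parts.append(
            pd.DataFrame(
                {
                    "site_id": f"site-{s:02d}",
                    "dataset": f"cohort-{s % 3}",
                    "manufacturer": ["Siemens", "Philips", "GE"][s % 3],
                    "field_strength": [3.0, 1.5][s % 2],
                    "diagnosis_group": ["CN", "Patient"][s % 2],
                },
                index=ids,
            )
        )

    table = QCFeatureTable(pd.concat(frames), pd.concat(meta_parts))
    labels = LabelSet(pd.concat(label_parts), provenance="visual")
    latent = LatentQuality(pd.concat(q_parts).rename("q"))
    return table, labels, latent


def simulate_tool_ratings(latent: LatentQuality, config: SyntheticConfig) -> ToolRating:
    """Simulate tool ratings monotonically coupled to the latent quality q.

    The MRIQC-style reject probability is ``logistic(slope * (q - 1) + noise)``
    and the CAT12-style grade is an ordinal binning of ``q + noise`` into the
    16-level A+..F scale with bin edges evenly spaced over ``grade_range``
    (values below/above the range clip to A+/F). Both are monotone in q in
    expectation; with ``rating_noise_sd = 0`` they are exactly monotone.
    """
    rng = np.random.default_rng(config.seed + 1)
    q = latent.q.to_numpy()
    n = len(q)

    noise_p = rng.normal(0.0, config.rating_noise_sd, size=n)
    # centre the logistic near the accept/reject latent boundary
    prob = 1.0 / (1.0 + np.exp(-(config.rating_slope * (q - 1.0) + noise_p)))

    noise_g = rng.normal(0.0, config.rating_noise_sd, size=n)
    lo, hi = config.grade_range
    edges = np.linspace(lo, hi, len(CAT12_GRADES) + 1)[1:-1]
    idx = np.searchsorted(edges, q + noise_g, side="right")
    grades = [CAT12_GRADES[i] for i in idx]

    return ToolRating(
        pd.DataFrame(
            {"mriqc_probability": prob, "cat12_grade": grades}, index=latent.scan_ids
        )
    )
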