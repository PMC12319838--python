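"""Default feature schemas for the two upstream QC tools and the CAT12 grade scale.

MRIQC emits per-scan image quality metrics (IQMs) for T1w images; the default
schema below is the standard anatomical IQM set (68 metrics), including image
size and spacing fields. CAT12's segmentation pipeline stores 36 scalar quality
measures per scan (noise/inhomogeneity/resolution ratings plus surface and
tissue measures); the default schema reconstructs that set from the documented
measure families. Both schemas are configurable at read time.
"""

from __future__ import annotations

_SUMMARY_STATS = ("k", "mad", "mean", "median", "n", "p05", "p95", "stdv")
_TISSUES = ("bg", "csf", "gm", "wm")

#: Default MRIQC T1w IQM schema (68 metrics).
MRIQC_METRICS: tuple[str, ...] = tuple(
    [
        "cjv",
        "cnr",
        "efc",
        "fber",
        "fwhm_avg",
        "fwhm_x",
        "fwhm_y",
        "fwhm_z",
        "icvs_csf",
        "icvs_gm",
        "icvs_wm",
        "inu_med",
        "inu_range",
        "qi_1",
        "qi_2",
        "rpve_csf",
        "rpve_gm",
        "rpve_wm",
        "size_x",
        "size_y",
        "size_z",
        "snr_csf",
        "snr_gm",
        "snr_total",
        "snr_wm",
        "snrd_csf",
        "snrd_gm",
        "snrd_total",
        "snrd_wm",
        "spacing_x",
        "spacing_y",
        "spacing_z",
    ]
    + [f"summary_{t}_{s}" for t in _TISSUES for s in _SUMMARY_STATS]
    + [
        "tpm_overlap_csf",
        "tpm_overlap_gm",
        "tpm_overlap_wm",
        "wm2max",
    ]
)

#: Default CAT12 quality-measure schema (36 scalars).
CAT12_MEASURES: tuple[str, ...] = tuple(
    [
        "NCR",
        "ICR",
        "res_RMS",
        "IQR",
        "surf_euler",
        "surf_defect_number",
        "surf_defect_area",
        "surf_intensity_rmse",
        "surf_position_rmse",
    ]
    + [
        f"tissue_{kind}_{stat}_{t}"
        for kind in ("abs", "rel")
        for stat in ("mean", "std")
        for t in ("CSF", "GM", "WM", "BG")
    ]
    + [
        "contrast_abs",
        "contrast_rel",
        "vol_abs_CSF",
        "vol_abs_GM",
        "vol_abs_WM",
        "vol_abs_WMH",
        "vol_rel_CSF",
        "vol_rel_GM",
        "vol_rel_WM",
        "vol_rel_WMH",
        "vol_TIV",
    ]
)

assert len(MRIQC_METRICS) == 68
assert len(CAT12_MEASURES) == 36

#: CAT12 weighted-IQR letter grades, best (A+) to worst (F).
CAT12_GRADES: tuple[str, ...] = (
    "A+", "A", "A-",
    "B+", "B", "B-",
    "C+", "C", "C-",
    "D+", "D", "D-",
    "E+", "E", "E-",
    "F",
)

#: Map from grade letter to ordinal index (0 = A+, 15 = F).
GRADE_INDEX: dict[str, int] = {g: i for i, g in enumerate(CAT12_GRADES)}


def canonical_grade(grade: str) -> str:
    """Normalise a CAT12 grade string (accepts unicode minus) to the ASCII scale."""
    g = str(grade).strip().replace("−", "-").replace("–", "-")
    if g not in GRADE_INDEX:
        raise ValueError(f"unknown CAT12 grade {grade!r}; expected one of {CAT12_GRADES}")
    return g


#: Source prefixes applied when MRIQC and CAT12 tables are merged.
MRIQC_PREFIX = "mriqc_"
CAT12_PREFIX = "cat12_"
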