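"""Reading, validation, merging, and persistence of QC feature tables.

The central container is :class:`QCFeatureTable`: a per-scan numeric feature
matrix (MRIQC IQMs, CAT12 quality measures, or their merged union) together
with scan metadata (site, dataset, scanner manufacturer, field strength,
diagnosis group). Binary accept/reject labels live in :class:`LabelSet`, and
the two tools' own quality ratings (MRIQC classifier probability, CAT12
weighted-IQR letter grade) in :class:`ToolRating`.

All tables serialise to plain TSV/CSV (UTF-8, '.' decimal separator); floats
are written at full precision so a write/read round-trip is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import (
    CAT12_MEASURES,
    CAT12_PREFIX,
    GRADE_INDEX,
    MRIQC_METRICS,
    MRIQC_PREFIX,
    canonical_grade,
)

logger = logging.getLogger(__name__)

#: Metadata columns recognised on a feature table, in canonical order.
META_COLUMNS = ("site_id", "dataset", "manufacturer", "field_strength", "diagnosis_group")

MANUFACTURERS = ("Siemens", "Philips", "GE", "other")

ACCEPT = "accept"
REJECT = "reject"
LABEL_PROVENANCES = ("visual", "mriqc", "cat12", "predicted")


class QCSchemaError(ValueError):
    """Input table does not match the expected metric schema."""


class DuplicateScanIDError(ValueError):
    """A scan identifier occurs more than once."""


class EmptyIntersectionError(ValueError):
    """No scan identifiers shared between the tables being merged."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class QCFeatureTable:
    """Per-scan numeric feature matrix with scan metadata.

    Both frames are indexed by ``scan_id`` (unique strings). ``meta`` may be
    empty (e.g. for a raw single-tool table before the metadata join); when
    present it carries a subset of :data:`META_COLUMNS`.
    """

    features: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.features.index)
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise DuplicateScanIDError(f"duplicate scan_id values: {dupes}")
        if not self.features.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.features.index)
        if not self.features.columns.is_unique:
            raise QCSchemaError("feature names must be unique")
        self.features.index.name = "scan_id"
        self.meta.index.name = "scan_id"

    # -- basic accessors -----------------------------------------------------

    @property
    def scan_ids(self) -> pd.Index:
        return self.features.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_scans(self) -> int:
        return len(self.features)

    @property
    def sites(self) -> pd.Series:
        if "site_id" not in self.meta.columns:
            raise KeyError("table has no site_id metadata")
        return self.meta["site_id"]

    def subset(self, scan_ids) -> "QCFeatureTable":
        ids = pd.Index(scan_ids)
        missing = ids.difference(self.features.index)
        if len(missing):
            raise KeyError(f"unknown scan_id values: {missing.tolist()[:5]}")
        return QCFeatureTable(self.features.loc[ids].copy(), self.meta.loc[ids].copy())

    def copy(self) -> "QCFeatureTable":
        return QCFeatureTable(self.features.copy(), self.meta.copy())

    # -- persistence ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Single wide frame: metadata columns first, then features."""
        return pd.concat([self.meta, self.features], axis=1)

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        # repr gives the shortest round-tripping decimal for each float
        self.to_frame().to_csv(
            path, sep=sep, index=True, encoding="utf-8", float_format=lambda v: repr(float(v))
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QCFeatureTable":
        meta_cols = [c for c in META_COLUMNS if c in frame.columns]
        feat_cols = [c for c in frame.columns if c not in META_COLUMNS]
        return cls(frame[feat_cols], frame[meta_cols])

    @classmethod
    def read(cls, path) -> "QCFeatureTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col="scan_id", encoding="utf-8", float_precision="round_trip")
        frame.index = frame.index.astype(str)
        return cls.from_frame(frame)


@dataclass
class LabelSet:
    """Binary accept/reject labels with provenance.

    ``labels`` is a Series indexed by ``scan_id`` with values 'accept' or
    'reject'; ``provenance`` records where the ratings came from (visual QC,
    a tool's thresholded rating, or a classifier prediction).
    """

    labels: pd.Series
    provenance: str = "visual"

    def __post_init__(self) -> None:
        if self.provenance not in LABEL_PROVENANCES:
            raise ValueError(
                f"provenance {self.provenance!r} not in {LABEL_PROVENANCES}"
            )
        self.labels = self.labels.astype(str)
        bad = set(self.labels.unique()) - {ACCEPT, REJECT}
        if bad:
            raise ValueError(f"labels must be accept/reject; found {sorted(bad)}")
        if not self.labels.index.is_unique:
            raise DuplicateScanIDError("duplicate scan_id in label set")
        self.labels.index.name = "scan_id"
        self.labels.name = "label"

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def scan_ids(self) -> pd.Index:
        return self.labels.index

    def subset(self, scan_ids) -> "LabelSet":
        return LabelSet(self.labels.loc[pd.Index(scan_ids)].copy(), self.provenance)

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {ACCEPT: int(vc.get(ACCEPT, 0)), REJECT: int(vc.get(REJECT, 0))}

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.to_frame()
        out["provenance"] = self.provenance
        return out

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.to_frame().to_csv(path, sep=sep, index=True, encoding="utf-8")

    @classmethod
    def read(cls, path) -> "LabelSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col="scan_id", encoding="utf-8", float_precision="round_trip")
        frame.index = frame.index.astype(str)
        prov = frame["provenance"].iloc[0] if "provenance" in frame.columns and len(frame) else "visual"
        return cls(frame["label"], str(prov))


@dataclass
class ToolRating:
    """Per-scan tool quality ratings.

    ``mriqc_probability`` is the MRIQC classifier's reject probability in
    [0, 1] (NaN when missing); ``cat12_grade`` the CAT12 weighted-IQR letter
    grade on the 16-level A+..F scale (NaN when missing).
    """

    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ratings.index.is_unique:
            raise DuplicateScanIDError("duplicate scan_id in tool ratings")
        self.ratings.index.name = "scan_id"
        for col in ("mriqc_probability", "cat12_grade"):
            if col not in self.ratings.columns:
                self.ratings[col] = np.nan
        prob = pd.to_numeric(self.ratings["mriqc_probability"], errors="coerce")
        out_of_range = prob.dropna()
        if ((out_of_range < 0) | (out_of_range > 1)).any():
            raise ValueError("mriqc_probability must lie in [0, 1]")
        self.ratings["mriqc_probability"] = prob
        grades = self.ratings["cat12_grade"]
        self.ratings["cat12_grade"] = [
            canonical_grade(g) if isinstance(g, str) else np.nan for g in grades
        ]

    @property
    def scan_ids(self) -> pd.Index:
        return self.ratings.index

    @property
    def mriqc_probability(self) -> pd.Series:
        return self.ratings["mriqc_probability"]

    @property
    def cat12_grade(self) -> pd.Series:
        return self.ratings["cat12_grade"]

    @property
    def grade_index(self) -> pd.Series:
        """Ordinal grade index (0 = A+ .. 15 = F); NaN where missing."""
        return self.ratings["cat12_grade"].map(GRADE_INDEX)

    def subset(self, scan_ids) -> "ToolRating":
        return ToolRating(self.ratings.loc[pd.Index(scan_ids)].copy())

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.ratings.to_csv(
            path, sep=sep, index=True, encoding="utf-8", float_format=lambda v: repr(float(v))
        )

    @classmethod
    def read(cls, path) -> "ToolRating":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col="scan_id", encoding="utf-8", float_precision="round_trip")
        frame.index = frame.index.astype(str)
        return cls(frame)


# ---------------------------------------------------------------------------
# readers


_ID_CANDIDATES = ("scan_id", "bids_name", "subject_id", "id")


def _read_tabular(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise QCSchemaError(f"empty input file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, encoding="utf-8", float_precision="round_trip")
    if frame.empty:
        raise QCSchemaError(f"no data rows in {path}")
    id_col = next((c for c in _ID_CANDIDATES if c in frame.columns), frame.columns[0])
    frame[id_col] = frame[id_col].astype(str)
    if frame[id_col].duplicated().any():
        dupes = frame.loc[frame[id_col].duplicated(), id_col].unique().tolist()
        raise DuplicateScanIDError(f"duplicate scan_id values in {path}: {dupes}")
    return frame.set_index(id_col)


def _read_json_dir(path: Path) -> pd.DataFrame:
    """Directory of per-scan MRIQC IQM JSON files -> one row per file."""
    rows = {}
    for jf in sorted(path.glob("*.json")):
        with open(jf, encoding="utf-8") as fh:
            payload = json.load(fh)
        scan_id = str(payload.get("bids_name", jf.stem))
        if scan_id in rows:
            raise DuplicateScanIDError(f"duplicate scan_id {scan_id!r} in {path}")
        rows[scan_id] = {k: v for k, v in payload.items() if np.isscalar(v)}
    if not rows:
        raise QCSchemaError(f"no JSON files with IQMs found in {path}")
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "scan_id"
    return frame


def _to_feature_table(frame: pd.DataFrame, schema, source: str) -> QCFeatureTable:
    schema = list(schema)
    missing = [c for c in schema if c not in frame.columns]
    if len(missing) == len(schema):
        raise QCSchemaError(f"no recognised {source} metric columns in input")
    if missing:
        raise QCSchemaError(f"{source} schema mismatch; missing columns: {missing}")
    extra = [c for c in frame.columns if c not in schema]
    if extra:
        logger.warning("%s table: ignoring %d extra column(s): %s", source, len(extra), extra[:10])
    feats = frame[schema].apply(pd.to_numeric, errors="coerce")
    feats = feats.replace([np.inf, -np.inf], np.nan)
    bad = feats.isna().any(axis=1)
    if bad.any():
        for sid in feats.index[bad]:
            cols = feats.columns[feats.loc[sid].isna()].tolist()
            logger.warning("%s table: excluding scan %s (non-finite values in %s)", source, sid, cols[:5])
    feats = feats.loc[~bad].astype(float)
    if feats.empty:
        raise QCSchemaError(f"all rows of the {source} table failed numeric validation")
    return QCFeatureTable(feats)


def read_mriqc_table(path, schema=MRIQC_METRICS) -> QCFeatureTable:
    """Read an MRIQC IQM table (group TSV/CSV, or a directory of per-scan JSONs).

    Returns a table with exactly the configured metric schema (68 metrics by
    default). Extra columns are ignored with a warning; rows containing
    non-numeric or non-finite entries are excluded and logged.
    """
    path = Path(path)
    frame = _read_json_dir(path) if path.is_dir() else _read_tabular(path)
    return _to_feature_table(frame, schema, "MRIQC")


def read_cat12_table(path, schema=CAT12_MEASURES) -> QCFeatureTable:
    """Read a CAT12 quality-measure table (flattened CSV/TSV export, one row per scan).

    CAT12 stores its per-scan quality scalars inside the segmentation output;
    this reader consumes a tabular export of those 36 measures rather than the
    proprietary container.
    """
    frame = _read_tabular(Path(path))
    return _to_feature_table(frame, schema, "CAT12")


def read_metadata(path) -> pd.DataFrame:
    """Read a scan metadata table (scan_id + site/dataset/manufacturer/... columns)."""
    frame = _read_tabular(Path(path))
    keep = [c for c in META_COLUMNS if c in frame.columns]
    if not keep:
        raise QCSchemaError(f"metadata table has none of the expected columns {META_COLUMNS}")
    return frame[keep]


# ---------------------------------------------------------------------------
# merge


def merge_tables(
    mriqc: QCFeatureTable,
    cat12: QCFeatureTable,
    meta: pd.DataFrame | None = None,
    labels: LabelSet | None = None,
) -> QCFeatureTable:
    """Inner-join MRIQC and CAT12 tables (and metadata/labels) on scan_id.

    Feature columns are prefixed by source (``mriqc_*`` / ``cat12_*``); with
    the default schemas the merged table has 68 + 36 = 104 features. Only
    scans present in every provided input are retained; the join cardinality
    is logged. Merging is order-independent up to documented column order
    (MRIQC features first, then CAT12).
    """
    ids = mriqc.scan_ids.intersection(cat12.scan_ids)
    if meta is not None:
        ids = ids.intersection(meta.index)
    if labels is not None:
        ids = ids.intersection(labels.scan_ids)
    if len(ids) == 0:
        raise EmptyIntersectionError("no scan_id shared between the inputs")
    ids = ids.sort_values()
    n_in = max(mriqc.n_scans, cat12.n_scans)
    if len(ids) < n_in:
        logger.warning(
            "merge: retaining %d of %d scans (dropped scans missing from some input)",
            len(ids), n_in,
        )
    logger.info(
        "merge: mriqc=%d cat12=%d meta=%s labels=%s -> merged=%d",
        mriqc.n_scans, cat12.n_scans,
        "-" if meta is None else len(meta),
        "-" if labels is None else len(labels),
        len(ids),
    )
    left = mriqc.features.loc[ids].add_prefix(MRIQC_PREFIX)
    right = cat12.features.loc[ids].add_prefix(CAT12_PREFIX)
    merged_meta = pd.DataFrame(index=ids)
    if meta is not None:
        if meta.index.has_duplicates:
            conflicting = meta[meta.index.duplicated(keep=False)]
            if not all(
                len(grp.drop_duplicates()) == 1 for _, grp in conflicting.groupby(level=0)
            ):
                raise ValueError("conflicting metadata rows for the same scan_id")
            meta = meta[~meta.index.duplicated()]
        merged_meta = meta.loc[ids, [c for c in META_COLUMNS if c in meta.columns]].copy()
    return QCFeatureTable(pd.concat([left, right], axis=1), merged_meta)
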