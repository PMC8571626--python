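"""Core data model and readers/writers for feature tables, taxonomy and sample metadata.

Feature tables are feature × sample abundance matrices (counts or relative
abundances) carried as pandas DataFrames.  Two on-disk formats are supported:
a tab-separated layout whose first header cell is ``#FeatureID``, and BIOM
1.0 JSON (dense or sparse).  Sample metadata encodes the factorial design of
a pulse-perturbation mesocosm study: morphological niche, treatment,
timepoint, experimental patch, replicate and (optionally) sequencing run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NICHES",
    "TREATMENTS",
    "TIMEPOINTS",
    "TIMEPOINT_DAYS",
    "FeatureTable",
    "TaxonomyMap",
    "SampleMetadata",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
]

#: Closed factor levels for the mesocosm design.
NICHES = ("endo", "epi", "rhizo", "sediment", "water")
TREATMENTS = ("control", "nutrient", "temperature", "combination")
TIMEPOINTS = ("T0", "T1", "T2")
#: Sampling days: before the pulse, directly after the 3-day pulse, after recovery.
TIMEPOINT_DAYS = {"T0": 0, "T1": 3, "T2": 12}

_REL_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


class ValidationError(ValueError):
    """Raised when values violate the data model (bad enum level, negative count...)."""


@dataclass
class FeatureTable:
    """A non-negative feature × sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.  Both axes must carry unique
        string labels; all entries must be non-negative and finite.
    scale : {"counts", "relative"}
        ``relative`` requires every sample column to sum to 1 (±1e-9).
    axis_kind : {"taxonomic", "functional"}
        Whether features are taxa (OTUs) or functional categories (e.g. KOs).
    """

    data: pd.DataFrame
    scale: str = "counts"
    axis_kind: str = "taxonomic"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "relative"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.axis_kind not in ("taxonomic", "functional"):
            raise ValidationError(f"unknown axis_kind {self.axis_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("non-finite entries in feature table")
        if values.size and values.min() < 0:
            raise ValidationError("negative entries in feature table")
        if self.scale == "relative" and self.data.shape[1]:
            sums = values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > _REL_TOL):
                bad = [
                    str(s)
                    for s, t in zip(self.data.columns, sums)
                    if abs(t - 1.0) > _REL_TOL
                ]
                raise ValidationError(
                    f"relative-scale columns must sum to 1: {bad[:5]}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Subset to the given samples, preserving feature order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(),
                            scale=self.scale, axis_kind=self.axis_kind)

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        return FeatureTable(self.data.loc[list(feature_ids), :].copy(),
                            scale=self.scale, axis_kind=self.axis_kind)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), scale=self.scale, axis_kind=self.axis_kind)

    def equals(self, other: "FeatureTable", tol: float = 0.0) -> bool:
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        if self.scale != other.scale:
            return False
        if tol == 0.0:
            return bool(np.array_equal(self.values, other.values))
        return bool(np.allclose(self.values, other.values, atol=tol, rtol=0.0))


@dataclass
class TaxonomyMap:
    """feature_id → ordered lineage (domain ... genus), optional per-rank confidence.

    Empty strings are allowed at any rank (partially unclassified lineages).
    """

    lineages: dict[str, tuple[str, ...]]
    confidence: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.confidence is not None:
            for fid, conf in self.confidence.items():
                if fid not in self.lineages:
                    raise ValidationError(f"confidence for unknown feature {fid!r}")
                if any(not (0.0 <= c <= 1.0) for c in conf):
                    raise ValidationError(f"confidence outside [0, 1] for {fid!r}")

    def lineage_string(self, feature_id: str, sep: str = ";") -> str:
        return sep.join(self.lineages.get(feature_id, ()))

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample design factors, indexed by sample_id.

    Columns: niche, treatment, timepoint, experiment, replicate, run (optional,
    may be missing).  Enum columns are validated against the closed level sets;
    matching is case-insensitive on read and values are stored normalised
    (lower-case niches/treatments, upper-case timepoints).
    """

    frame: pd.DataFrame

    _ENUMS = {
        "niche": NICHES,
        "treatment": TREATMENTS,
        "timepoint": TIMEPOINTS,
    }
    _REQUIRED = ("niche", "treatment", "timepoint", "experiment", "replicate")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        missing = [c for c in self._REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"missing metadata columns: {missing}")
        frame = self.frame.copy()
        for col, levels in self._ENUMS.items():
            lookup = {lv.lower(): lv for lv in levels}
            normed = []
            for sample_id, raw in frame[col].items():
                key = str(raw).strip().lower()
                if key not in lookup:
                    raise ValidationError(
                        f"sample {sample_id!r}: unknown {col} level {raw!r} "
                        f"(expected one of {list(levels)})"
                    )
                normed.append(lookup[key])
            frame[col] = normed
        if "run" not in frame.columns:
            frame["run"] = pd.Series(pd.NA, index=frame.index, dtype="string")
        else:
            frame["run"] = frame["run"].astype("string")
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def samples_where(self, **factors: str) -> list[str]:
        """Sample ids matching every given factor=value condition."""
        mask = pd.Series(True, index=self.frame.index)
        for col, value in factors.items():
            mask &= self.frame[col] == value
        return [str(i) for i in self.frame.index[mask]]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = "#FeatureID"


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".biom", ".json"):
        return "biom_json"
    return "tsv"


def read_feature_table(path: str | Path, format: str | None = None,
                       axis_kind: str = "taxonomic") -> FeatureTable:
    """Read a feature table from TSV or BIOM 1.0 JSON.

    The returned table has ``scale="counts"`` and preserves the file's feature
    and sample ordering.  Duplicate ids, negative values and non-numeric cells
    raise :class:`FormatError`.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = _read_table_tsv(path)
    elif fmt == "biom_json":
        df = _read_table_biom(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        return FeatureTable(df, scale="counts", axis_kind=axis_kind)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_table_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                         comment=None, header=0)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if len(df):  # zero-feature tables have no cells to type-check
        non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c])
                                  for c in df.columns]]
        if len(non_numeric):
            raise FormatError(
                f"{path}: non-numeric cells in columns {list(non_numeric)[:5]}")
    return df.astype(float)


def _read_table_biom(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "shape", "matrix_type", "data"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM JSON missing key {key!r}")
    n_rows, n_cols = doc["shape"]
    row_ids = [str(r["id"]) for r in doc["rows"]]
    col_ids = [str(c["id"]) for c in doc["columns"]]
    if len(row_ids) != n_rows or len(col_ids) != n_cols:
        raise FormatError(f"{path}: BIOM shape inconsistent with row/column lists")
    mat = np.zeros((n_rows, n_cols), dtype=float)
    if doc["matrix_type"] == "dense":
        data = np.asarray(doc["data"], dtype=float)
        if data.shape != (n_rows, n_cols):
            raise FormatError(f"{path}: dense data shape {data.shape} != {doc['shape']}")
        mat[:] = data
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = float(v)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return pd.DataFrame(mat, index=row_ids, columns=col_ids)


def write_feature_table(table: FeatureTable, path: str | Path,
                        format: str | None = None) -> None:
    """Write a feature table as TSV (header ``#FeatureID``) or BIOM 1.0 JSON."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = table.data.copy()
        df.index.name = _TSV_HEADER
        df.to_csv(path, sep="\t", lineterminator="\n")
    elif fmt == "biom_json":
        _write_table_biom(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_table_biom(table: FeatureTable, path: Path) -> None:
    values = table.values
    rows_nz, cols_nz = np.nonzero(values)
    data = [[int(i), int(j), float(values[i, j])] for i, j in zip(rows_nz, cols_nz)]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org/documentation/format_versions/biom-1.0.html",
        "type": "OTU table" if table.axis_kind == "taxonomic" else "Function table",
        "generated_by": "microstab",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [table.n_features, table.n_samples],
        "rows": [{"id": fid, "metadata": None} for fid in table.feature_ids],
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Metadata and taxonomy I/O
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata from a TSV with columns sample_id, niche, treatment,
    timepoint, experiment, replicate and optionally run."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns feature_id, lineage and optionally
    confidence; lineage ranks (and confidences) are semicolon-separated."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("feature_id", "lineage"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups[:5]}")
    lineages = {
        str(fid): tuple(rank.strip() for rank in str(lin).split(";"))
        for fid, lin in zip(df["feature_id"], df["lineage"])
    }
    confidence = None
    if "confidence" in df.columns:
        confidence = {}
        for fid, conf in zip(df["feature_id"], df["confidence"]):
            conf = str(conf).strip()
            if conf:
                confidence[str(fid)] = tuple(float(c) for c in conf.split(";"))
    return TaxonomyMap(lineages=lineages, confidence=confidence)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    rows = []
    for fid, lineage in taxonomy.lineages.items():
        row = {"feature_id": fid, "lineage": ";".join(lineage)}
        if taxonomy.confidence and fid in taxonomy.confidence:
            row["confidence"] = ";".join(f"{c:g}" for c in taxonomy.confidence[fid])
        rows.append(row)
    cols = ["feature_id", "lineage"]
    if taxonomy.confidence:
        cols.append("confidence")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")
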