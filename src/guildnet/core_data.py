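"""Data model, readers/writers, filtering, and compositional transforms.

The central object is :class:`OtuTable`, a samples x OTUs matrix of
non-negative integer counts with unique string identifiers on both axes.
All downstream stages (network inference, guild abundance, classification)
consume either raw counts, relative abundances, or the centered log-ratio
(CLR) transform produced here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "FilterSpec",
    "ValidationError",
    "ParseError",
    "EmptyFeatureSetError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "filter_samples_by_depth",
    "filter_otus",
    "relative_abundance",
    "clr_transform",
    "rarefy",
]


class ValidationError(ValueError):
    """Raised when a table or metadata object violates its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


class EmptyFeatureSetError(ValueError):
    """Raised when filtering removes every OTU."""


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs count matrix with identifiers.

    Parameters
    ----------
    sample_ids : sequence of str
        Row identifiers, unique and ordered.
    otu_ids : sequence of str
        Column identifiers, unique and ordered.
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer counts.
    taxonomy : mapping otu_id -> lineage string, optional
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (samples x OTUs)")
        if counts.size and not np.issubdtype(counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if counts.size and np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if counts.size and not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    def select_samples(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            tuple(self.sample_ids[i] for i in keep),
            self.otu_ids,
            self.counts[keep, :],
            self.taxonomy,
        )

    def select_otus(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        otu_ids = tuple(self.otu_ids[j] for j in keep)
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.sample_ids, otu_ids, self.counts[:, keep], taxonomy)


@dataclass(frozen=True)
class SampleMetadata:
    """Clinical/cohort annotation for a single sample."""

    sample_id: str
    condition: str  # "case" or "control"
    cohort: str = "default"
    timepoint: str | None = None
    outcomes: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("case", "control"):
            raise ValidationError(
                f"condition must be 'case' or 'control', got {self.condition!r}"
            )


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for OTU-level filtering.

    An OTU is removed when its prevalence (fraction of samples with a
    strictly positive count) is below ``min_prevalence`` OR its mean
    relative abundance is below ``min_mean_rel_abundance``.  Both
    comparisons are strict, matching the printed exclusion rules.
    """

    min_depth: int = 10_000
    min_prevalence: float = 0.10
    min_mean_rel_abundance: float = 0.00005

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_prevalence < 0 or self.min_mean_rel_abundance < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if self.min_prevalence > 1:
            raise ValidationError("min_prevalence must be <= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(
    path: str | Path,
    format: str = "tsv_wide",
    orientation: str = "auto",
    sample_ids: Iterable[str] | None = None,
) -> OtuTable:
    """Read an OTU table from disk.

    Parameters
    ----------
    format : {"tsv_wide", "biom_json"}
        ``tsv_wide``: header row of sample ids, first column of OTU ids
        (the common wide export; rows are OTUs).  ``biom_json``: BIOM
        format version 1.0 (JSON dialect).
    orientation : {"auto", "otus_as_rows", "samples_as_rows"}
        For TSV input.  ``auto`` assumes OTUs as rows unless the known
        ``sample_ids`` overlap the first column better than the header.
    sample_ids : iterable of str, optional
        Known sample identifiers used by orientation auto-detection.
    """
    path = Path(path)
    if format == "tsv_wide":
        return _read_tsv_wide(path, orientation, sample_ids)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv_wide(
    path: Path, orientation: str, sample_ids: Iterable[str] | None
) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty data section")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate column id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except Exception as exc:
        raise ParseError(f"{path}: non-numeric entry in data section: {exc}") from exc

    rows_are_otus = True
    if orientation == "samples_as_rows":
        rows_are_otus = False
    elif orientation == "auto" and sample_ids is not None:
        known = set(map(str, sample_ids))
        row_overlap = len(known & set(df.index))
        col_overlap = len(known & set(df.columns))
        if row_overlap > col_overlap:
            rows_are_otus = False
    elif orientation not in ("auto", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if rows_are_otus:
        return OtuTable(tuple(df.columns), tuple(df.index), values.T)
    return OtuTable(tuple(df.index), tuple(df.columns), values)


def _read_biom_json(path: Path) -> OtuTable:
    # BIOM 1.0 is plain JSON; the reference parser adds nothing we need here.
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise ParseError(f"{path}: missing required BIOM field {key!r}")
    n_rows, n_cols = doc["shape"]
    otu_ids = tuple(str(r["id"]) for r in doc["rows"])
    sids = tuple(str(c["id"]) for c in doc["columns"])
    if len(otu_ids) != n_rows or len(sids) != n_cols:
        raise ParseError(f"{path}: shape does not match rows/columns lists")
    dense = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, v = entry
            dense[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        dense = np.asarray(doc["data"], dtype=float)
    else:
        raise ParseError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is not None:
            taxonomy[str(r["id"])] = ";".join(tax) if isinstance(tax, list) else str(tax)
    # BIOM rows are observations (OTUs): transpose to samples x OTUs.
    return OtuTable(sids, otu_ids, dense.T, taxonomy or None)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table as wide TSV (rows = OTUs, columns = samples)."""
    df = pd.DataFrame(
        table.counts.T, index=list(table.otu_ids), columns=list(table.sample_ids)
    )
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV with columns sample_id, condition, cohort, timepoint."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    outcome_cols = [
        c for c in df.columns if c not in ("sample_id", "condition", "cohort", "timepoint")
    ]
    records = []
    for _, row in df.iterrows():
        outcomes = None
        if outcome_cols:
            outcomes = {
                c: float(row[c]) for c in outcome_cols if pd.notna(row[c])
            } or None
        tp = row.get("timepoint")
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                cohort=str(row.get("cohort", "default") or "default"),
                timepoint=None if pd.isna(tp) else str(tp),
                outcomes=outcomes,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id in metadata")
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "condition": r.condition,
            "cohort": r.cohort,
            "timepoint": r.timepoint if r.timepoint is not None else "",
        }
        if r.outcomes:
            row.update(r.outcomes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_samples_by_depth(table: OtuTable, min_depth: int = 10_000) -> OtuTable:
    """Remove samples whose total read count is strictly below ``min_depth``."""
    keep = [i for i, d in enumerate(table.depths()) if d >= min_depth]
    return table.select_samples(keep)


def filter_otus(table: OtuTable, spec: FilterSpec | None = None) -> OtuTable:
    """Remove low-prevalence / low-abundance OTUs.

    An OTU is dropped iff prevalence < ``spec.min_prevalence`` (strict) or
    mean per-sample relative abundance < ``spec.min_mean_rel_abundance``
    (strict).  Column order of survivors is preserved.
    """
    if spec is None:
        spec = FilterSpec()
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValidationError("cannot filter an empty table")
    prevalence = (table.counts > 0).mean(axis=0)
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=0)
    keep = [
        j
        for j in range(table.n_otus)
        if prevalence[j] >= spec.min_prevalence
        and mean_rel[j] >= spec.min_mean_rel_abundance
    ]
    if not keep:
        raise EmptyFeatureSetError("all OTUs removed by filter")
    return table.select_otus(keep)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample relative abundances; each row sums to 1."""
    depths = table.depths()
    zero = np.nonzero(depths == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero-depth sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    return table.counts / depths[:, None]


def clr_transform(table: OtuTable, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of counts + pseudocount.

    For each sample, ``clr_i = ln(x_i + d) - mean_j ln(x_j + d)``.  Rows of
    the result sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(table.counts + pseudocount)
    return logged - logged.mean(axis=1, keepdims=True)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to a common depth.

    Off by default in the analysis pipeline; provided because upstream
    processing pipelines commonly rarefy before normalisation.  Samples
    below the target depth are dropped with a warning.
    """
    depths = table.depths()
    if depth is None:
        depth = int(depths.min())
    rng = np.random.default_rng(seed)
    keep_rows = []
    new_counts = []
    for i in range(table.n_samples):
        if depths[i] < depth:
            warnings.warn(
                f"sample {table.sample_ids[i]} dropped: depth {depths[i]} < {depth}"
            )
            continue
        row = table.counts[i]
        drawn = rng.multivariate_hypergeometric(row, depth)
        keep_rows.append(i)
        new_counts.append(drawn)
    return OtuTable(
        tuple(table.sample_ids[i] for i in keep_rows),
        table.otu_ids,
        np.array(new_counts, dtype=np.int64).reshape(len(keep_rows), table.n_otus),
        table.taxonomy,
    )
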