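"""Core tabular types shared by every stage of the pipeline.

The study design is a longitudinal single-subject comparison of two omic
layers over a shared ORF namespace: metagenomic gene abundances in counts
per million (CPM) and TMT-metaproteomic protein abundances as normalized
summed signal-to-noise ratios.  Samples are (collection date, technical
replicate) pairs; downstream statistics operate on date-collapsed tables.

Conventions
-----------
* A :class:`FeatureTable` stores abundances as a features x samples
  ``pandas.DataFrame`` of floats; ``NaN`` marks a missing (unquantified)
  cell.  Gene-layer absences become explicit zeros during CPM
  normalization; protein-layer absences stay missing and are excluded
  from means and correlations.
* All TSV files are tab-separated, UTF-8, header row, feature identifiers
  in the first column, ``NA`` for missing cells.
* Dates are ISO-8601 strings and sample ordering is chronological.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

#: Ordered taxonomic ranks used in lineage annotations.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Canonical immune biomarker names tracked in the study.
BIOMARKERS = ("calprotectin", "CRP", "lysozyme", "lactoferrin", "S-IgA")

#: Missing-value token in all TSV files.
NA_TOKEN = "NA"

Layer = Literal["gene", "protein"]


class DataModelError(ValueError):
    """Raised when a table violates a structural invariant."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Features x samples abundance matrix for one omic layer.

    Parameters
    ----------
    values
        Float matrix indexed by feature id with sample ids as columns.
        ``NaN`` encodes a missing cell.
    layer
        ``"gene"`` (counts per million) or ``"protein"`` (normalized summed
        signal-to-noise, dimensionless).
    """

    values: pd.DataFrame
    layer: Layer

    def __post_init__(self) -> None:
        if self.layer not in ("gene", "protein"):
            raise DataModelError(f"unknown layer {self.layer!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataModelError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataModelError(f"duplicate sample id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise DataModelError("abundances must be nonnegative where present")

    # -- basic accessors ----------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean matrix, ``True`` where a value is present."""
        return self.values.notna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.layer)

    # -- I/O ----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", na_rep=NA_TOKEN)

    @classmethod
    def read_tsv(cls, path, layer: Layer) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                         keep_default_na=False)
        df.index.name = None
        return cls(df, layer)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample collection date, replicate index and inflammation state.

    ``table`` columns: ``sample_id``, ``date`` (ISO-8601), ``replicate``
    (1..3), ``inflammation`` (``high``/``low``/``unknown``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "date", "replicate", "inflammation"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataModelError(f"metadata missing columns {sorted(missing)}")
        pairs = self.table[["date", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DataModelError("duplicate (date, replicate) pair in metadata")
        bad = set(self.table["inflammation"]) - {"high", "low", "unknown"}
        if bad:
            raise DataModelError(f"unknown inflammation states {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def dates(self) -> list[str]:
        return sorted(set(self.table["date"]))

    def date_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["date"]))

    def inflammation_by_date(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for _, row in self.table.iterrows():
            out.setdefault(row["date"], row["inflammation"])
        return out

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", na_values=[NA_TOKEN],
                               keep_default_na=False))


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Feature -> taxonomy / function / Gram-stain annotation map.

    ``table`` is indexed by feature id with columns for each rank in
    :data:`RANKS` (empty string = unassigned), ``go_terms`` (semicolon
    joined), ``ko``, ``eggnog`` and ``gram``
    (``positive``/``negative``/``unknown``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(RANKS) + ["go_terms", "ko", "eggnog", "gram"]
        for c in cols:
            if c not in self.table.columns:
                self.table[c] = ""
        self.table = self.table[cols].fillna("").astype(str)
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataModelError(f"duplicate annotation for feature {dup!r}")
        self.table.loc[self.table["gram"] == "", "gram"] = "unknown"
        bad = set(self.table["gram"]) - {"positive", "negative", "unknown"}
        if bad:
            raise DataModelError(f"unknown gram values {sorted(bad)}")
        # no rank may be present below an absent rank
        ranks = self.table[list(RANKS)].to_numpy()
        present = ranks != ""
        for i in range(len(self.table)):
            row = present[i]
            if row.any():
                last = np.max(np.nonzero(row))
                if not row[: last + 1].all():
                    fid = self.table.index[i]
                    raise DataModelError(
                        f"feature {fid!r}: rank present below an absent rank")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        row = self.table.loc[feature_id, list(RANKS)]
        return tuple(v for v in row if v != "")

    def category_map(self, level: str) -> dict[str, tuple[str, ...]]:
        """Feature -> categories at a level (GO may be multi-valued)."""
        if level == "GO":
            col = self.table["go_terms"]
            return {f: tuple(t for t in v.split(";") if t)
                    for f, v in col.items()}
        if level == "KO":
            col = self.table["ko"]
        elif level == "eggNOG":
            col = self.table["eggnog"]
        elif level in ("genus", "phylum", "species"):
            col = self.table[level]
        elif level == "gram":
            col = self.table["gram"]
        else:
            raise DataModelError(f"unknown annotation level {level!r}")
        return {f: ((v,) if v else ()) for f, v in col.items()}

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        df.index.name = None
        return cls(df)


# ---------------------------------------------------------------------------
# Biomarker series
# ---------------------------------------------------------------------------


def biomarker_frame(series: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack named biomarker series into a biomarkers x samples frame."""
    df = pd.DataFrame({k: v for k, v in series.items()}).T
    return df


def write_biomarkers_tsv(series: Mapping[str, pd.Series], path) -> None:
    out = biomarker_frame(series)
    out.index.name = "biomarker"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_biomarkers_tsv(path) -> dict[str, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    return {name: row.astype(float) for name, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def cpm_normalize(counts: pd.DataFrame | FeatureTable) -> FeatureTable:
    """Scale read counts to counts per million, padding absences as zeros.

    Each sample column is scaled so that it sums to 1e6; features absent
    (missing) in a sample become explicit zeros, reflecting that a
    non-detected gene contributes zero reads.
    """
    if isinstance(counts, FeatureTable):
        counts = counts.values
    df = pd.DataFrame(counts).astype(float).fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise DataModelError("counts must be nonnegative")
    sums = df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DataModelError(
            f"sample(s) with all-zero counts: {list(zero.index)}")
    out = df.div(sums, axis=1) * 1e6
    return FeatureTable(out, "gene")


def collapse_replicates(table: FeatureTable, meta: SampleMetadata,
                        mode: str | None = None) -> FeatureTable:
    """Collapse technical replicates to one column per collection date.

    ``mode="sum"`` treats missing cells as zero (count semantics, default
    for the gene layer); ``mode="mean"`` averages present cells only
    (ratio semantics, default for the protein layer).
    """
    if mode is None:
        mode = "sum" if table.layer == "gene" else "mean"
    if mode not in ("sum", "mean"):
        raise DataModelError(f"unknown collapse mode {mode!r}")
    date_of = meta.date_of()
    unmapped = [s for s in table.sample_ids if s not in date_of]
    if unmapped:
        raise DataModelError(f"samples without metadata: {unmapped}")
    groups: dict[str, list[str]] = {}
    for s in table.sample_ids:
        groups.setdefault(date_of[s], []).append(s)
    empty = [d for d in meta.dates if d not in groups]
    if empty:
        raise DataModelError(f"date(s) with zero replicates: {empty}")
    cols = {}
    for date in sorted(groups):
        block = table.values[groups[date]]
        if mode == "sum":
            cols[date] = block.fillna(0.0).sum(axis=1)
        else:
            cols[date] = block.mean(axis=1, skipna=True)
    return FeatureTable(pd.DataFrame(cols), table.layer)


def filter_complete_features(table: FeatureTable) -> FeatureTable:
    """Keep only features quantified (non-missing) in every sample."""
    keep = table.values.notna().all(axis=1)
    return FeatureTable(table.values.loc[keep], table.layer)


@dataclass
class PairedTables:
    """Gene and protein tables aligned over the shared ORF namespace."""

    genes: FeatureTable
    proteins: FeatureTable

    def __post_init__(self) -> None:
        if self.genes.feature_ids != self.proteins.feature_ids:
            raise DataModelError("paired tables must share feature order")

    @property
    def feature_ids(self) -> list[str]:
        return self.genes.feature_ids

    @property
    def n_features(self) -> int:
        return len(self.genes.feature_ids)


def subset_shared_features(genes: FeatureTable,
                           proteins: FeatureTable) -> PairedTables:
    """Align both layers over the intersection of their feature ids.

    Order follows the gene table.  An empty intersection produces a
    warning and an empty pair.
    """
    shared = [f for f in genes.feature_ids if f in set(proteins.feature_ids)]
    if not shared:
        warnings.warn("gene/protein tables share no feature ids")
    return PairedTables(
        FeatureTable(genes.values.loc[shared], "gene"),
        FeatureTable(proteins.values.loc[shared], "protein"),
    )
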