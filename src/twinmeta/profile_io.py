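"""Readers and writers for the tab-delimited profile tables the pipeline consumes.

Four table families are supported, all plain TSV with a header row and UTF-8
encoding, following the public conventions of the upstream profilers:

* taxonomic profiles — first column a pipe-delimited, rank-prefixed clade
  lineage (``k__...|p__...|...|s__...``), remaining columns samples, values
  *percentages* in [0, 100].  Internally everything is a proportion in [0, 1];
  the conversion happens once, here, at the boundary.
* functional (KEGG-module) profiles — first column a module identifier
  (``M00319`` style), values relative-abundance proportions.
* per-species marker-gene tables — one file per species, rows markers,
  columns samples, values reads-per-kilobase (RPK).
* sample metadata — one row per sample with subject/pair/time-point
  identifiers and clinical variables; ``NA`` marks missing values.

Missing clinical values are kept as explicit missing (NaN) and handled
per-model downstream, never dropped globally.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProfileFormatError",
    "AbundanceTable",
    "FunctionTable",
    "MarkerProfileSet",
    "CarriageMatrix",
    "MetadataTable",
    "read_taxonomic_profile",
    "read_module_profile",
    "read_marker_profiles",
    "read_carriage_matrix",
    "read_metadata",
    "write_table",
    "write_marker_profiles",
    "species_short_name",
    "lineage_rank",
    "validate_cohort_tables",
    "CLINICAL_VARIABLES",
    "CATEGORICAL_VARIABLES",
]


class ProfileFormatError(ValueError):
    """A table violates the format contract or one of its invariants."""


RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "strain")
RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}
PREFIX_RANK = {v: k for k, v in RANK_PREFIX.items()}

MANDATORY_METADATA_COLUMNS = ("sample_id", "subject_id", "pair_id", "timepoint")
#: clinical variables the association stage treats as candidate predictors
CLINICAL_VARIABLES = (
    "bmi",
    "fbs",
    "fbi",
    "homa",
    "systolic_bp",
    "diastolic_bp",
    "triglycerides",
    "hscrp",
)
CATEGORICAL_VARIABLES = ("sex", "smoking")


def split_lineage(lineage: str) -> list[str]:
    """Split and validate a pipe-delimited rank-prefixed clade lineage."""
    parts = str(lineage).split("|")
    last_rank_idx = -1
    for part in parts:
        prefix = part[:3]
        if prefix not in PREFIX_RANK or len(part) <= 3:
            raise ProfileFormatError(
                f"malformed lineage {lineage!r}: unknown rank prefix in segment {part!r}"
            )
        idx = RANKS.index(PREFIX_RANK[prefix])
        if idx <= last_rank_idx:
            raise ProfileFormatError(
                f"malformed lineage {lineage!r}: ranks out of order at {part!r}"
            )
        last_rank_idx = idx
    return parts


def lineage_rank(lineage: str) -> str:
    """Taxonomic rank of a lineage string (the rank of its deepest segment)."""
    return PREFIX_RANK[split_lineage(lineage)[-1][:3]]


def species_short_name(clade: str) -> str:
    """Last lineage segment with its rank prefix stripped (``..|s__X`` -> ``X``)."""
    part = str(clade).split("|")[-1]
    return part[3:] if part[:3] in PREFIX_RANK else part


_leaf = species_short_name


@dataclass
class AbundanceTable:
    """Samples x clades relative-abundance matrix (proportions in [0, 1]).

    ``data`` is indexed by sample identifier with clade lineage strings as
    columns.  ``rank`` records the taxonomic rank the table was filtered to,
    if any.
    """

    data: pd.DataFrame
    rank: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def clades(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_names(self) -> list[str]:
        """Leaf clade names with rank prefixes stripped."""
        return [_leaf(c) for c in self.data.columns]

    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()]
            raise ProfileFormatError(f"duplicate clade columns: {list(dups)}")
        if self.data.index.duplicated().any():
            raise ProfileFormatError("duplicate sample identifiers")
        if (self.data.to_numpy() < 0).any():
            raise ProfileFormatError("negative relative abundance")
        # per sample, values at any single rank must sum to <= 1 (+ fp slack)
        ranks = pd.Series([lineage_rank(c) for c in self.data.columns], index=self.data.columns)
        for rank in ranks.unique():
            sums = self.data.loc[:, ranks[ranks == rank].index].sum(axis=1)
            if (sums > 1 + 1e-6).any():
                bad = sums[sums > 1 + 1e-6].index[0]
                raise ProfileFormatError(
                    f"{rank}-level abundances of sample {bad!r} sum to {sums[bad]:.6g} > 1"
                )


@dataclass
class FunctionTable:
    """Samples x KEGG-module relative-abundance matrix (proportions)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def modules(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            raise ProfileFormatError("duplicate module columns")
        if self.data.index.duplicated().any():
            raise ProfileFormatError("duplicate sample identifiers")
        if (self.data.to_numpy() < 0).any():
            raise ProfileFormatError("negative module abundance")


@dataclass
class MarkerProfileSet:
    """Per-species marker-gene abundance matrices (samples x markers, RPK)."""

    species_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, df in self.species_tables.items():
            df = df.astype(float)
            df.index = df.index.astype(str)
            df.index.name = "sample_id"
            self.species_tables[name] = df
        self.validate()

    @property
    def species(self) -> list[str]:
        return list(self.species_tables)

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.species_tables.values()))
        return list(first.index)

    def __getitem__(self, species: str) -> pd.DataFrame:
        return self.species_tables[species]

    def __len__(self) -> int:
        return len(self.species_tables)

    def __iter__(self):
        return iter(self.species_tables)

    def validate(self) -> None:
        reference: list[str] | None = None
        for name, df in self.species_tables.items():
            if df.columns.duplicated().any():
                raise ProfileFormatError(f"duplicate marker ids for species {name!r}")
            if (df.to_numpy() < 0).any():
                raise ProfileFormatError(f"negative RPK for species {name!r}")
            if reference is None:
                reference = sorted(df.index)
            elif sorted(df.index) != reference:
                raise ProfileFormatError(
                    f"sample columns of species {name!r} do not match the other species"
                )


@dataclass
class CarriageMatrix:
    """Species x module fraction of reference genomes carrying the module."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "species"
        self.validate()

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def modules(self) -> list[str]:
        return list(self.data.columns)

    def fraction(self, species: str, module: str) -> float:
        try:
            return float(self.data.at[species, module])
        except KeyError:
            return float("nan")

    def validate(self) -> None:
        vals = self.data.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ProfileFormatError("carriage fractions must lie in [0, 1]")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ProfileFormatError("duplicate species or module identifiers in carriage matrix")


@dataclass
class MetadataTable:
    """Per-sample subject/pair/time-point identifiers plus clinical variables."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ProfileFormatError("metadata missing mandatory column 'sample_id'")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        for col in CATEGORICAL_VARIABLES:
            if col in df.columns:
                df[col] = df[col].astype("category")
        self.data = df
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.data["subject_id"]))

    @property
    def clinical_columns(self) -> list[str]:
        return [c for c in CLINICAL_VARIABLES if c in self.data.columns]

    def missing_clinical(self) -> pd.DataFrame:
        """Boolean mask of missing clinical values (samples x variables)."""
        cols = self.clinical_columns
        return self.data[cols].isna()

    def validate(self) -> None:
        df = self.data
        for col in MANDATORY_METADATA_COLUMNS[1:]:
            if col not in df.columns:
                raise ProfileFormatError(f"metadata missing mandatory column {col!r}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ProfileFormatError(f"duplicate sample_id {dup!r}")
        tp = pd.to_numeric(df["timepoint"], errors="coerce")
        if tp.isna().any() or (~tp.isin([1, 2])).any():
            bad = df["timepoint"][~tp.isin([1, 2])].iloc[0]
            raise ProfileFormatError(f"timepoint must be 1 or 2, got {bad!r}")
        self.data["timepoint"] = tp.astype(int)
        counts = df.groupby("subject_id", observed=True).size()
        if (counts > 2).any():
            subj = counts[counts > 2].index[0]
            raise ProfileFormatError(f"subject {subj!r} has more than 2 time points")
        per = df.groupby(["subject_id", "timepoint"], observed=True).size()
        if (per > 1).any():
            raise ProfileFormatError("a subject appears twice at the same time point")
        for col in self.clinical_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & (vals <= 0) & df[col].notna()
            if (vals.isna() & df[col].notna()).any():
                cell = df.index[vals.isna() & df[col].notna()][0]
                raise ProfileFormatError(f"non-numeric {col} for sample {cell!r}")
            if bad.any():
                cell = df.index[bad][0]
                raise ProfileFormatError(f"non-positive {col} for sample {cell!r}")
            self.data[col] = vals


# ---------------------------------------------------------------------------
# readers


def _read_tsv(source, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if df.shape[1] < 2:
        raise ProfileFormatError("expected a tab-delimited table with at least two columns")
    df = df.set_index(df.columns[0])
    df.index.name = index_col
    return df


def _numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = bad[col][bad[col]].index[0]
        raise ProfileFormatError(f"non-numeric {what} value at ({row!r}, {col!r})")
    if out.isna().any().any():
        col = out.isna().any()[out.isna().any()].index[0]
        row = out[col][out[col].isna()].index[0]
        raise ProfileFormatError(f"missing {what} value at ({row!r}, {col!r})")
    return out.astype(float)


def read_taxonomic_profile(source, rank: str = "species") -> AbundanceTable:
    """Read a clade-lineage percentage table and keep rows of one rank.

    Values are percentages in [0, 100] (the upstream profiler convention) and
    are converted to proportions.  Malformed lineages, duplicates and negative
    values are rejected with an error naming the offending row.
    """
    if rank not in RANKS:
        raise ProfileFormatError(f"unknown taxonomic rank {rank!r}")
    df = _read_tsv(source, "clade_name")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ProfileFormatError(f"duplicated lineage row {dup!r}")
    values = _numeric(df, "abundance")
    if (values.to_numpy() < 0).any():
        row = values.index[(values < 0).any(axis=1)][0]
        raise ProfileFormatError(f"negative abundance in row {row!r}")
    keep = [c for c in values.index if lineage_rank(c) == rank]
    return AbundanceTable(data=values.loc[keep].T / 100.0, rank=rank)


def read_module_profile(source) -> FunctionTable:
    """Read a KEGG-module relative-abundance table (rows modules, cols samples)."""
    df = _read_tsv(source, "module")
    if df.shape[0] == 0:
        raise ProfileFormatError("no modules in table")
    if df.index.duplicated().any():
        raise ProfileFormatError("duplicated module row")
    values = _numeric(df, "module abundance")
    return FunctionTable(data=values.T)


def read_marker_profiles(directory) -> MarkerProfileSet:
    """Read one marker RPK table per species from ``directory`` (``<species>.tsv``)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise ProfileFormatError(f"no marker tables (*.tsv) found in {directory}")
    tables: dict[str, pd.DataFrame] = {}
    for path in files:
        df = _numeric(_read_tsv(path, "marker"), "RPK")
        if (df.to_numpy() < 0).any():
            raise ProfileFormatError(f"negative RPK in {path.name}")
        tables[path.stem] = df.T
    return MarkerProfileSet(species_tables=tables)


def read_carriage_matrix(source) -> CarriageMatrix:
    """Read a species x module genome-carriage fraction table."""
    return CarriageMatrix(data=_numeric(_read_tsv(source, "species"), "carriage"))


def read_metadata(source) -> MetadataTable:
    """Read the per-sample metadata table; ``NA`` marks missing clinical values."""
    df = pd.read_csv(source, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    for col in MANDATORY_METADATA_COLUMNS:
        if col not in df.columns:
            raise ProfileFormatError(f"metadata missing mandatory column {col!r}")
    numeric_cols = [c for c in df.columns if c in CLINICAL_VARIABLES or c in ("age",)]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return MetadataTable(data=df)


# ---------------------------------------------------------------------------
# writers


def write_table(table, dest) -> None:
    """Write any table type back to its tab-delimited on-disk form.

    Taxonomic tables are written as percentages (the convention they are read
    in); everything else is written verbatim.  ``read(write(x))`` reproduces
    ``x`` (up to one floating-point rounding of the percent scaling for
    abundance tables).
    """
    if isinstance(table, AbundanceTable):
        out = (table.data * 100.0).T
        out.index.name = "clade_name"
        out.to_csv(dest, sep="\t")
    elif isinstance(table, FunctionTable):
        out = table.data.T
        out.index.name = "module"
        out.to_csv(dest, sep="\t")
    elif isinstance(table, CarriageMatrix):
        table.data.to_csv(dest, sep="\t")
    elif isinstance(table, MetadataTable):
        table.data.reset_index().to_csv(dest, sep="\t", index=False, na_rep="NA")
    elif isinstance(table, MarkerProfileSet):
        write_marker_profiles(table, dest)
    else:
        raise TypeError(f"do not know how to write {type(table).__name__}")


def write_marker_profiles(markers: MarkerProfileSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for species, df in markers.species_tables.items():
        out = df.T
        out.index.name = "marker"
        out.to_csv(directory / f"{species}.tsv", sep="\t")


# ---------------------------------------------------------------------------
# cross-table validation


def validate_cohort_tables(
    abundance: AbundanceTable | None = None,
    functions: FunctionTable | None = None,
    markers: MarkerProfileSet | None = None,
    metadata: MetadataTable | None = None,
    carriage: CarriageMatrix | None = None,
) -> None:
    """Check cross-table consistency: shared sample ids and species naming.

    Sample-id mismatches raise :class:`ProfileFormatError`; species-name drift
    between the marker set and the abundance table only warns, since upstream
    naming conventions routinely disagree.
    """
    sample_sets: dict[str, set[str]] = {}
    if abundance is not None:
        sample_sets["abundance"] = set(abundance.sample_ids)
    if functions is not None:
        sample_sets["functions"] = set(functions.sample_ids)
    if markers is not None and len(markers):
        sample_sets["markers"] = set(markers.sample_ids)
    if metadata is not None:
        sample_sets["metadata"] = set(metadata.sample_ids)
    if len(sample_sets) > 1:
        names = list(sample_sets)
        ref = sample_sets[names[0]]
        for name in names[1:]:
            if sample_sets[name] != ref:
                raise ProfileFormatError(
                    f"sample identifiers of {name} do not match {names[0]}"
                )
    if markers is not None and abundance is not None:
        species_names = {_leaf(c) for c in abundance.clades}
        unmatched = [s for s in markers.species if s not in species_names]
        if unmatched:
            warnings.warn(
                f"marker species not found in abundance table: {unmatched}",
                stacklevel=2,
            )
    if carriage is not None and abundance is not None:
        species_names = {_leaf(c) for c in abundance.clades}
        missing = [s for s in species_names if s not in set(carriage.species)]
        if missing:
            warnings.warn(f"species without carriage rows: {missing}", stacklevel=2)
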