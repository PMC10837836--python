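"""Tabular interchange formats shared by all pipeline stages.

All tables are UTF-8 TSV with a header row and no quoting; missing KO or taxon
annotations are written as ``NA``.  Peptide lengths are stored in amino acids
throughout (convert nucleotide lengths as 3x aa upstream).

Formats
-------
ASV counts      samples in rows (``sample_id`` first column), ASVs in columns.
ASV taxonomy    ``asv_id`` plus one column per lineage rank
                (domain, phylum, class, order, family, genus).
Sample metadata ``sample_id``, ``species``, ``location``, ``habitat``
                (habitat is ``deep`` or ``shallow``).
Transcript counts  transcripts in rows (``transcript_id``), samples in columns;
                expected counts may be fractional (multi-mapping reads).
ORF annotation  ``transcript_id``, ``peptide_id``, ``peptide_length``, ``ko``,
                ``taxon`` (semicolon-joined lineage or NA).
Module catalog  flat text: id TAB name TAB level_B TAB level_C TAB definition;
                definitions are parsed eagerly at read time.
Pathway catalog flat text: id TAB name TAB level_A TAB level_B TAB
                comma-joined KO list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kegg_modules import Node, parse_definition

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
METADATA_COLUMNS = ("species", "location", "habitat")
HABITATS = ("deep", "shallow")

__all__ = [
    "LINEAGE_RANKS",
    "METADATA_COLUMNS",
    "AsvTable",
    "TranscriptCounts",
    "OrfAnnotation",
    "ModuleCatalog",
    "PathwayCatalog",
    "FormatError",
    "read_asv_table",
    "write_asv_table",
    "read_transcript_counts",
    "write_transcript_counts",
    "read_orf_annotation",
    "write_orf_annotation",
    "read_module_catalog",
    "write_module_catalog",
    "read_pathway_catalog",
    "write_pathway_catalog",
    "read_truth",
    "write_truth",
]


class FormatError(ValueError):
    """Malformed or inconsistent input table."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} ids: {dups}")


@dataclass
class AsvTable:
    """Sample x ASV count matrix with per-ASV taxonomy and sample metadata."""

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self.counts.index.name = "sample_id"
        self.counts.columns.name = "asv_id"
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "ASV")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts in ASV table")
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise FormatError(f"taxonomy missing for ASVs: {missing_tax.tolist()}")
        missing_meta = self.counts.index.difference(self.metadata.index)
        if len(missing_meta):
            raise FormatError(f"metadata missing for samples: {missing_meta.tolist()}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise FormatError(f"metadata missing column {col!r}")
        bad_hab = set(self.metadata["habitat"]) - set(HABITATS)
        if bad_hab:
            raise FormatError(f"unknown habitat labels: {sorted(bad_hab)}")
        for rank in LINEAGE_RANKS:
            if rank not in self.taxonomy.columns:
                raise FormatError(f"taxonomy missing rank column {rank!r}")
        # align auxiliary frames to the count matrix
        self.taxonomy = self.taxonomy.loc[self.counts.columns, list(LINEAGE_RANKS)]
        self.metadata = self.metadata.loc[self.counts.index, list(METADATA_COLUMNS)]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.columns

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AsvTable)
            and self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.metadata.equals(other.metadata)
        )


@dataclass
class TranscriptCounts:
    """Transcript x sample expected-count matrix (non-negative, finite)."""

    expected_counts: pd.DataFrame

    def __post_init__(self):
        self.expected_counts.index.name = "transcript_id"
        self.expected_counts.columns.name = "sample_id"
        _check_unique(self.expected_counts.index, "transcript")
        values = self.expected_counts.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("non-finite expected counts")
        if (values < 0).any():
            raise FormatError("negative expected counts")

    @property
    def sample_ids(self) -> pd.Index:
        return self.expected_counts.columns


@dataclass
class OrfAnnotation:
    """Transcript -> peptide records with length, optional KO and taxon."""

    records: pd.DataFrame  # transcript_id, peptide_id, peptide_length, ko, taxon

    def __post_init__(self):
        required = ["transcript_id", "peptide_id", "peptide_length", "ko", "taxon"]
        for col in required:
            if col not in self.records.columns:
                raise FormatError(f"ORF annotation missing column {col!r}")
        self.records = self.records[required].reset_index(drop=True)
        _check_unique(pd.Index(self.records["peptide_id"]), "peptide")
        lengths = self.records["peptide_length"]
        if (lengths < 1).any() or lengths.isna().any():
            bad = self.records.loc[~(lengths >= 1), "peptide_id"].tolist()
            raise FormatError(f"non-positive peptide lengths for: {bad}")

    def kos(self) -> pd.Series:
        return self.records.set_index("peptide_id")["ko"]

    def lengths(self) -> pd.Series:
        return self.records.set_index("peptide_id")["peptide_length"]


@dataclass
class ModuleCatalog:
    """Parsed module definitions with their two hierarchy labels."""

    entries: pd.DataFrame  # module_id, name, level_B, level_C, definition
    trees: dict[str, Node] = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(pd.Index(self.entries["module_id"]), "module")
        if not self.trees:
            self.trees = {
                row.module_id: parse_definition(row.definition, row.module_id)
                for row in self.entries.itertuples()
            }

    def __len__(self) -> int:
        return len(self.entries)

    def definition(self, module_id: str) -> str:
        row = self.entries.set_index("module_id").loc[module_id]
        return row["definition"]


@dataclass
class PathwayCatalog:
    """Flat KO-membership pathway entries (no completeness grammar)."""

    entries: pd.DataFrame  # pathway_id, name, level_A, level_B, kos (tuple)

    def __post_init__(self):
        _check_unique(pd.Index(self.entries["pathway_id"]), "pathway")


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    if index_col not in df.columns:
        raise FormatError(f"{path}: missing {index_col!r} column")
    return df.set_index(index_col)


def read_asv_table(counts_path, taxonomy_path, metadata_path) -> AsvTable:
    """Read and validate the three ASV-table files.

    Raises :class:`FormatError` naming the offending ids on any mismatch
    between the count matrix, taxonomy, and metadata.
    """
    counts = _read_tsv(counts_path, "sample_id")
    bad = counts.columns[counts.isna().any(axis=0) | (counts < 0).any(axis=0)]
    if len(bad):
        raise FormatError(f"{counts_path}: negative or missing counts in {bad.tolist()}")
    counts = counts.astype(np.int64)
    taxonomy = _read_tsv(taxonomy_path, "asv_id")
    metadata = _read_tsv(metadata_path, "sample_id")
    return AsvTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def write_asv_table(table: AsvTable, counts_path, taxonomy_path, metadata_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.taxonomy.to_csv(taxonomy_path, sep="\t", na_rep="NA")
    table.metadata.to_csv(metadata_path, sep="\t")


def read_transcript_counts(path) -> TranscriptCounts:
    df = _read_tsv(path, "transcript_id").astype(float)
    return TranscriptCounts(expected_counts=df)


def write_transcript_counts(tc: TranscriptCounts, path) -> None:
    tc.expected_counts.to_csv(path, sep="\t")


def read_orf_annotation(path) -> OrfAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "peptide_id": str, "ko": str, "taxon": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    if "peptide_length" in df.columns:
        df["peptide_length"] = pd.to_numeric(df["peptide_length"], errors="raise")
    return OrfAnnotation(records=df)


def write_orf_annotation(ann: OrfAnnotation, path) -> None:
    ann.records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_module_catalog(path) -> ModuleCatalog:
    """Parse the flat module-catalog text: id, name, level_B, level_C, definition.

    Every definition is parsed eagerly; a grammar error is reported with the
    module id and character position.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            rows.append(parts)
    entries = pd.DataFrame(
        rows, columns=["module_id", "name", "level_B", "level_C", "definition"]
    )
    return ModuleCatalog(entries=entries)


def write_module_catalog(catalog: ModuleCatalog, path) -> None:
    catalog.entries.to_csv(path, sep="\t", index=False, header=False)


def read_pathway_catalog(path) -> PathwayCatalog:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            pid, name, level_a, level_b, kos = parts
            rows.append((pid, name, level_a, level_b, tuple(kos.split(","))))
    entries = pd.DataFrame(
        rows, columns=["pathway_id", "name", "level_A", "level_B", "kos"]
    )
    return PathwayCatalog(entries=entries)


def write_pathway_catalog(pathways: PathwayCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in pathways.entries.itertuples():
            fh.write(
                "\t".join([e.pathway_id, e.name, e.level_A, e.level_B, ",".join(e.kos)])
                + "\n"
            )


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
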