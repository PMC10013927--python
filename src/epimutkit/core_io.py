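"""Data model and delimited-text I/O for the epimutation pipeline.

The pipeline's primary containers are thin dataclass wrappers around pandas
DataFrames with validated shapes:

* :class:`CountTable` -- raw or normalized sequencing counts for one
  (lineage, assay), loci in rows and integer generation labels in columns.
  Generation 0 is the pre-mutation-accumulation (PMA) founder and must be
  present; later even generations may be missing (lineages occasionally lack
  a time point) and their absence is recorded, never imputed at I/O time.
* :class:`ZTable` -- per-locus residual Z-scores versus the PMA generation.
* :class:`StatusTable` -- ternary epimutation calls, ``+1`` (Up), ``-1``
  (Down) or ``0`` per (locus, generation) cell.
* :class:`AnnotationTable` -- BED-like locus annotation carrying the
  gene <-> regulatory-element mapping and optional chromatin-domain labels.

All files are plain delimited text (comma by default, tab via ``sep``),
UTF-8, with a header row.  Coordinates in annotations follow the BED
convention (0-based, half-open); they are bookkeeping only and never enter
any arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ASSAYS = ("expression", "atac", "sRNA-22G", "sRNA-piRNA", "sRNA-miRNA")

LOCUS_CLASSES = ("gene", "regulatory_element")


class TableValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_generations(columns, require_pma: bool) -> list[int]:
    try:
        gens = [int(c) for c in columns]
    except (TypeError, ValueError) as exc:
        raise TableValidationError(
            f"generation labels must be integers, got {list(columns)!r}"
        ) from exc
    if any(b <= a for a, b in zip(gens, gens[1:])):
        raise TableValidationError(f"generations not strictly increasing: {gens}")
    if require_pma and 0 not in gens:
        raise TableValidationError("PMA generation absent (no generation-0 column)")
    return gens


def _check_loci(index) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate locus ids: {dups}")


@dataclass
class CountTable:
    """Counts for one (lineage, assay): loci x generations, generation 0 required."""

    lineage_id: str
    assay: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        df.columns = _check_generations(df.columns, require_pma=True)
        _check_loci(df.index)
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise TableValidationError("counts contain missing values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise TableValidationError(
                f"negative count at locus {df.index[i]!r}, generation {df.columns[j]}"
            )
        self.counts = df

    @property
    def locus_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def generations(self) -> list[int]:
        return list(self.counts.columns)


@dataclass
class ZTable:
    """Residual Z-scores versus PMA; generations exclude 0."""

    lineage_id: str
    assay: str
    z: pd.DataFrame

    def __post_init__(self) -> None:
        gens = _check_generations(self.z.columns, require_pma=False)
        if 0 in gens:
            raise TableValidationError("Z table must not contain generation 0")
        _check_loci(self.z.index)
        self.z.columns = gens

    @property
    def locus_ids(self) -> pd.Index:
        return self.z.index

    @property
    def generations(self) -> list[int]:
        return list(self.z.columns)


@dataclass
class StatusTable:
    """Ternary epimutation calls in {-1, 0, +1} per (locus, generation)."""

    lineage_id: str
    assay: str
    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        gens = _check_generations(self.statuses.columns, require_pma=False)
        _check_loci(self.statuses.index)
        vals = self.statuses.to_numpy()
        bad = ~np.isin(vals, (-1, 0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableValidationError(
                f"non-ternary status {vals[i, j]!r} at locus "
                f"{self.statuses.index[i]!r}, generation {gens[j]}"
            )
        self.statuses = self.statuses.astype(int)
        self.statuses.columns = gens

    @property
    def locus_ids(self) -> pd.Index:
        return self.statuses.index

    @property
    def generations(self) -> list[int]:
        return list(self.statuses.columns)


@dataclass
class AnnotationTable:
    """BED-like locus annotation with a gene -> regulatory-element index.

    Columns: chromosome, start, end, locus_id, locus_class, gene_id, domain.
    Genes carry their own id in ``gene_id``; every regulatory element must
    name its associated gene (several elements may share one gene, as with
    multi-promoter genes).
    """

    table: pd.DataFrame
    gene_to_elements: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.table
        required = ["chromosome", "start", "end", "locus_id", "locus_class", "gene_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableValidationError(f"annotation missing columns: {missing}")
        if "domain" not in df.columns:
            df = df.assign(domain="unassigned")
        if df["locus_id"].duplicated().any():
            dups = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise TableValidationError(f"duplicate locus ids in annotation: {dups}")
        bad_coord = df["start"].astype(int) >= df["end"].astype(int)
        if bad_coord.any():
            offender = df.loc[bad_coord, "locus_id"].iloc[0]
            raise TableValidationError(f"start >= end for locus {offender!r}")
        unknown = ~df["locus_class"].isin(LOCUS_CLASSES)
        if unknown.any():
            raise TableValidationError(
                f"unknown locus_class values: {df.loc[unknown, 'locus_class'].unique().tolist()}"
            )
        elements = df[df["locus_class"] == "regulatory_element"]
        no_gene = elements["gene_id"].isna() | (elements["gene_id"].astype(str) == "")
        if no_gene.any():
            offenders = elements.loc[no_gene, "locus_id"].tolist()
            raise TableValidationError(
                f"regulatory elements without gene_id: {offenders}"
            )
        self.table = df.set_index("locus_id", drop=False)
        idx: dict[str, list[str]] = {}
        for locus, gene in zip(elements["locus_id"], elements["gene_id"]):
            idx.setdefault(gene, []).append(locus)
        self.gene_to_elements = idx

    @property
    def genes(self) -> pd.Index:
        return self.table.loc[self.table["locus_class"] == "gene", "locus_id"]

    @property
    def elements(self) -> pd.Index:
        return self.table.loc[
            self.table["locus_class"] == "regulatory_element", "locus_id"
        ]

    def element_gene(self, locus_id: str) -> str:
        """Gene associated with a locus (itself for genes)."""
        return self.table.at[locus_id, "gene_id"]

    def domain_of(self, locus_id: str) -> str:
        return self.table.at[locus_id, "domain"]


# ---------------------------------------------------------------------------
# Readers / writers


def _read_matrix(path, sep: str, id_column: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise TableValidationError(f"{path}: expected an id column plus data columns")
    id_col = id_column if id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise TableValidationError(f"{path}: id column {id_col!r} not found")
    return df.set_index(id_col).rename_axis("locus_id")


def read_count_table(
    path,
    lineage_id: str,
    assay: str,
    sep: str = ",",
    id_column: str | None = None,
) -> CountTable:
    """Read a loci x generations count CSV (header of generation labels)."""
    return CountTable(lineage_id, assay, _read_matrix(path, sep, id_column))


def write_count_table(ct: CountTable, path, sep: str = ",") -> None:
    ct.counts.rename_axis("locus_id").to_csv(path, sep=sep)


def read_status_table(
    path,
    lineage_id: str = "",
    assay: str = "",
    sep: str = ",",
    id_column: str | None = None,
) -> StatusTable:
    """Read a ternary status CSV (locus-id column plus one column per generation)."""
    return StatusTable(lineage_id, assay, _read_matrix(path, sep, id_column))


def write_status_table(st: StatusTable, path, sep: str = ",") -> None:
    st.statuses.rename_axis("locus_id").to_csv(path, sep=sep)


def read_z_table(
    path,
    lineage_id: str = "",
    assay: str = "",
    sep: str = ",",
    id_column: str | None = None,
) -> ZTable:
    return ZTable(lineage_id, assay, _read_matrix(path, sep, id_column))


def write_z_table(zt: ZTable, path, sep: str = ",") -> None:
    zt.z.rename_axis("locus_id").to_csv(path, sep=sep)


ANNOTATION_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "locus_id",
    "locus_class",
    "gene_id",
    "domain",
]


def read_annotation(path, sep: str = ",") -> AnnotationTable:
    """Read a BED-like annotation (chrom, start, end, id, class, gene, domain)."""
    df = pd.read_csv(path, sep=sep)
    if not set(["locus_id", "locus_class"]).issubset(df.columns):
        # headerless BED-like layout: positional columns
        df = pd.read_csv(path, sep=sep, header=None)
        df.columns = ANNOTATION_COLUMNS[: df.shape[1]]
    return AnnotationTable(df.reset_index(drop=True))


def write_annotation(ann: AnnotationTable, path, sep: str = ",") -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in ann.table.columns]
    ann.table[cols].to_csv(path, sep=sep, index=False)
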