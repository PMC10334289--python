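"""Readers and writers for the package's external formats.

Every genomic coordinate in this package is 0-based, half-open
(``[start, end)``, the BED convention).  Readers validate invariants and
raise :class:`FormatError` naming the offending line rather than clamping
or silently dropping records.

Formats handled here: chromosome-sizes TSV, BED3/BED6 tag files, BED6+
region files, a 6-column gene-model TSV, GMT gene-category collections,
and TSV count matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeModel",
    "TagSet",
    "GeneSet",
    "CategoryMap",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tags_bed",
    "write_tags_bed",
    "read_regions_bed",
    "write_regions_bed",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_set",
    "write_gene_set",
]

ASSAYS = ("5mC", "5hmC", "RNA")


class FormatError(ValueError):
    """A file violated its format contract or a coordinate invariant."""


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of named chromosomes with lengths in bp."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(names) != len(set(names)):
            raise FormatError("duplicate chromosome names in genome model")
        for name, length in self.chroms:
            if length < 1:
                raise FormatError(f"chromosome {name!r} has non-positive length {length}")
        if self.total_length < 1:
            raise FormatError("genome has zero total length")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass
class TagSet:
    """One sample's uniquely-mapped sequencing tags on a genome.

    ``tags`` is a DataFrame with columns chrom/start/end/strand.  Strand is
    recorded for provenance but ignored by all counting operations; a DIP
    tag is unstranded evidence of methylation.
    """

    sample_id: str
    assay: str
    genome: GenomeModel
    tags: pd.DataFrame
    _starts_by_chrom: dict[str, np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        t = self.tags
        expected = ["chrom", "start", "end", "strand"]
        if list(t.columns) != expected:
            raise ValueError(f"tag frame must have columns {expected}")
        if len(t):
            bad = ~t["chrom"].isin(self.genome.names)
            if bad.any():
                raise FormatError(
                    f"tags on chromosomes absent from genome: {sorted(t.loc[bad, 'chrom'].unique())}"
                )
            if (t["start"] >= t["end"]).any():
                raise FormatError("tag with start >= end")
            if (t["start"] < 0).any():
                raise FormatError("tag with negative start")
            lengths = t["chrom"].map(self.genome.lengths)
            if (t["end"] > lengths).any():
                raise FormatError("tag extends past chromosome end")
        object.__setattr__(self, "_starts_by_chrom", None)

    def __len__(self) -> int:
        return len(self.tags)

    def starts(self, chrom: str) -> np.ndarray:
        """Sorted tag start positions on ``chrom`` (cached)."""
        if self._starts_by_chrom is None:
            by = {
                c: np.sort(g["start"].to_numpy(dtype=np.int64))
                for c, g in self.tags.groupby("chrom", sort=False)
            }
            object.__setattr__(self, "_starts_by_chrom", by)
        return self._starts_by_chrom.get(chrom, np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene identifiers.

    The unit of every intersection statistic downstream.  ``provenance``
    records how the set was derived (condition, direction, selection
    parameters) so reports stay auditable.
    """

    label: str
    genes: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gene set label must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    def sorted(self) -> list[str]:
        return sorted(self.genes)


@dataclass(frozen=True)
class CategoryMap:
    """Gene categories (GO/KEGG-style): category_id -> (name, member ids)."""

    categories: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for cid, (_, members) in self.categories.items():
            if not members:
                raise FormatError(f"category {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.categories)

    def members(self, cid: str) -> frozenset[str]:
        return self.categories[cid][1]


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a two-column (name, length) TSV into a GenomeModel.

    Rows keep file order.  Duplicate names, non-positive lengths and
    malformed lines raise :class:`FormatError` naming the line number.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length {raw_len!r} is not an integer") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise FormatError(f"{path}: empty chromosome sizes file")
    return GenomeModel(tuple(chroms))


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# tags (BED)


def read_tags_bed(path: str | Path, genome: GenomeModel, sample_id: str, assay: str) -> TagSet:
    """Read a BED3/BED6 tag file against ``genome``.

    BED3 lines default to strand "+".  Tags on chromosomes absent from the
    genome, inverted intervals and unparsable lines are format errors.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    tags = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "strand": pd.Series(strands, dtype=str),
        }
    )
    return TagSet(sample_id=sample_id, assay=assay, genome=genome, tags=tags)


def write_tags_bed(tagset: TagSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in tagset.tags.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# regions (BED6+)


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED6: name = region id, score = -log10(p).

    ``regions`` needs columns chrom/start/end and optionally id and pval.
    A missing or undefined p-value is written as score ".".
    """
    with open(path, "w") as fh:
        for i, row in enumerate(regions.itertuples(index=False)):
            rid = getattr(row, "id", f"r{i + 1}")
            p = getattr(row, "pval", None)
            if p is None or (isinstance(p, float) and math.isnan(p)):
                score = "."
            else:
                score = f"{-math.log10(p):g}" if p > 0 else "inf"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{rid}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read back a BED6+ region file written by :func:`write_regions_bed`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rid = fields[3] if len(fields) > 3 else f"r{lineno}"
            pval = np.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
                pval = 0.0 if math.isinf(score) else 10.0 ** (-score)
            rows.append((chrom, start, end, rid, pval))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "pval"])


# ---------------------------------------------------------------------------
# gene models


GENE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end"]


def _finalize_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene table and add derived tss / length columns."""
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene ids: {dups[:5]}")
    if (genes["tx_start"] >= genes["tx_end"]).any():
        raise FormatError("gene with tx_start >= tx_end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise FormatError("gene strand must be + or -")
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"])
    genes["length"] = genes["tx_end"] - genes["tx_start"]
    return genes


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the 6-column gene-model TSV.

    Columns: gene_id, symbol, chrom, strand, tx_start, tx_end.  The TSS is
    derived as tx_start on "+" genes and tx_end on "-" genes (the 5' end).
    """
    genes = pd.read_csv(
        path,
        sep="\t",
        names=GENE_COLUMNS,
        header=None,
        comment="#",
        dtype={"gene_id": str, "symbol": str, "chrom": str, "strand": str},
    )
    return _finalize_gene_table(genes)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> CategoryMap:
    """Read a GMT file: id <tab> description <tab> member [tab member ...]."""
    cats: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with fewer than 3 fields")
            cid, name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: category {cid!r} with no members")
            cats[cid] = (name, members)
    return CategoryMap(cats)


def write_gmt(cmap: CategoryMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, (name, members) in cmap.categories.items():
            fh.write("\t".join([cid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# count matrices and gene sets


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """TSV count matrix, rows = regions/genes, columns = samples."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.isna().any().any():
        raise FormatError(f"{path}: missing values in count matrix")
    return mat


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """One-gene-per-line text file; '#' lines carry provenance and are skipped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    return GeneSet(label=label or Path(path).stem, genes=frozenset(genes))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in gene_set.provenance.items():
            fh.write(f"# {key}: {val}\n")
        for g in gene_set.sorted():
            fh.write(g + "\n")
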