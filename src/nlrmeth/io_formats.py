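"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are converted to 0-based half-open intervals at the
parsing boundary: GFF3 (1-based closed) and Bismark-style CX reports
(1-based positions) are the only formats that need conversion.  Parsers
reject malformed rows with the offending line number rather than repairing
them silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_CONTEXTS = ("CG", "CHG", "CHH")


class ParseError(ValueError):
    """A malformed row in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).  Zero-length
    intervals (``start == end``) are permitted only for clipped analysis
    windows, never for parsed records.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneRecord:
    """A located, stranded gene belonging to one species."""

    gene_id: str
    species: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or - "
                "(flank orientation requires it)"
            )


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine with methylated/unmethylated read counts.

    ``pos`` is the 0-based position of the cytosine on the reference;
    zero-coverage records (``m + u == 0``) are retained at parse time.
    """

    chrom: str
    pos: int
    strand: str
    m: int
    u: int
    context: str

    def __post_init__(self) -> None:
        if self.m < 0 or self.u < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def depth(self) -> int:
        return self.m + self.u


@dataclass(frozen=True)
class SimilarityRecord:
    """One deduplicated pairwise protein-identity observation."""

    query_id: str
    subject_id: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class SpeciesQC:
    """Per-species WGBS quality summary: mean depth and mapping rate."""

    species: str
    wgbs_depth: float
    mapping_rate: float

    def __post_init__(self) -> None:
        if self.wgbs_depth < 0:
            raise ValueError(f"{self.species}: negative WGBS depth")
        if not 0.0 <= self.mapping_rate <= 1.0:
            raise ValueError(f"{self.species}: mapping rate outside [0, 1]")


# ---------------------------------------------------------------------------
# GFF3 / BED readers
# ---------------------------------------------------------------------------

def _attr_field(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff_genes(
    path: str | Path, species: str = "", feature_type: str = "gene"
) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    Only rows whose third column equals ``feature_type`` are kept.  GFF3
    1-based closed coordinates become 0-based half-open.  Every gene must
    carry an ``ID`` attribute, a ``+``/``-`` strand, and a unique ID.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}"
                )
            if cols[2] != feature_type:
                continue
            chrom, start_s, end_s, strand, attrs = (
                cols[0], cols[3], cols[4], cols[6], cols[8],
            )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise ParseError(f"{path}:{lineno}: start > end")
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: gene strand must be + or -, got {strand!r}"
                )
            gene_id = _attr_field(attrs, "ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    species=species,
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                )
            )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_gff_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records as minimal GFF3 (inverse of :func:`read_gff_genes`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tnlrmeth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


def read_te_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read transposon intervals from BED (>=3 cols) or GFF3.

    Only interval coordinates are used; TE class and strand are ignored
    (coverage is the sole downstream quantity).  Format is sniffed: rows
    with 9 tab-separated columns and an integer 4th column are GFF3,
    otherwise BED.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            is_gff = len(cols) == 9 and cols[3].isdigit() and cols[4].isdigit() \
                and not cols[1].isdigit()
            try:
                if is_gff:
                    chrom, start, end = cols[0], int(cols[3]) - 1, int(cols[4])
                else:
                    if len(cols) < 3:
                        raise ParseError(
                            f"{path}:{lineno}: expected >=3 BED columns"
                        )
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval")
            intervals.append(GenomicInterval(chrom, start, end))
    intervals.sort()
    return intervals


def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    """Write (interval, name) pairs as BED6; score 0, strand from the interval."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# CX report
# ---------------------------------------------------------------------------

def read_cx_report(path: str | Path) -> list[CytosineRecord]:
    """Read a 7-column Bismark-style CX report.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context (CG/CHG/CHH), trinucleotide.  Positions
    become 0-based; zero-coverage rows are retained.
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 CX-report columns, got {len(cols)}"
                )
            chrom, pos_s, strand, m_s, u_s, context = cols[:6]
            try:
                pos1, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if m < 0 or u < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            if context not in VALID_CONTEXTS:
                raise ParseError(f"{path}:{lineno}: unknown context {context!r}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            records.append(CytosineRecord(chrom, pos1 - 1, strand, m, u, context))
    return records


def read_cx_report_arrays(path: str | Path):
    """Fast columnar CX-report reader for pipeline-scale files.

    Same dialect and validation as :func:`read_cx_report` but returns
    ``(chrom, pos, m, u, context_codes)`` with 0-based positions and
    context codes indexing CG/CHG/CHH order.  Requires a single
    chromosome per file (the pipeline's per-species layout).
    """
    import numpy as np
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "pos", "strand", "m", "u", "context", "tri"],
        dtype={"chrom": str, "strand": str, "context": str, "tri": str},
    )
    if df.empty:
        return "", np.array([], dtype=np.int64), np.array([], dtype=np.int64), \
            np.array([], dtype=np.int64), np.array([], dtype=np.uint8)
    if (df["m"] < 0).any() or (df["u"] < 0).any():
        bad = int(df.index[(df["m"] < 0) | (df["u"] < 0)][0]) + 1
        raise ParseError(f"{path}:{bad}: negative read count")
    ctx_codes = df["context"].map(
        {c: i for i, c in enumerate(VALID_CONTEXTS)}
    )
    if ctx_codes.isna().any():
        bad = int(df.index[ctx_codes.isna()][0]) + 1
        raise ParseError(
            f"{path}:{bad}: unknown context {df['context'][bad - 1]!r}"
        )
    if not df["strand"].isin(["+", "-"]).all():
        bad = int(df.index[~df["strand"].isin(['+', '-'])][0]) + 1
        raise ParseError(f"{path}:{bad}: invalid strand")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ParseError(f"{path}: expected one chromosome, found {len(chroms)}")
    return (
        str(chroms[0]),
        df["pos"].to_numpy(np.int64) - 1,
        df["m"].to_numpy(np.int64),
        df["u"].to_numpy(np.int64),
        ctx_codes.to_numpy(np.uint8),
    )


def write_cx_report(records: Sequence[CytosineRecord], path: str | Path,
                    trinucleotides: Sequence[str] | None = None) -> None:
    """Write cytosine records in CX-report layout (inverse of the reader)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            tri = trinucleotides[i] if trinucleotides is not None else r.context
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.m}\t{r.u}\t"
                f"{r.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# Similarity table (BLAST outfmt-6-like)
# ---------------------------------------------------------------------------

def read_similarity_table(path: str | Path) -> list[SimilarityRecord]:
    """Read a tab-separated pairwise-identity table.

    First three columns are query, subject, percent identity (extra columns,
    as in BLAST outfmt 6, are ignored).  Self-hits are dropped; reciprocal
    duplicates (a,b)/(b,a) are collapsed keeping the maximum identity.
    """
    best: dict[tuple[str, str], float] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            q, s = cols[0], cols[1]
            try:
                ident = float(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric identity") from exc
            if not 0.0 <= ident <= 100.0:
                raise ParseError(
                    f"{path}:{lineno}: identity {ident} outside [0, 100]"
                )
            n_rows += 1
            if q == s:
                continue
            key = (q, s) if q <= s else (s, q)
            if key not in best or ident > best[key]:
                best[key] = ident
    if n_rows == 0:
        logger.warning("similarity table %s is empty", path)
    return [
        SimilarityRecord(q, s, ident)
        for (q, s), ident in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# Species QC
# ---------------------------------------------------------------------------

def read_species_qc(path: str | Path) -> list[SpeciesQC]:
    """Read a species/depth/mapping-rate TSV (header row optional)."""
    out: list[SpeciesQC] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and cols[0].lower() in ("species", "sample"):
                continue
            try:
                depth, rate = float(cols[1]), float(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric QC value") from exc
            out.append(SpeciesQC(cols[0], depth, rate))
    return out


def qc_filter(
    records: Iterable[SpeciesQC],
    min_depth: float = 5.0,
    min_mapping_rate: float = 0.60,
) -> list[SpeciesQC]:
    """Retain species with depth strictly above ``min_depth`` and mapping rate
    strictly above ``min_mapping_rate`` (both bounds exclusive)."""
    return [
        r for r in records
        if r.wgbs_depth > min_depth and r.mapping_rate > min_mapping_rate
    ]


# ---------------------------------------------------------------------------
# Family assignment table
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (species, gene_id, family_id) rows from a TSV (header optional)."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and cols[0].lower() == "species":
                continue
            rows.append((cols[0], cols[1], cols[2]))
    return rows
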