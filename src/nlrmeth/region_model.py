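"""Strand-aware analysis windows around genes.

Two schemes are built per gene:

* ``coarse`` — four 5 kb flank bins on each side of the gene body
  (20 kb of flank total per side), labelled ``up4..up1`` from farthest to
  nearest the TSS, then ``body``, then ``down1..down4`` outward from the
  TTS.  Used for the per-region statistics and TE coverage.
* ``metagene`` — the gene body rescaled to a fixed number of bins with
  fixed-width flank bins (defaults: 100 body bins, 100 x 50 bp per 5 kb
  flank), anchored at TSS and TTS.  Used for profile plots and the
  body-conservation checks.

Upstream/downstream are transcriptional: for a minus-strand gene the
upstream flank lies at higher genomic coordinates.  Windows are clipped at
chromosome ends; clipped-away bins are retained zero-length and flagged
truncated so bin counts stay constant across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneRecord, GenomicInterval


@dataclass(frozen=True)
class RegionSet:
    """Ordered, labelled analysis windows for one gene (5' -> 3')."""

    gene_id: str
    scheme: str  # "coarse" | "metagene"
    regions: tuple[tuple[str, GenomicInterval], ...]
    truncated: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")

    def __iter__(self):
        return iter(self.regions)

    def get(self, label: str) -> GenomicInterval:
        for lab, iv in self.regions:
            if lab == label:
                return iv
        raise KeyError(label)


def _clip(chrom: str, start: int, end: int, chrom_length: int,
          strand: str) -> tuple[GenomicInterval, bool]:
    cs, ce = max(0, start), min(chrom_length, end)
    if ce < cs:
        cs = ce = min(max(0, start), chrom_length)
    return GenomicInterval(chrom, cs, ce, strand), (cs, ce) != (start, end)


def build_coarse_regions(
    gene: GeneRecord,
    chrom_length: int,
    flank: int = 20_000,
    bin_size: int = 5_000,
) -> RegionSet:
    """Gene body plus ``flank``/``bin_size`` flank bins per side.

    Labels run ``up{n}..up1, body, down1..down{n}`` in transcriptional
    order, where up1 abuts the TSS and down1 the TTS.
    """
    if flank % bin_size != 0:
        raise ValueError(f"flank {flank} not divisible by bin size {bin_size}")
    n_bins = flank // bin_size
    iv = gene.interval
    if iv.end > chrom_length:
        raise ValueError(f"gene {gene.gene_id} extends past chromosome end")
    regions: list[tuple[str, GenomicInterval]] = []
    truncated: set[str] = set()

    def add(label: str, start: int, end: int) -> None:
        clipped, trunc = _clip(iv.chrom, start, end, chrom_length, iv.strand)
        regions.append((label, clipped))
        if trunc:
            truncated.add(label)

    if iv.strand == "+":
        for i in range(n_bins, 0, -1):  # up4 .. up1
            add(f"up{i}", iv.start - i * bin_size, iv.start - (i - 1) * bin_size)
        add("body", iv.start, iv.end)
        for i in range(1, n_bins + 1):  # down1 .. down4
            add(f"down{i}", iv.end + (i - 1) * bin_size, iv.end + i * bin_size)
    else:
        for i in range(n_bins, 0, -1):  # upstream at higher coordinates
            add(f"up{i}", iv.end + (i - 1) * bin_size, iv.end + i * bin_size)
        add("body", iv.start, iv.end)
        for i in range(1, n_bins + 1):
            add(f"down{i}", iv.start - i * bin_size, iv.start - (i - 1) * bin_size)
    return RegionSet(gene.gene_id, "coarse", tuple(regions), frozenset(truncated))


def _partition(start: int, end: int, n_bins: int,
               from_right: bool = False) -> list[tuple[int, int]]:
    """Cut [start, end) into ``n_bins`` contiguous bins whose widths differ
    by at most 1 bp, wider bins at the 5' end (largest-remainder order).

    Bins are returned in transcriptional order: left-to-right genomically
    when ``from_right`` is False (+ strand), right-to-left when True.
    """
    length = end - start
    base, extra = divmod(length, n_bins)
    widths = [base + 1] * extra + [base] * (n_bins - extra)
    bounds = []
    if not from_right:
        pos = start
        for w in widths:
            bounds.append((pos, pos + w))
            pos += w
    else:
        pos = end
        for w in widths:
            bounds.append((pos - w, pos))
            pos -= w
    return bounds


def build_metagene_regions(
    gene: GeneRecord,
    chrom_length: int,
    flank: int = 5_000,
    body_bins: int = 100,
    flank_bins: int = 100,
) -> RegionSet:
    """Fixed-bin metagene windows: 5' flank bins, body bins, 3' flank bins.

    Body bins partition the gene exactly (integer largest-remainder rule,
    wider bins 5'-most); genes shorter than ``body_bins`` get one base per
    bin and trailing empty bins flagged truncated.  Flank bins are equal
    width (``flank`` must divide by ``flank_bins``).  Labels are
    ``u001..u{F}``, ``b001..b{B}``, ``d001..d{F}`` in transcriptional order.
    """
    iv = gene.interval
    if len(iv) < 1:
        raise ValueError(f"gene {gene.gene_id} has zero length")
    if flank % flank_bins != 0:
        raise ValueError("flank must divide evenly into flank_bins")
    fw = flank // flank_bins
    regions: list[tuple[str, GenomicInterval]] = []
    truncated: set[str] = set()
    width = max(len(str(body_bins)), len(str(flank_bins)), 3)

    def add(label: str, start: int, end: int) -> None:
        clipped, trunc = _clip(iv.chrom, start, end, chrom_length, iv.strand)
        regions.append((label, clipped))
        if trunc or len(clipped) == 0:
            truncated.add(label)

    if iv.strand == "+":
        body = _partition(iv.start, iv.end, body_bins)
        for i in range(flank_bins):  # 5' flank, farthest bin first
            s = iv.start - (flank_bins - i) * fw
            add(f"u{i + 1:0{width}d}", s, s + fw)
        for i, (s, e) in enumerate(body):
            add(f"b{i + 1:0{width}d}", s, e)
        for i in range(flank_bins):
            s = iv.end + i * fw
            add(f"d{i + 1:0{width}d}", s, s + fw)
    else:
        # transcriptional 5' -> 3' runs right to left on the genome
        body = _partition(iv.start, iv.end, body_bins, from_right=True)
        for i in range(flank_bins):
            e = iv.end + (flank_bins - i) * fw
            add(f"u{i + 1:0{width}d}", e - fw, e)
        for i, (s, e) in enumerate(body):
            add(f"b{i + 1:0{width}d}", s, e)
        for i in range(flank_bins):
            e = iv.start - i * fw
            add(f"d{i + 1:0{width}d}", e - fw, e)
    return RegionSet(gene.gene_id, "metagene", tuple(regions), frozenset(truncated))
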