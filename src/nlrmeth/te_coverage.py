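"""Transposon coverage of analysis regions.

TE annotations routinely overlap and nest, so intervals are unioned per
chromosome before any coverage arithmetic; coverage of a window is then
100 x (bp of the window intersecting the union) / window length.  TE
strand and classification are ignored — only accumulated length matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, GenomicInterval
from .region_model import RegionSet


@dataclass(frozen=True)
class TECoverageSummary:
    """TE coverage of one region for one gene; undefined for empty regions."""

    species: str
    gene_id: str
    region_label: str
    coverage_percent: float | None
    region_length: int
    covered_bp: int


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or book-ended intervals on one chromosome."""
    ivs = sorted(intervals, key=lambda x: (x.start, x.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    merged: list[GenomicInterval] = []
    cur_s, cur_e = ivs[0].start, ivs[0].end
    chrom = ivs[0].chrom
    for iv in ivs[1:]:
        if iv.start <= cur_e:  # overlap or book-ended
            cur_e = max(cur_e, iv.end)
        else:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
            cur_s, cur_e = iv.start, iv.end
    merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def merge_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Group intervals by chromosome and union each group."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}


def region_te_coverage(
    te_intervals: Sequence[GenomicInterval],
    region: GenomicInterval,
    species: str = "",
    gene_id: str = "",
    region_label: str = "",
) -> TECoverageSummary:
    """Coverage of ``region`` by pre-merged TE intervals on its chromosome.

    Zero-length (clipped-away) regions yield an undefined percentage.
    """
    length = len(region)
    if length == 0:
        return TECoverageSummary(species, gene_id, region_label, None, 0, 0)
    covered = sum(region.overlap(te) for te in te_intervals)
    return TECoverageSummary(
        species=species, gene_id=gene_id, region_label=region_label,
        coverage_percent=100.0 * covered / length,
        region_length=length, covered_bp=covered,
    )


def te_coverage_profile(
    genes: Sequence[GeneRecord],
    regionsets: Mapping[str, RegionSet],
    te_intervals: Iterable[GenomicInterval],
) -> pd.DataFrame:
    """One row per gene x region with TE coverage; NaN for empty regions.

    ``te_intervals`` need not be pre-merged; merging happens per chromosome
    here so duplicated or overlapping annotations cannot exceed 100%.
    """
    merged = merge_by_chrom(te_intervals)
    rows = []
    for gene in sorted(genes, key=lambda g: (g.species, g.gene_id)):
        try:
            rs = regionsets[gene.gene_id]
        except KeyError:
            raise ValueError(f"gene {gene.gene_id} has no RegionSet") from None
        for ordinal, (label, iv) in enumerate(rs):
            tes = merged.get(iv.chrom, [])
            summ = region_te_coverage(tes, iv, gene.species, gene.gene_id, label)
            rows.append({
                "species": gene.species,
                "gene_id": gene.gene_id,
                "region_label": label,
                "region_ordinal": ordinal,
                "coverage_percent": (np.nan if summ.coverage_percent is None
                                     else summ.coverage_percent),
                "region_length": summ.region_length,
                "covered_bp": summ.covered_bp,
            })
    return pd.DataFrame(
        rows,
        columns=["species", "gene_id", "region_label", "region_ordinal",
                 "coverage_percent", "region_length", "covered_bp"],
    )
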