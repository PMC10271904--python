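"""Cytosine context classification and weighted methylation levels.

The weighted methylation level of a region is the count-weighted ratio
``sum(m_i) / sum(m_i + u_i)`` over all cytosines of one sequence context
(CG, CHG or CHH) falling in the region, on either strand — not the mean of
per-site fractions.  This makes the statistic exactly additive: the level
of a region equals the (m, m+u)-weighted combination of the levels of any
partition of it.  Regions with no covered cytosine have an undefined level
(``None``), which is propagated as missing downstream, never coerced to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CytosineRecord, GeneRecord, GenomicInterval, VALID_CONTEXTS
from .region_model import RegionSet

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_H = ("A", "T", "C")


def classify_context(sequence: str, pos: int, strand: str) -> str | None:
    """Sequence context (CG/CHG/CHH) of the cytosine at ``pos`` on ``strand``.

    ``sequence`` is the plus-strand reference.  The two bases downstream
    (5'->3' on the cytosine's strand) decide the context: CG when the next
    base is G; CHG when the next is H (A/T/C) and the second-next is G;
    CHH otherwise.  Returns ``None`` when the needed downstream bases run
    off the sequence or any involved base is ambiguous (N).

    Raises ``ValueError`` when ``pos`` is out of range or the strand-adjusted
    reference base is not a cytosine.
    """
    if not 0 <= pos < len(sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    base = sequence[pos].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {pos} on + strand is {base!r}, not C")
        nxt = sequence[pos + 1].upper() if pos + 1 < len(sequence) else None
        nxt2 = sequence[pos + 2].upper() if pos + 2 < len(sequence) else None
    elif strand == "-":
        if base != "G":
            raise ValueError(f"base at {pos} on - strand is {base!r}, not C "
                             "(reference G expected)")
        nxt = _COMPLEMENT.get(sequence[pos - 1].upper(), "N") if pos - 1 >= 0 else None
        nxt2 = _COMPLEMENT.get(sequence[pos - 2].upper(), "N") if pos - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if nxt is None or nxt not in "ACGT":
        return None
    if nxt == "G":
        return "CG"
    if nxt2 is None or nxt2 not in "ACGT":
        return None
    return "CHG" if nxt2 == "G" else "CHH"


@dataclass(frozen=True)
class MethylationSummary:
    """Weighted methylation of one region x context for one gene."""

    species: str
    gene_id: str
    region_label: str
    context: str
    level: float | None  # None when total_reads == 0
    n_cytosines: int
    total_reads: int
    sum_m: int = 0


class CytosineIndex:
    """Per-(chrom, context) positional index with prefix sums.

    Cytosines below ``min_depth`` total reads are excluded at build time,
    so range queries are O(log n) and exact (integer prefix sums).
    Both strands are pooled.
    """

    def __init__(self, cytosines: Iterable[CytosineRecord], min_depth: int = 1):
        if min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        self.min_depth = min_depth
        buckets: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for c in cytosines:
            if c.depth >= min_depth:
                buckets.setdefault((c.chrom, c.context), []).append(
                    (c.pos, c.m, c.depth)
                )
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        self._cum_m: dict[tuple[str, str], np.ndarray] = {}
        self._cum_d: dict[tuple[str, str], np.ndarray] = {}
        for key, rows in buckets.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            m = np.array([r[1] for r in rows], dtype=np.int64)
            d = np.array([r[2] for r in rows], dtype=np.int64)
            self._pos[key] = pos
            self._cum_m[key] = np.concatenate(([0], np.cumsum(m)))
            self._cum_d[key] = np.concatenate(([0], np.cumsum(d)))

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        pos: np.ndarray,
        m: np.ndarray,
        u: np.ndarray,
        context_codes: np.ndarray,
        min_depth: int = 1,
    ) -> "CytosineIndex":
        """Build an index straight from column arrays (one chromosome).

        ``context_codes`` indexes into CG/CHG/CHH order.  Equivalent to —
        and interchangeable with — building from ``CytosineRecord`` lists,
        just without materialising per-site objects.
        """
        if min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        self = object.__new__(cls)
        self.min_depth = min_depth
        self._pos, self._cum_m, self._cum_d = {}, {}, {}
        pos = np.asarray(pos, dtype=np.int64)
        m = np.asarray(m, dtype=np.int64)
        d = m + np.asarray(u, dtype=np.int64)
        keep = d >= min_depth
        for code, context in enumerate(VALID_CONTEXTS):
            mask = keep & (np.asarray(context_codes) == code)
            p, mm, dd = pos[mask], m[mask], d[mask]
            order = np.argsort(p, kind="stable")
            p, mm, dd = p[order], mm[order], dd[order]
            key = (chrom, context)
            self._pos[key] = p
            self._cum_m[key] = np.concatenate(([0], np.cumsum(mm)))
            self._cum_d[key] = np.concatenate(([0], np.cumsum(dd)))
        return self

    def query(self, region: GenomicInterval, context: str) -> tuple[int, int, int]:
        """Return (n_cytosines, sum_m, sum_depth) for a region x context."""
        key = (region.chrom, context)
        if key not in self._pos:
            return 0, 0, 0
        pos = self._pos[key]
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        return (
            hi - lo,
            int(self._cum_m[key][hi] - self._cum_m[key][lo]),
            int(self._cum_d[key][hi] - self._cum_d[key][lo]),
        )


def weighted_methylation(
    cytosines: Sequence[CytosineRecord] | CytosineIndex,
    region: GenomicInterval,
    context: str,
    min_depth: int = 1,
    species: str = "",
    gene_id: str = "",
    region_label: str = "",
) -> MethylationSummary:
    """Weighted methylation level of one region in one context.

    ``cytosines`` may be raw records or a prebuilt :class:`CytosineIndex`
    (whose ``min_depth`` must then match).  The level is undefined (None)
    when no qualifying cytosine falls in the region.
    """
    if context not in VALID_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if isinstance(cytosines, CytosineIndex):
        if cytosines.min_depth != min_depth:
            raise ValueError("index min_depth does not match requested min_depth")
        index = cytosines
    else:
        index = CytosineIndex(cytosines, min_depth=min_depth)
    n, sum_m, sum_d = index.query(region, context)
    level = sum_m / sum_d if sum_d > 0 else None
    return MethylationSummary(
        species=species, gene_id=gene_id, region_label=region_label,
        context=context, level=level, n_cytosines=n, total_reads=sum_d,
        sum_m=sum_m,
    )


def methylation_profile(
    genes: Sequence[GeneRecord],
    regionsets: Mapping[str, RegionSet],
    cytosines: Sequence[CytosineRecord] | CytosineIndex,
    min_depth: int = 1,
) -> pd.DataFrame:
    """One row per gene x region x context with the weighted level.

    ``regionsets`` maps gene_id -> RegionSet; a gene without one is an
    error.  Row order is deterministic: (species, gene, region ordinal,
    context in CG/CHG/CHH order).  Undefined levels appear as NaN.
    """
    index = (cytosines if isinstance(cytosines, CytosineIndex)
             else CytosineIndex(cytosines, min_depth=min_depth))
    rows = []
    for gene in sorted(genes, key=lambda g: (g.species, g.gene_id)):
        try:
            rs = regionsets[gene.gene_id]
        except KeyError:
            raise ValueError(f"gene {gene.gene_id} has no RegionSet") from None
        for ordinal, (label, iv) in enumerate(rs):
            for context in VALID_CONTEXTS:
                n, sum_m, sum_d = (index.query(iv, context) if len(iv) > 0
                                   else (0, 0, 0))
                rows.append({
                    "species": gene.species,
                    "gene_id": gene.gene_id,
                    "region_label": label,
                    "region_ordinal": ordinal,
                    "context": context,
                    "level": sum_m / sum_d if sum_d > 0 else np.nan,
                    "n_cytosines": n,
                    "sum_m": sum_m,
                    "total_reads": sum_d,
                })
    return pd.DataFrame(
        rows,
        columns=["species", "gene_id", "region_label", "region_ordinal",
                 "context", "level", "n_cytosines", "sum_m", "total_reads"],
    )
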