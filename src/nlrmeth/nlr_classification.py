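"""Copy-number counting, high/low-copy cutoff selection and type I/II calls.

NLR gene families expand unevenly across species: most (species, family)
pairs hold one or two copies, while a minority carry large expansions.
Genes in expanded families (copy number above the cutoff) are called
type I — fast-evolving, high-copy — and the rest type II (conserved,
low-copy).  The cutoff is chosen where the first-order difference of the
copy-number frequency distribution flattens out; the operational default
is 5, i.e. copy number > 5 means type I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyCount:
    species: str
    family_id: str
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(frozen=True)
class CopyNumberDistribution:
    """Frequency of each copy number over all (species, family) pairs."""

    f: dict[int, float]

    @property
    def support(self) -> list[int]:
        return sorted(k for k, v in self.f.items() if v > 0)

    @classmethod
    def from_counts(cls, counts: Iterable[FamilyCount]) -> "CopyNumberDistribution":
        f: dict[int, float] = {}
        for c in counts:
            f[c.copy_number] = f.get(c.copy_number, 0) + 1
        return cls(f)


@dataclass(frozen=True)
class NLRAssignment:
    gene_id: str
    species: str
    family_id: str
    copy_number: int
    nlr_type: Literal["I", "II"]


def count_copy_numbers(
    family_table: Iterable[tuple[str, str, str]]
) -> list[FamilyCount]:
    """Tally gene counts per (species, family) pair.

    ``family_table`` holds (species, gene_id, family_id) rows; a gene
    assigned to two different families is an error.
    """
    membership: dict[tuple[str, str], str] = {}
    tally: dict[tuple[str, str], int] = {}
    for species, gene_id, family_id in family_table:
        key = (species, gene_id)
        if key in membership:
            if membership[key] != family_id:
                raise ValueError(
                    f"gene {gene_id!r} ({species}) assigned to two families: "
                    f"{membership[key]!r} and {family_id!r}"
                )
            continue  # exact duplicate row: idempotent
        membership[key] = family_id
        tally[(species, family_id)] = tally.get((species, family_id), 0) + 1
    return [
        FamilyCount(sp, fam, n)
        for (sp, fam), n in sorted(tally.items())
    ]


def select_cutoff(
    dist: CopyNumberDistribution,
    tau: float = 0.01,
    fallback: int = 5,
) -> int:
    """Pick the copy number where the frequency curve's slope stabilises.

    First-order differences between consecutive support points are
    normalised by the frequency at the smallest copy number; the cutoff is
    the smallest k from which every remaining normalised difference stays
    below ``tau`` in magnitude.  When no such k exists (including
    single-point support), ``fallback`` is returned with a warning.
    """
    support = dist.support
    if not support:
        raise ValueError("empty copy-number distribution")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    if len(support) == 1:
        logger.warning(
            "copy-number support has a single point; using fallback cutoff %d",
            fallback,
        )
        return fallback
    f0 = dist.f[support[0]]
    # normalised |f(k_i) - f(k_{i+1})| for consecutive support points
    deltas = [
        abs(dist.f[support[i]] - dist.f[support[i + 1]]) / f0
        for i in range(len(support) - 1)
    ]
    for i, k in enumerate(support[:-1]):
        # a lone stable difference at the tail is noise, not a plateau
        if len(deltas) - i >= 2 and all(d < tau for d in deltas[i:]):
            return k
    logger.warning(
        "no stable slope at tau=%g; using fallback cutoff %d", tau, fallback
    )
    return fallback


def classify_nlrs(
    counts: Iterable[FamilyCount],
    family_table: Iterable[tuple[str, str, str]],
    cutoff: int = 5,
) -> list[NLRAssignment]:
    """Assign each gene its family copy number and type.

    Copy number strictly above ``cutoff`` is type I; at or below, type II.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    cn = {(c.species, c.family_id): c.copy_number for c in counts}
    out: list[NLRAssignment] = []
    for species, gene_id, family_id in family_table:
        k = cn.get((species, family_id))
        if k is None:
            raise ValueError(
                f"no copy-number entry for ({species}, {family_id})"
            )
        out.append(
            NLRAssignment(
                gene_id=gene_id,
                species=species,
                family_id=family_id,
                copy_number=k,
                nlr_type="I" if k > cutoff else "II",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise identity (test-scale global alignment)
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _GAP = 1, -1, -2


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment.

    Scoring: match +1, mismatch -1, gap -2.  Ties in the traceback prefer
    the diagonal move, then the vertical (gap in ``seq_b``).  Identity is
    100 x identical aligned pairs / alignment columns.  Intended for
    test-scale protein comparisons, not genome-scale search.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = _GAP * np.arange(n + 1)
    score[0, :] = _GAP * np.arange(m + 1)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(a[i - 1] == b, _MATCH, _MISMATCH)
        row, prev = score[i], score[i - 1]
        # vectorise diagonal+up, then resolve the left-dependency serially
        diag = prev[:-1] + sub
        up = prev[1:] + _GAP
        best = np.maximum(diag, up)
        acc = row[0]
        for j in range(m):
            acc = max(best[j], acc + _GAP)
            row[j + 1] = acc
    # traceback, diagonal preferred, then up, then left
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = _MATCH if seq_a[i - 1] == seq_b[j - 1] else _MISMATCH
            if score[i, j] == score[i - 1, j - 1] + sub:
                matches += seq_a[i - 1] == seq_b[j - 1]
                i, j = i - 1, j - 1
                cols += 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + _GAP:
            i -= 1
        else:
            j -= 1
        cols += 1
    return 100.0 * matches / cols


# ---------------------------------------------------------------------------
# Group similarity comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityComparison:
    """Outcome of the high-copy vs low-copy within-family identity test."""

    high_group_means: tuple[float, ...]
    low_group_means: tuple[float, ...]
    statistic: float
    p_value: float
    direction: str  # "high < low", "high > low" or "equal"
    testable: bool
    test: str


def compare_group_similarity(
    similarities: Sequence,
    assignments: Sequence[NLRAssignment],
    test: Literal["welch", "wilcoxon"] = "welch",
) -> SimilarityComparison:
    """Test whether expanded (type I) families are more diverged.

    Each similarity record is attributed to the (species, family) group of
    its two genes; per-group mean identity is the unit of observation
    (pooling raw pairs would pseudo-replicate large families).  Group means
    are then compared between high-copy (type I) and low-copy (type II)
    families with Welch's t-test or the Wilcoxon rank-sum test.
    """
    by_gene = {(a.species, a.gene_id): a for a in assignments}
    # gene_id lookup without species when unambiguous
    by_id: dict[str, NLRAssignment] = {}
    ambiguous: set[str] = set()
    for a in assignments:
        if a.gene_id in by_id and by_id[a.gene_id] is not a:
            ambiguous.add(a.gene_id)
        by_id[a.gene_id] = a

    def lookup(gene_id: str) -> NLRAssignment:
        if gene_id in ambiguous:
            raise ValueError(
                f"gene id {gene_id!r} is ambiguous across species; "
                "similarity records cannot be attributed"
            )
        try:
            return by_id[gene_id]
        except KeyError:
            raise ValueError(f"gene {gene_id!r} has no NLR assignment") from None

    groups: dict[tuple[str, str, str], list[float]] = {}
    for rec in similarities:
        qa, sa = lookup(rec.query_id), lookup(rec.subject_id)
        if (qa.species, qa.family_id) != (sa.species, sa.family_id):
            raise ValueError(
                f"similarity pair ({rec.query_id}, {rec.subject_id}) spans "
                "two (species, family) groups"
            )
        key = (qa.species, qa.family_id, qa.nlr_type)
        groups.setdefault(key, []).append(rec.percent_identity)

    high = tuple(
        float(np.mean(v)) for (sp, fam, t), v in sorted(groups.items()) if t == "I"
    )
    low = tuple(
        float(np.mean(v)) for (sp, fam, t), v in sorted(groups.items()) if t == "II"
    )
    if len(high) < 2 or len(low) < 2:
        return SimilarityComparison(high, low, float("nan"), float("nan"),
                                    "equal", False, test)
    if test == "welch":
        res = stats.ttest_ind(high, low, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # zero variance, equal means
            stat, p = 0.0, 1.0
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(high, low, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    mh, ml = float(np.mean(high)), float(np.mean(low))
    direction = "high < low" if mh < ml else ("high > low" if mh > ml else "equal")
    return SimilarityComparison(high, low, stat, p, direction, True, test)
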