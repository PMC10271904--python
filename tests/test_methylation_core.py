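"""Context classification and weighted methylation arithmetic."""

import numpy as np
import pytest

from nlrmeth import (
    CytosineIndex,
    CytosineRecord,
    GeneRecord,
    GenomicInterval,
    classify_context,
    methylation_profile,
    weighted_methylation,
)
from nlrmeth.region_model import build_coarse_regions, build_metagene_regions


class TestClassifyContext:
    @pytest.mark.parametrize("seq,pos,strand,expected", [
        ("CCGG", 0, "+", "CHG"),
        ("CCGG", 1, "+", "CG"),
        ("CCGG", 3, "-", "CHG"),  # minus read from pos 3: C,C,G
        ("CCGG", 2, "-", "CG"),   # minus read from pos 2: C,G
        ("CATG", 0, "+", "CHH"),  # C,A,T
        ("CAGT", 0, "+", "CHG"),
        ("ACGT", 1, "+", "CG"),
        ("TTGA", 2, "-", "CHH"),  # minus read from pos 2: C,A,A
    ])
    def test_rule_application(self, seq, pos, strand, expected):
        assert classify_context(seq, pos, strand) == expected

    def test_insufficient_downstream_bases(self):
        assert classify_context("AAC", 2, "+") is None     # C at last position
        assert classify_context("ACA", 1, "+") is None     # CHx needs 2 bases
        assert classify_context("GAA", 0, "-") is None     # nothing 5' of pos 0

    def test_ambiguous_base_gives_none(self):
        assert classify_context("CNG", 0, "+") is None
        assert classify_context("CANG", 0, "+") is None

    def test_wrong_base_or_position_rejected(self):
        with pytest.raises(ValueError):
            classify_context("ACGT", 0, "+")   # A, not C
        with pytest.raises(ValueError):
            classify_context("ACGT", 1, "-")   # C on minus needs reference G
        with pytest.raises(ValueError):
            classify_context("ACGT", 9, "+")

    def test_cg_symmetry_on_random_sequence(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        plus = sum(
            classify_context(seq, i, "+") == "CG"
            for i in range(len(seq)) if seq[i] == "C"
        )
        minus = sum(
            classify_context(seq, i, "-") == "CG"
            for i in range(len(seq)) if seq[i] == "G"
        )
        assert plus == minus  # CG sites are palindromic


def _records():
    return [
        CytosineRecord("chr1", 10, "+", 3, 1, "CHH"),
        CytosineRecord("chr1", 12, "-", 1, 3, "CHH"),
        CytosineRecord("chr1", 14, "+", 5, 0, "CG"),
        CytosineRecord("chr1", 100, "+", 9, 9, "CHH"),  # outside region
        CytosineRecord("chr1", 15, "+", 0, 0, "CHH"),   # zero coverage
    ]


class TestWeightedMethylation:
    def test_ratio_of_summed_counts(self):
        region = GenomicInterval("chr1", 0, 50)
        s = weighted_methylation(_records(), region, "CHH")
        assert s.level == pytest.approx(4 / 8)
        assert s.n_cytosines == 2 and s.total_reads == 8

    def test_fully_methylated_region(self):
        recs = [CytosineRecord("chr1", i, "+", 4, 0, "CG") for i in range(5)]
        s = weighted_methylation(recs, GenomicInterval("chr1", 0, 10), "CG")
        assert s.level == 1.0

    def test_uncovered_region_is_undefined(self):
        s = weighted_methylation(_records(), GenomicInterval("chr1", 200, 300),
                                 "CHH")
        assert s.level is None and s.n_cytosines == 0

    def test_min_depth_excludes_shallow_sites(self):
        region = GenomicInterval("chr1", 0, 50)
        s = weighted_methylation(_records(), region, "CHH", min_depth=1)
        s5 = weighted_methylation(_records(), region, "CHH", min_depth=5)
        assert s.n_cytosines == 2 and s5.n_cytosines == 0

    def test_conservation_under_partition(self):
        """Splitting a region anywhere leaves the pooled level unchanged."""
        recs = _records()
        whole = weighted_methylation(recs, GenomicInterval("chr1", 0, 120), "CHH")
        for cut in (5, 11, 13, 60, 101):
            a = weighted_methylation(recs, GenomicInterval("chr1", 0, cut), "CHH")
            b = weighted_methylation(recs, GenomicInterval("chr1", cut, 120), "CHH")
            total_m = (a.sum_m + b.sum_m)
            total_d = (a.total_reads + b.total_reads)
            assert total_m / total_d == whole.level


class TestMethylationProfile:
    def test_row_cardinality_and_order(self):
        genes = [
            GeneRecord("g1", "sp", GenomicInterval("chr1", 50_000, 52_000, "+")),
            GeneRecord("g2", "sp", GenomicInterval("chr1", 80_000, 82_000, "-")),
        ]
        rs = {g.gene_id: build_coarse_regions(g, 10**6) for g in genes}
        df = methylation_profile(genes, rs, _records())
        assert len(df) == 2 * 9 * 3
        assert list(df["gene_id"].unique()) == ["g1", "g2"]
        first = df.iloc[:3]
        assert list(first["context"]) == ["CG", "CHG", "CHH"]

    def test_missing_regionset_is_an_error(self):
        genes = [GeneRecord("g1", "sp",
                            GenomicInterval("chr1", 50_000, 52_000, "+"))]
        with pytest.raises(ValueError, match="g1"):
            methylation_profile(genes, {}, _records())

    def test_index_from_arrays_matches_record_index(
            self, small_species, small_cytosine_records):
        """The columnar and record-based index constructions are one index."""
        from nlrmeth.synthetic_data import CONTEXT_NAMES

        cyt = small_species.cytosines
        idx_arr = CytosineIndex.from_arrays(cyt.chrom, cyt.pos, cyt.m, cyt.u,
                                            cyt.context)
        idx_rec = CytosineIndex(small_cytosine_records)
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = int(rng.integers(0, small_species.chrom_length - 5000))
            region = GenomicInterval(cyt.chrom, s, s + int(rng.integers(1, 5000)))
            ctx = CONTEXT_NAMES[int(rng.integers(0, 3))]
            assert idx_arr.query(region, ctx) == idx_rec.query(region, ctx)
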