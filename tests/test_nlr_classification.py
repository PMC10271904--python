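"""Copy-number counting, cutoff selection, identity and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrmeth import (
    CopyNumberDistribution,
    SimilarityRecord,
    classify_nlrs,
    compare_group_similarity,
    count_copy_numbers,
    pairwise_identity,
    select_cutoff,
)

EXAMPLE_F = {1: 500, 2: 200, 3: 80, 4: 40, 5: 20, 6: 18, 7: 17, 8: 16}


class TestCountCopyNumbers:
    def test_counts_per_species_family_pair(self):
        table = [("spA", "g1", "F1"), ("spA", "g2", "F1"), ("spB", "g3", "F1")]
        counts = count_copy_numbers(table)
        assert [(c.species, c.family_id, c.copy_number) for c in counts] == [
            ("spA", "F1", 2), ("spB", "F1", 1)]

    def test_empty_table(self):
        assert count_copy_numbers([]) == []

    def test_gene_in_two_families_is_an_error(self):
        with pytest.raises(ValueError, match="two families"):
            count_copy_numbers([("spA", "g1", "F1"), ("spA", "g1", "F2")])


class TestSelectCutoff:
    def test_worked_distribution_gives_five(self):
        assert select_cutoff(CopyNumberDistribution(EXAMPLE_F), tau=0.01) == 5

    def test_single_support_point_falls_back(self):
        assert select_cutoff(CopyNumberDistribution({1: 10})) == 5

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(CopyNumberDistribution({}))

    @pytest.mark.parametrize("scale", [0.5, 3, 1000])
    def test_scale_invariance(self, scale):
        scaled = {k: v * scale for k, v in EXAMPLE_F.items()}
        assert select_cutoff(CopyNumberDistribution(scaled), tau=0.01) == 5


class TestClassify:
    @pytest.mark.parametrize("copies,expected", [(6, "I"), (5, "II"), (1, "II")])
    def test_boundary(self, copies, expected):
        table = [("sp", f"g{i}", "F1") for i in range(copies)]
        assignments = classify_nlrs(count_copy_numbers(table), table, cutoff=5)
        assert {a.nlr_type for a in assignments} == {expected}

    @given(st.integers(min_value=1, max_value=30))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_copy_number(self, copies):
        """Raising a family's copy number never demotes type I to type II."""
        t1 = [("sp", f"g{i}", "F") for i in range(copies)]
        t2 = t1 + [("sp", f"g{copies}", "F")]
        a1 = classify_nlrs(count_copy_numbers(t1), t1, cutoff=5)[0].nlr_type
        a2 = classify_nlrs(count_copy_numbers(t2), t2, cutoff=5)[0].nlr_type
        assert (a1, a2) != ("I", "II")


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKV", "MKV") == 100.0

    def test_single_mismatch(self):
        assert pairwise_identity("ACDE", "ACDF") == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("A", "")

    def test_gap_handling(self):
        # one deletion: 4 matching columns out of 5
        assert pairwise_identity("MKVLE", "MKVE") == pytest.approx(80.0)

    @given(st.text(alphabet="ACDEG", min_size=1, max_size=12),
           st.text(alphabet="ACDEG", min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_100_iff_identical(self, a, b):
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        assert (pairwise_identity(a, b) == 100.0) == (a == b)


class TestCompareGroupSimilarity:
    @staticmethod
    def _setup(high_means, low_means):
        """Build one-pair families whose mean identities equal the inputs."""
        table, sims = [], []
        for i, ident in enumerate(high_means):
            fam = f"H{i}"
            genes = [f"h{i}_{j}" for j in range(6)]
            table += [("sp", g, fam) for g in genes]
            sims.append(SimilarityRecord(genes[0], genes[1], ident))
        for i, ident in enumerate(low_means):
            fam = f"L{i}"
            genes = [f"l{i}_{j}" for j in range(2)]
            table += [("sp", g, fam) for g in genes]
            sims.append(SimilarityRecord(genes[0], genes[1], ident))
        assignments = classify_nlrs(count_copy_numbers(table), table, cutoff=5)
        return sims, assignments

    def test_diverged_high_copy_detected(self):
        sims, assignments = self._setup([60, 62, 61], [90, 91, 92])
        res = compare_group_similarity(sims, assignments)
        assert res.direction == "high < low"
        assert res.p_value < 0.01
        assert sorted(res.high_group_means) == [60, 61, 62]
        assert res.testable

    def test_identical_groups_give_null_result(self):
        sims, assignments = self._setup([80, 85, 90], [80, 85, 90])
        res = compare_group_similarity(sims, assignments)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_not_testable(self):
        sims, assignments = self._setup([60, 61], [90])
        res = compare_group_similarity(sims, assignments)
        assert not res.testable
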