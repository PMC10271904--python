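"""Generator: determinism, self-consistency, and planted structure."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from nlrmeth import (
    SyntheticConfig,
    classify_context,
    generate_dataset,
    score_recovery,
    write_dataset,
)
from nlrmeth.synthetic_data import CONTEXT_NAMES, _distance_to_intervals
from nlrmeth.io_formats import GenomicInterval

from conftest import small_config


class TestDeterminism:
    def test_regeneration_is_bit_identical(self, tmp_path):
        cfg = small_config()
        a = generate_dataset(cfg, seed=5)
        b = generate_dataset(cfg, seed=5)
        assert a.dataset_id == b.dataset_id
        sa, sb = a.species[0], b.species[0]
        assert sa.sequence == sb.sequence
        assert np.array_equal(sa.cytosines.m, sb.cytosines.m)
        assert sa.genes == sb.genes and sa.te_intervals == sb.te_intervals

    def test_written_files_are_byte_identical(self, tmp_path):
        cfg = small_config()
        for d in ("run1", "run2"):
            write_dataset(generate_dataset(cfg, seed=9), tmp_path / d)
        files = sorted(p.relative_to(tmp_path / "run1")
                       for p in (tmp_path / "run1").rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(tmp_path / "run1" / rel, tmp_path / "run2" / rel,
                               shallow=False), rel

    def test_different_seeds_differ(self):
        a = generate_dataset(small_config(), seed=1)
        b = generate_dataset(small_config(), seed=2)
        assert a.species[0].sequence != b.species[0].sequence


class TestSelfConsistency:
    def test_cx_contexts_rederivable_from_sequence(self, small_species):
        """Every emitted cytosine's context matches a fresh classification
        of the emitted genome sequence."""
        cyt = small_species.cytosines
        seq = small_species.sequence
        idx = np.random.default_rng(0).choice(len(cyt), size=2000,
                                              replace=False)
        for i in idx:
            strand = "+" if cyt.strand[i] == 0 else "-"
            assert classify_context(seq, int(cyt.pos[i]), strand) == \
                CONTEXT_NAMES[cyt.context[i]]

    def test_genes_fit_chromosome_with_clearance(self, small_species):
        genes = sorted(small_species.genes, key=lambda g: g.interval.start)
        for g1, g2 in zip(genes, genes[1:]):
            assert g2.interval.start >= g1.interval.end
        assert genes[-1].interval.end <= small_species.chrom_length

    def test_te_distal_background_mean(self, small_species):
        """Far from any TE the CHH level converges to the configured
        background within Monte-Carlo error."""
        cyt = small_species.cytosines
        dist = _distance_to_intervals(cyt.pos, small_species.te_intervals)
        far = (dist > 10_000) & (cyt.context == 2)
        m, d = cyt.m[far], (cyt.m[far] + cyt.u[far])
        level = m.sum() / d.sum()
        mu = 0.03
        # beta-binomial: per-read variance inflated by (1 + (E[depth]-1)/(k+1))
        kappa, lam = 50.0, 10.0
        var_per_read = mu * (1 - mu) * (1 + (lam - 1) / (kappa + 1))
        se = np.sqrt(var_per_read / d.sum())
        assert abs(level - mu) < 3 * se


class TestPlantedStructure:
    def test_te_enrichment_near_type_one_genes(self, small_dataset):
        truth = small_dataset.truth.genes
        frac_I = truth[truth.nlr_type == "I"]["te_planted"].mean()
        frac_II = truth[truth.nlr_type == "II"]["te_planted"].mean()
        assert frac_I > frac_II

    def test_copy_numbers_match_type_definition(self, small_dataset):
        truth = small_dataset.truth.genes
        assert (truth.loc[truth.nlr_type == "I", "copy_number"] > 5).all()
        assert (truth.loc[truth.nlr_type == "II", "copy_number"] <= 5).all()

    def test_high_copy_families_are_more_diverged(self, small_species):
        fam_of = {g: f for (_, g, f) in small_species.family_rows}
        high, low = [], []
        for q, s, ident, _ in small_species.similarity_rows:
            (high if "famI" in fam_of[q] and "famII" not in fam_of[q]
             else low).append(ident)
        assert np.mean(high) < np.mean(low)

    def test_null_config_has_no_planted_contrast(self):
        cfg = small_config(
            te_insertion_prob_typeI=0.3, te_insertion_prob_typeII=0.3,
            te_effect={"CG": 0.0, "CHG": 0.0, "CHH": 0.0})
        ds = generate_dataset(cfg, seed=21)
        truth = ds.truth.genes
        # types still defined by copy number, but TEs unbiased
        assert abs(truth[truth.nlr_type == "I"]["te_planted"].mean()
                   - truth[truth.nlr_type == "II"]["te_planted"].mean()) < 0.5


class TestScoreRecovery:
    def test_mismatched_dataset_ids_rejected(self, small_dataset):
        import pandas as pd

        with pytest.raises(ValueError, match="dataset"):
            score_recovery({"dataset_id": "other", "meth_screen": pd.DataFrame(),
                            "assignments": [], "cutoff": 5},
                           small_dataset.truth)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(te_insertion_prob_typeI=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(beta_precision=0.0)
    with pytest.raises(ValueError):
        SyntheticConfig(copy_number_law={1: 0.5, 2: 0.4})
    with pytest.raises(ValueError, match="chrom_length"):
        generate_dataset(small_config(chrom_length=50_000), seed=0)
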