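"""Welch tests, screens, pooled consensus tests and overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from nlrmeth import NLRAssignment, welch_t_test
from nlrmeth.group_stats import (
    overlap_analysis,
    per_species_screen,
    pooled_consensus_table,
    pooled_consensus_test,
)


class TestWelch:
    def test_closed_form_example(self):
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0213, abs=1e-4)

    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 20))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 20))
            a, b = welch_t_test(x, y), welch_t_test(y, x)
            assert a.t == pytest.approx(-b.t)
            assert a.p == pytest.approx(b.p)
            assert a.df == pytest.approx(b.df)

    def test_small_samples_not_testable(self):
        assert not welch_t_test([1.0], [2.0, 3.0]).testable

    def test_matches_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(scale=3.0, size=rng.integers(3, 30))
            mine = welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert mine.t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert mine.p == pytest.approx(float(ref.pvalue), abs=1e-10)


def _values_frame(levels_I, levels_II, species="spA", feature="mCHH",
                  region="upstream"):
    rows = []
    for i, v in enumerate(levels_I):
        rows.append((species, f"t1_{i}", feature, region, v))
    for i, v in enumerate(levels_II):
        rows.append((species, f"t2_{i}", feature, region, v))
    return pd.DataFrame(
        rows, columns=["species", "gene_id", "feature", "region_label", "value"])


def _assignments(levels_I, levels_II, species="spA"):
    out = []
    for i in range(len(levels_I)):
        out.append(NLRAssignment(f"t1_{i}", species, "F1", 8, "I"))
    for i in range(len(levels_II)):
        out.append(NLRAssignment(f"t2_{i}", species, "F2", 2, "II"))
    return out


class TestScreen:
    def test_planted_difference_flagged(self):
        rng = np.random.default_rng(0)
        hi = rng.normal(0.15, 0.02, size=40)
        lo = rng.normal(0.05, 0.02, size=40)
        screen = per_species_screen(_values_frame(hi, lo),
                                    _assignments(hi, lo), alpha=0.01)
        row = screen.iloc[0]
        assert row["significant"] and row["mean_typeI"] > row["mean_typeII"]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(1)
        frames, assigns = [], []
        for s in range(12):
            hi = rng.normal(0.08, 0.03, size=10)
            lo = rng.normal(0.05, 0.03, size=10)
            frames.append(_values_frame(hi, lo, species=f"sp{s}"))
            assigns += _assignments(hi, lo, species=f"sp{s}")
        vals = pd.concat(frames, ignore_index=True)
        strict = per_species_screen(vals, assigns, alpha=0.001)
        loose = per_species_screen(vals, assigns, alpha=0.01)
        sig_strict = set(strict[strict.significant]["species"])
        sig_loose = set(loose[loose.significant]["species"])
        assert sig_strict <= sig_loose

    def test_tiny_group_not_testable(self):
        screen = per_species_screen(
            _values_frame([0.1, 0.2, 0.3, 0.4], [0.1]),
            _assignments([0.1, 0.2, 0.3, 0.4], [0.1]))
        assert not screen.iloc[0]["testable"]
        assert not screen.iloc[0]["significant"]


class TestPooled:
    def test_single_significant_species_reduces_to_its_screen_test(self):
        rng = np.random.default_rng(2)
        hi = rng.normal(0.15, 0.02, size=20)
        lo = rng.normal(0.05, 0.02, size=20)
        vals = _values_frame(hi, lo)
        assigns = _assignments(hi, lo)
        screen = per_species_screen(vals, assigns, alpha=0.01)
        pooled = pooled_consensus_test(vals, screen, assigns, "mCHH",
                                       "upstream", alpha=0.01)
        assert pooled["n_species"] == 1
        assert pooled["t_stat"] == pytest.approx(screen.iloc[0]["t_stat"])
        assert pooled["p_value"] == pytest.approx(screen.iloc[0]["p_value"])

    def test_empty_significant_set_flagged_undefined(self):
        vals = _values_frame([0.1, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.1])
        assigns = _assignments([0.1] * 4, [0.1] * 4)
        screen = per_species_screen(vals, assigns, alpha=0.01)
        pooled = pooled_consensus_test(vals, screen, assigns, "mCHH",
                                       "upstream")
        assert not pooled["testable"] and pooled["n_species"] == 0

    def test_pooling_two_species_with_same_effect_increases_evidence(self):
        rng = np.random.default_rng(3)
        frames, assigns = [], []
        for s in ("spA", "spB"):
            hi = rng.normal(0.12, 0.03, size=15)
            lo = rng.normal(0.05, 0.03, size=15)
            frames.append(_values_frame(hi, lo, species=s))
            assigns += _assignments(hi, lo, species=s)
        vals = pd.concat(frames, ignore_index=True)
        screen = per_species_screen(vals, assigns, alpha=0.01)
        assert screen["significant"].all()
        pooled = pooled_consensus_test(vals, screen, assigns, "mCHH",
                                       "upstream", alpha=0.01)
        assert pooled["p_value"] <= screen["p_value"].max()


def _screen_frame(rows):
    return pd.DataFrame(
        [
            {"species": sp, "feature": feat, "region_label": reg,
             "significant": sig, "testable": True, "p_value": 0.001 if sig else 0.5}
            for sp, feat, reg, sig in rows
        ]
    )


class TestOverlap:
    def test_set_arithmetic(self):
        meth = _screen_frame([(s, "mCHH", "upstream", True)
                              for s in "ABC"])
        te = _screen_frame([(s, "TE", "body", True) for s in "BCD"])
        (res,) = overlap_analysis(meth, te, features=("mCHH",))
        assert res.overlap_count == 2
        assert res.overlap_percent == pytest.approx(200 / 3)

    def test_disjoint_and_subset(self):
        meth = _screen_frame([("A", "mCHG", "body", True)])
        te_disjoint = _screen_frame([("B", "TE", "body", True)])
        te_superset = _screen_frame([("A", "TE", "upstream", True),
                                     ("B", "TE", "body", True)])
        (r1,) = overlap_analysis(meth, te_disjoint, features=("mCHG",))
        (r2,) = overlap_analysis(meth, te_superset, features=("mCHG",))
        assert r1.overlap_percent == 0.0
        assert r2.overlap_percent == 100.0

    def test_matched_region_is_stricter(self):
        meth = _screen_frame([("A", "mCHH", "upstream", True)])
        te = _screen_frame([("A", "TE", "body", True)])
        (any_r,) = overlap_analysis(meth, te, "any_region", features=("mCHH",))
        (match_r,) = overlap_analysis(meth, te, "matched_region",
                                      features=("mCHH",))
        assert any_r.overlap_percent == 100.0
        assert match_r.overlap_percent == 0.0

    def test_empty_meth_set_undefined(self):
        meth = _screen_frame([("A", "mCHH", "upstream", False)])
        te = _screen_frame([("A", "TE", "body", True)])
        (res,) = overlap_analysis(meth, te, features=("mCHH",))
        assert res.overlap_percent is None and not res.defined
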