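"""Two-group screens, pooled consensus-region tests, and the
methylation x TE overlap statistic.

The unit of observation throughout is the gene: each gene contributes one
weighted methylation level (per context) or one TE coverage value per
aggregated region (upstream 20 kb, gene body, downstream 20 kb).  Per
species x feature x region, type I and type II genes are compared with
Welch's t-test; species significant for a (feature, region) stratum define
its "consensus region", on which a pooled test across those species' genes
is run.  Finally, the overlap stage asks what fraction of species with a
significant non-CG methylation difference also shows a significant TE
coverage difference.

The significance threshold defaults to alpha = 0.001; 0.01 is offered as
well because published per-species screens of this design have used both.
No multiple-testing correction is applied by default (a Benjamini-
Hochberg option exists).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nlr_classification import NLRAssignment

logger = logging.getLogger(__name__)

METH_FEATURES = ("mCG", "mCHG", "mCHH")
_CONTEXT_TO_FEATURE = {"CG": "mCG", "CHG": "mCHG", "CHH": "mCHH"}
CONSENSUS_REGIONS = ("upstream", "body", "downstream")


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchTTest:
    t: float
    df: float
    p: float
    testable: bool


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchTTest:
    """Two-sided Welch's t-test (unequal variances).

    Degenerate cases: fewer than two observations on either side is
    not-testable; zero variance on both sides with equal means gives
    t = 0, p = 1; zero variance with unequal means gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return WelchTTest(math.nan, math.nan, math.nan, False)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    dmean = x.mean() - y.mean()
    if se2 == 0.0:
        if dmean == 0.0:
            return WelchTTest(0.0, float(nx + ny - 2), 1.0, True)
        return WelchTTest(math.copysign(math.inf, dmean),
                          float(nx + ny - 2), 0.0, True)
    t = dmean / math.sqrt(se2)
    df = se2 ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchTTest(float(t), float(df), p, True)


# ---------------------------------------------------------------------------
# Value tables: one observation per gene x feature x aggregated region
# ---------------------------------------------------------------------------

def _flank_group(label: str) -> str | None:
    if label.startswith("up"):
        return "upstream"
    if label.startswith("down"):
        return "downstream"
    if label == "body":
        return "body"
    return None


def meth_values(profile: pd.DataFrame) -> pd.DataFrame:
    """Collapse a coarse methylation profile to gene-level region values.

    The four 5 kb flank bins on each side are combined by summing
    methylated and total read counts, which reproduces the weighted level
    of the whole 20 kb flank exactly.  Output columns: species, gene_id,
    feature, region_label (upstream/body/downstream), value.
    """
    df = profile.copy()
    df["region_label"] = df["region_label"].map(_flank_group)
    df = df.dropna(subset=["region_label"])
    grouped = df.groupby(
        ["species", "gene_id", "context", "region_label"], as_index=False
    )[["sum_m", "total_reads"]].sum()
    grouped["value"] = np.where(
        grouped["total_reads"] > 0,
        grouped["sum_m"] / grouped["total_reads"].replace(0, 1),
        np.nan,
    )
    grouped["feature"] = grouped["context"].map(_CONTEXT_TO_FEATURE)
    return grouped[["species", "gene_id", "feature", "region_label", "value"]]


def te_values(te_profile: pd.DataFrame) -> pd.DataFrame:
    """Collapse a coarse TE coverage profile to gene-level region values.

    Flank bins combine by summing covered bp and region lengths — the
    length-weighted mean, i.e. coverage of the whole flank.  Feature is
    always ``TE``; value is a percentage.
    """
    df = te_profile.copy()
    df["region_label"] = df["region_label"].map(_flank_group)
    df = df.dropna(subset=["region_label"])
    grouped = df.groupby(
        ["species", "gene_id", "region_label"], as_index=False
    )[["covered_bp", "region_length"]].sum()
    grouped["value"] = np.where(
        grouped["region_length"] > 0,
        100.0 * grouped["covered_bp"] / grouped["region_length"].replace(0, 1),
        np.nan,
    )
    grouped["feature"] = "TE"
    return grouped[["species", "gene_id", "feature", "region_label", "value"]]


# ---------------------------------------------------------------------------
# Per-species screen
# ---------------------------------------------------------------------------

_SCREEN_COLUMNS = [
    "species", "feature", "region_label", "n_typeI", "n_typeII",
    "mean_typeI", "mean_typeII", "t_stat", "df", "p_value",
    "significant", "testable",
]


def per_species_screen(
    values: pd.DataFrame,
    assignments: Sequence[NLRAssignment],
    alpha: float = 0.001,
    min_group_n: int = 3,
    correction: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Type I vs type II Welch test per species x feature x region.

    A stratum is testable when both types contribute at least
    ``min_group_n`` non-missing values; ``significant`` requires
    testability and p < alpha.  With ``correction="bh"`` the
    Benjamini-Hochberg adjustment is applied across all testable strata
    before thresholding.
    """
    type_of = {(a.species, a.gene_id): a.nlr_type for a in assignments}
    df = values.copy()
    df["nlr_type"] = [
        type_of.get((sp, g)) for sp, g in zip(df["species"], df["gene_id"])
    ]
    missing = df["nlr_type"].isna()
    if missing.any():
        logger.warning("%d value rows without NLR assignment dropped",
                       int(missing.sum()))
        df = df[~missing]
    rows = []
    for (species, feature, region), sub in df.groupby(
        ["species", "feature", "region_label"], sort=True
    ):
        x = sub.loc[sub["nlr_type"] == "I", "value"].dropna().to_numpy()
        y = sub.loc[sub["nlr_type"] == "II", "value"].dropna().to_numpy()
        if len(x) == 0 and len(y) == 0:
            logger.info("species %s lacks both types for %s/%s; skipped",
                        species, feature, region)
            continue
        res = welch_t_test(x, y)
        testable = res.testable and len(x) >= min_group_n and len(y) >= min_group_n
        rows.append({
            "species": species, "feature": feature, "region_label": region,
            "n_typeI": len(x), "n_typeII": len(y),
            "mean_typeI": float(np.mean(x)) if len(x) else np.nan,
            "mean_typeII": float(np.mean(y)) if len(y) else np.nan,
            "t_stat": res.t, "df": res.df,
            "p_value": res.p if testable else np.nan,
            "significant": False, "testable": testable,
        })
    out = pd.DataFrame(rows, columns=_SCREEN_COLUMNS)
    if out.empty:
        return out
    testable_mask = out["testable"] & out["p_value"].notna()
    pvals = out.loc[testable_mask, "p_value"].to_numpy()
    if correction == "bh" and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    elif correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    out.loc[testable_mask, "significant"] = pvals < alpha
    return out


def species_counts_per_region(screen: pd.DataFrame) -> pd.DataFrame:
    """Number of significant species per feature x region (tally table)."""
    sig = screen[screen["significant"]]
    return (
        sig.groupby(["feature", "region_label"])
        .agg(n_species=("species", "nunique"))
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Pooled consensus-region test
# ---------------------------------------------------------------------------

def pooled_consensus_test(
    values: pd.DataFrame,
    screen: pd.DataFrame,
    assignments: Sequence[NLRAssignment],
    feature: str,
    region_label: str,
    alpha: float = 0.001,
    min_group_n: int = 3,
) -> pd.Series:
    """Pool genes from the species significant for (feature, region) and
    run one Welch test of type I vs type II on the pooled values.

    With no significant species the result is flagged not-testable.  With
    one significant species the pooled test coincides with that species'
    screen test.
    """
    sig_species = set(
        screen.loc[
            screen["significant"]
            & (screen["feature"] == feature)
            & (screen["region_label"] == region_label),
            "species",
        ]
    )
    base = {"species": "pooled", "feature": feature, "region_label": region_label}
    if not sig_species:
        return pd.Series({**base, "n_typeI": 0, "n_typeII": 0,
                          "mean_typeI": np.nan, "mean_typeII": np.nan,
                          "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
                          "significant": False, "testable": False,
                          "n_species": 0})
    type_of = {(a.species, a.gene_id): a.nlr_type for a in assignments}
    sub = values[
        (values["feature"] == feature)
        & (values["region_label"] == region_label)
        & values["species"].isin(sig_species)
    ]
    tt = np.array([
        type_of.get((sp, g), "")
        for sp, g in zip(sub["species"], sub["gene_id"])
    ])
    x = sub.loc[tt == "I", "value"].dropna().to_numpy()
    y = sub.loc[tt == "II", "value"].dropna().to_numpy()
    res = welch_t_test(x, y)
    testable = res.testable and len(x) >= min_group_n and len(y) >= min_group_n
    return pd.Series({
        **base, "n_typeI": len(x), "n_typeII": len(y),
        "mean_typeI": float(np.mean(x)) if len(x) else np.nan,
        "mean_typeII": float(np.mean(y)) if len(y) else np.nan,
        "t_stat": res.t, "df": res.df,
        "p_value": res.p if testable else np.nan,
        "significant": bool(testable and res.p < alpha),
        "testable": testable,
        "n_species": len(sig_species),
    })


def pooled_consensus_table(
    values: pd.DataFrame,
    screen: pd.DataFrame,
    assignments: Sequence[NLRAssignment],
    alpha: float = 0.001,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Pooled test for every feature x consensus region in the screen."""
    rows = [
        pooled_consensus_test(values, screen, assignments, feature, region,
                              alpha=alpha, min_group_n=min_group_n)
        for feature in screen["feature"].unique()
        for region in CONSENSUS_REGIONS
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Methylation x TE overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """Fraction of methylation-significant species that are also
    TE-significant, per non-CG feature."""

    feature: str
    mode: str
    species_meth_sig: frozenset[str]
    species_te_sig: frozenset[str]
    overlap_count: int
    overlap_percent: float | None  # None when no meth-significant species

    @property
    def defined(self) -> bool:
        return self.overlap_percent is not None


def _sig_species(screen: pd.DataFrame, features: Iterable[str]) -> dict[str, set[str]]:
    """species -> set of significant region labels, for the given features."""
    sig = screen[screen["significant"] & screen["feature"].isin(list(features))]
    out: dict[str, set[str]] = {}
    for _, row in sig.iterrows():
        out.setdefault(row["species"], set()).add(row["region_label"])
    return out


def overlap_analysis(
    meth_screen: pd.DataFrame,
    te_screen: pd.DataFrame,
    mode: Literal["any_region", "matched_region"] = "any_region",
    features: Sequence[str] = ("mCHG", "mCHH", "nonCG"),
) -> list[OverlapResult]:
    """Overlap between non-CG-methylation-significant and TE-significant
    species.

    ``any_region`` counts a species as overlapping when it is significant
    for the feature in any region and for TE coverage in any region;
    ``matched_region`` requires the same region on both sides.  The
    ``nonCG`` pseudo-feature combines mCHG and mCHH.
    """
    if mode not in ("any_region", "matched_region"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    te_by_species = _sig_species(te_screen, ["TE"])
    results = []
    for feature in features:
        feats = ("mCHG", "mCHH") if feature == "nonCG" else (feature,)
        meth_by_species = _sig_species(meth_screen, feats)
        if mode == "any_region":
            overlap = {
                sp for sp in meth_by_species if sp in te_by_species
            }
        else:
            overlap = {
                sp for sp, regions in meth_by_species.items()
                if regions & te_by_species.get(sp, set())
            }
        n_meth = len(meth_by_species)
        results.append(OverlapResult(
            feature=feature, mode=mode,
            species_meth_sig=frozenset(meth_by_species),
            species_te_sig=frozenset(te_by_species),
            overlap_count=len(overlap),
            overlap_percent=(100.0 * len(overlap) / n_meth) if n_meth else None,
        ))
    return results


def overlap_table(results: Sequence[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "feature": r.feature,
            "mode": r.mode,
            "n_meth_sig": len(r.species_meth_sig),
            "n_te_sig": len(r.species_te_sig),
            "overlap_count": r.overlap_count,
            "overlap_percent": (np.nan if r.overlap_percent is None
                                else r.overlap_percent),
            "species_meth_sig": ",".join(sorted(r.species_meth_sig)),
            "species_te_sig": ",".join(sorted(r.species_te_sig)),
        }
        for r in results
    ])
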