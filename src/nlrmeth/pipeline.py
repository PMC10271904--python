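"""End-to-end orchestration and the command-line interface.

Stages run in a fixed order — QC filter, copy-number classification,
region building, methylation summarisation, TE coverage, per-species
screens, pooled consensus tests, methylation x TE overlap — over a
dataset directory laid out one subdirectory per species (genome.fa,
genes.gff3, te.bed, cx_report.tsv) plus shared tables (families.tsv,
similarity.tsv, qc.tsv).  All outputs are TSV with fixed column order and
``NA`` for undefined values; a run manifest records the configuration,
input checksums and per-table row counts and checksums, so a rerun on
identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import group_stats, io_formats, synthetic_data
from .io_formats import GeneRecord, GenomicInterval
from .methylation_core import CytosineIndex, methylation_profile
from .nlr_classification import (
    CopyNumberDistribution,
    classify_nlrs,
    compare_group_similarity,
    count_copy_numbers,
    select_cutoff,
)
from .region_model import build_coarse_regions, build_metagene_regions
from .te_coverage import te_coverage_profile

logger = logging.getLogger(__name__)

EXIT_VALIDATION, EXIT_PARSE, EXIT_COMPUTE = 2, 3, 4


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs beyond the dataset directory itself."""

    input_dir: str = "."
    output_dir: str = "out"
    # cutoff selection
    cutoff_tau: float = 0.01
    cutoff_fallback: int = 5
    # regions
    flank: int = 20_000
    bin_size: int = 5_000
    metagene_flank: int = 5_000
    body_bins: int = 100
    flank_bins: int = 100
    # methylation
    min_depth: int = 1
    # statistics
    alpha: float = 0.001
    min_group_n: int = 3
    correction: str = "none"
    overlap_mode: str = "any_region"
    # QC (both bounds strict)
    qc_min_depth: float = 5.0
    qc_min_mapping_rate: float = 0.60
    # synthetic runs only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank % self.bin_size != 0:
            raise ValueError(
                f"flank {self.flank} not divisible by bin size {self.bin_size}"
            )
        if self.metagene_flank % self.flank_bins != 0:
            raise ValueError("metagene_flank must divide evenly by flank_bins")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("none", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.overlap_mode not in ("any_region", "matched_region"):
            raise ValueError(f"unknown overlap mode {self.overlap_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# In-memory analysis core (shared by the file CLI and library callers)
# ---------------------------------------------------------------------------

@dataclass
class SpeciesInputs:
    """Parsed inputs for one species, ready for analysis."""

    species: str
    genes: list[GeneRecord]
    chrom_lengths: Mapping[str, int]
    cytosine_index: CytosineIndex
    te_intervals: list[GenomicInterval]


def analyze(
    species_inputs: Sequence[SpeciesInputs],
    family_rows: Sequence[tuple[str, str, str]],
    similarity_records: Sequence,
    config: PipelineConfig,
    compute_metagene: bool = True,
) -> dict:
    """Run classification, summarisation and statistics on parsed inputs.

    Returns a dict of result tables (DataFrames) plus the selected cutoff
    and assignment objects.  Species present in ``family_rows`` but not in
    ``species_inputs`` are assumed QC-filtered and ignored.
    """
    retained = {si.species for si in species_inputs}
    family_rows = [r for r in family_rows if r[0] in retained]
    counts = count_copy_numbers(family_rows)
    dist = CopyNumberDistribution.from_counts(counts)
    cutoff = select_cutoff(dist, tau=config.cutoff_tau,
                           fallback=config.cutoff_fallback)
    assignments = classify_nlrs(counts, family_rows, cutoff)
    assign_ids = {(a.species, a.gene_id) for a in assignments}
    known = {a.gene_id for a in assignments}
    sims = [s for s in similarity_records
            if s.query_id in known and s.subject_id in known]
    simcomp = compare_group_similarity(sims, assignments)

    meth_frames, metagene_frames, te_frames = [], [], []
    for si in species_inputs:
        genes = [g for g in si.genes if (si.species, g.gene_id) in assign_ids]
        coarse = {
            g.gene_id: build_coarse_regions(
                g, si.chrom_lengths[g.interval.chrom],
                flank=config.flank, bin_size=config.bin_size)
            for g in genes
        }
        meth_frames.append(methylation_profile(
            genes, coarse, si.cytosine_index, min_depth=config.min_depth))
        te_frames.append(te_coverage_profile(genes, coarse, si.te_intervals))
        if compute_metagene:
            meta = {
                g.gene_id: build_metagene_regions(
                    g, si.chrom_lengths[g.interval.chrom],
                    flank=config.metagene_flank,
                    body_bins=config.body_bins,
                    flank_bins=config.flank_bins)
                for g in genes
            }
            metagene_frames.append(methylation_profile(
                genes, meta, si.cytosine_index, min_depth=config.min_depth))

    meth_profile = pd.concat(meth_frames, ignore_index=True) if meth_frames \
        else pd.DataFrame()
    te_profile = pd.concat(te_frames, ignore_index=True) if te_frames \
        else pd.DataFrame()

    meth_vals = group_stats.meth_values(meth_profile)
    te_vals = group_stats.te_values(te_profile)
    meth_screen = group_stats.per_species_screen(
        meth_vals, assignments, alpha=config.alpha,
        min_group_n=config.min_group_n, correction=config.correction)
    te_screen = group_stats.per_species_screen(
        te_vals, assignments, alpha=config.alpha,
        min_group_n=config.min_group_n, correction=config.correction)
    pooled = pd.concat([
        group_stats.pooled_consensus_table(
            meth_vals, meth_screen, assignments,
            alpha=config.alpha, min_group_n=config.min_group_n),
        group_stats.pooled_consensus_table(
            te_vals, te_screen, assignments,
            alpha=config.alpha, min_group_n=config.min_group_n),
    ], ignore_index=True)
    overlaps = group_stats.overlap_table(
        group_stats.overlap_analysis(meth_screen, te_screen, "any_region")
        + group_stats.overlap_analysis(meth_screen, te_screen, "matched_region")
    )

    metagene_summary = pd.DataFrame()
    if compute_metagene and metagene_frames:
        metagene_all = pd.concat(metagene_frames, ignore_index=True)
        type_of = {(a.species, a.gene_id): a.nlr_type for a in assignments}
        metagene_all["nlr_type"] = [
            type_of.get((sp, g))
            for sp, g in zip(metagene_all["species"], metagene_all["gene_id"])
        ]
        metagene_summary = (
            metagene_all
            .groupby(["species", "nlr_type", "region_ordinal", "region_label",
                      "context"], as_index=False)
            .agg(mean_level=("level", "mean"), n_genes=("level", "count"))
            .sort_values(["species", "nlr_type", "context", "region_ordinal"])
            .reset_index(drop=True)
        )

    assignments_df = pd.DataFrame(
        [dataclasses.asdict(a) for a in assignments],
        columns=["gene_id", "species", "family_id", "copy_number", "nlr_type"],
    )
    simcomp_df = pd.DataFrame([{
        "test": simcomp.test,
        "n_high_groups": len(simcomp.high_group_means),
        "n_low_groups": len(simcomp.low_group_means),
        "mean_high": (np.mean(simcomp.high_group_means)
                      if simcomp.high_group_means else np.nan),
        "mean_low": (np.mean(simcomp.low_group_means)
                     if simcomp.low_group_means else np.nan),
        "statistic": simcomp.statistic,
        "p_value": simcomp.p_value,
        "direction": simcomp.direction,
        "testable": simcomp.testable,
    }])

    return {
        "cutoff": cutoff,
        "copy_number_distribution": pd.DataFrame(
            sorted(dist.f.items()), columns=["copy_number", "frequency"]),
        "assignments": assignments,
        "tables": {
            "assignments": assignments_df,
            "similarity_comparison": simcomp_df,
            "meth_profile": meth_profile,
            "metagene_profile": metagene_summary,
            "te_profile": te_profile,
            "meth_screen": meth_screen,
            "te_screen": te_screen,
            "pooled_consensus": pooled,
            "overlap": overlaps,
        },
    }


def analyze_dataset(dataset: synthetic_data.SyntheticDataset,
                    config: PipelineConfig | None = None,
                    compute_metagene: bool = False) -> dict:
    """Run the analysis core directly on an in-memory synthetic dataset."""
    cfg = config or PipelineConfig()
    species_inputs = []
    family_rows: list[tuple[str, str, str]] = []
    sim_records = []
    qc = io_formats.qc_filter(
        [sd.qc for sd in dataset.species],
        min_depth=cfg.qc_min_depth, min_mapping_rate=cfg.qc_min_mapping_rate)
    kept = {q.species for q in qc}
    for sd in dataset.species:
        family_rows += sd.family_rows
        sim_records += [
            io_formats.SimilarityRecord(q, s, ident)
            for (q, s, ident, _len) in sd.similarity_rows if q != s
        ]
        if sd.species not in kept:
            continue
        index = CytosineIndex.from_arrays(
            sd.chrom, sd.cytosines.pos, sd.cytosines.m, sd.cytosines.u,
            sd.cytosines.context, min_depth=cfg.min_depth)
        species_inputs.append(SpeciesInputs(
            species=sd.species, genes=sd.genes,
            chrom_lengths={sd.chrom: sd.chrom_length},
            cytosine_index=index, te_intervals=sd.te_intervals))
    result = analyze(species_inputs, family_rows, sim_records, cfg)
    result["dataset_id"] = dataset.dataset_id
    return result


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _chrom_lengths_from_fasta(path: Path) -> dict[str, int]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), build_index=True)
    return {name: len(fa[name]) for name in fa.keys()}


def load_species_inputs(input_dir: Path, species: str,
                        min_depth: int = 1) -> SpeciesInputs:
    sp_dir = input_dir / species
    genes = io_formats.read_gff_genes(sp_dir / "genes.gff3", species=species)
    chrom_lengths = _chrom_lengths_from_fasta(sp_dir / "genome.fa")
    chrom, pos, m, u, ctx = io_formats.read_cx_report_arrays(
        sp_dir / "cx_report.tsv")
    index = CytosineIndex.from_arrays(chrom, pos, m, u, ctx,
                                      min_depth=min_depth)
    te = io_formats.read_te_intervals(sp_dir / "te.bed")
    return SpeciesInputs(species=species, genes=genes,
                         chrom_lengths=chrom_lengths,
                         cytosine_index=index, te_intervals=te)


def write_table(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.10g")
    return {"rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage over a dataset directory and write the output tables.

    Any stage failure removes the partial outputs of this run before the
    error propagates, annotated with the failing stage.
    """
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "validate"
    t0 = time.monotonic()
    try:
        stage = "qc"
        qc_records = io_formats.read_species_qc(input_dir / "qc.tsv")
        kept = io_formats.qc_filter(
            qc_records, min_depth=config.qc_min_depth,
            min_mapping_rate=config.qc_min_mapping_rate)
        logger.info("QC retained %d/%d species", len(kept), len(qc_records))
        stage = "parse"
        family_rows = io_formats.read_family_table(input_dir / "families.tsv")
        sims = io_formats.read_similarity_table(input_dir / "similarity.tsv")
        species_inputs = [
            load_species_inputs(input_dir, q.species,
                                min_depth=config.min_depth)
            for q in kept
        ]
        stage = "analyze"
        result = analyze(species_inputs, family_rows, sims, config)
        stage = "write"
        manifest: dict = {
            "config": dataclasses.asdict(config),
            "config_hash": config.digest(),
            "cutoff": result["cutoff"],
            "species_retained": sorted(q.species for q in kept),
            "input_checksums": {
                str(p.relative_to(input_dir)): _sha256(p)
                for p in sorted(input_dir.rglob("*"))
                if p.is_file() and p.suffix != ".fai"
            },
            "tables": {},
        }
        sidecar = input_dir / "truth.json"
        if sidecar.exists():
            with open(sidecar) as fh:
                manifest["dataset_id"] = json.load(fh)["dataset_id"]
        tables = dict(result["tables"])
        tables["copy_number_distribution"] = result["copy_number_distribution"]
        for name in sorted(tables):
            path = out_dir / f"{name}.tsv"
            manifest["tables"][name] = write_table(tables[name], path)
            written.append(path)
        manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
        result["manifest"] = manifest
        if "dataset_id" in manifest:
            result["dataset_id"] = manifest["dataset_id"]
        return result
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _config_from_options(**kw) -> PipelineConfig:
    cfg_path = kw.pop("config", None)
    base = (PipelineConfig.from_yaml(cfg_path) if cfg_path
            else PipelineConfig())
    overrides = {k: v for k, v in kw.items() if v is not None}
    return dataclasses.replace(base, **overrides)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage timing to stderr.")
def cli(verbose: bool) -> None:
    """Methylation and transposon context around expanded NLR gene families."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


_common = [
    click.option("--config", type=click.Path(exists=True), default=None,
                 help="YAML file with PipelineConfig keys."),
    click.option("--alpha", type=float, default=None),
    click.option("--min-depth", "min_depth", type=int, default=None),
    click.option("--flank", type=int, default=None),
    click.option("--bin-size", "bin_size", type=int, default=None),
]


def _add_options(opts):
    def wrap(fn):
        for opt in reversed(opts):
            fn = opt(fn)
        return fn
    return wrap


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--n-species", type=int, default=None)
@click.option("--chrom-length", type=int, default=None)
@click.option("--genes-per-type", type=int, default=None,
              help="Type I and type II gene count per species.")
def simulate(seed: int, out: str, n_species: int | None,
             chrom_length: int | None, genes_per_type: int | None) -> None:
    """Generate a synthetic multi-species dataset."""
    kw = {}
    if n_species is not None:
        kw["n_species"] = n_species
    if chrom_length is not None:
        kw["chrom_length"] = chrom_length
    if genes_per_type is not None:
        kw["n_genes_typeI"] = genes_per_type
        kw["n_genes_typeII"] = genes_per_type
    cfg = synthetic_data.SyntheticConfig(**kw)
    dataset = synthetic_data.generate_dataset(cfg, seed=seed)
    synthetic_data.write_dataset(dataset, out)
    click.echo(f"dataset {dataset.dataset_id} written to {out}")


@cli.command()
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@_add_options(_common)
def run(input_dir: str, output_dir: str, **kw) -> None:
    """Run all stages end-to-end and, when the dataset carries planted
    truth, score recovery into recovery.json."""
    try:
        cfg = _config_from_options(
            input_dir=input_dir, output_dir=output_dir, **kw)
    except ValueError as exc:
        raise click.exceptions.Exit(EXIT_VALIDATION) from _echo_err(exc)
    try:
        result = run_pipeline(cfg)
    except RuntimeError as exc:
        code = EXIT_PARSE if "parse" in str(exc) else EXIT_COMPUTE
        raise click.exceptions.Exit(code) from _echo_err(exc)
    truth_path = Path(input_dir) / "truth.tsv"
    sidecar = Path(input_dir) / "truth.json"
    if truth_path.exists() and sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        cfg_payload = dict(meta["config"])
        cfg_payload["copy_number_law"] = {
            int(k): v for k, v in cfg_payload["copy_number_law"].items()}
        truth = synthetic_data.TruthRecord(
            dataset_id=meta["dataset_id"], seed=meta["seed"],
            config=synthetic_data.SyntheticConfig(**cfg_payload),
            genes=pd.read_csv(truth_path, sep="\t"),
        )
        report = synthetic_data.score_recovery(
            {"dataset_id": result.get("dataset_id"),
             "meth_screen": result["tables"]["meth_screen"],
             "assignments": result["assignments"],
             "cutoff": result["cutoff"]},
            truth, alpha=max(cfg.alpha, 0.01))
        rec_path = Path(output_dir) / "recovery.json"
        payload = dataclasses.asdict(report)
        payload["detected_strata"] = [list(t) for t in report.detected_strata]
        with open(rec_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        click.echo(f"recovery report written to {rec_path}")
    click.echo(f"outputs in {output_dir} (cutoff={result['cutoff']})")


def _echo_err(exc: Exception) -> None:
    click.echo(f"error: {exc}", err=True)
    return None


@cli.command()
@click.option("--families", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@click.option("--tau", type=float, default=0.01, show_default=True)
@click.option("--fallback", type=int, default=5, show_default=True)
def classify(families: str, output_dir: str, tau: float, fallback: int) -> None:
    """Classify NLR genes into type I/II from a family table alone."""
    rows = io_formats.read_family_table(families)
    counts = count_copy_numbers(rows)
    dist = CopyNumberDistribution.from_counts(counts)
    cutoff = select_cutoff(dist, tau=tau, fallback=fallback)
    assignments = classify_nlrs(counts, rows, cutoff)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [dataclasses.asdict(a) for a in assignments],
        columns=["gene_id", "species", "family_id", "copy_number", "nlr_type"])
    write_table(df, out / "assignments.tsv")
    write_table(
        pd.DataFrame(sorted(dist.f.items()),
                     columns=["copy_number", "frequency"]),
        out / "copy_number_distribution.tsv")
    click.echo(f"cutoff={cutoff}; {len(df)} genes classified")


def _staged_analysis(input_dir: str, output_dir: str, tables: list[str],
                     **kw) -> None:
    cfg = _config_from_options(input_dir=input_dir, output_dir=output_dir, **kw)
    qc = io_formats.qc_filter(
        io_formats.read_species_qc(Path(input_dir) / "qc.tsv"),
        min_depth=cfg.qc_min_depth, min_mapping_rate=cfg.qc_min_mapping_rate)
    family_rows = io_formats.read_family_table(Path(input_dir) / "families.tsv")
    sims = io_formats.read_similarity_table(Path(input_dir) / "similarity.tsv")
    species_inputs = [
        load_species_inputs(Path(input_dir), q.species, min_depth=cfg.min_depth)
        for q in qc
    ]
    result = analyze(species_inputs, family_rows, sims, cfg,
                     compute_metagene="metagene_profile" in tables)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in tables:
        write_table(result["tables"][name], out / f"{name}.tsv")
    click.echo(f"wrote {', '.join(tables)} to {output_dir}")


@cli.command()
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@_add_options(_common)
def methylate(input_dir: str, output_dir: str, **kw) -> None:
    """Emit methylation profile tables (coarse regions and metagene)."""
    _staged_analysis(input_dir, output_dir,
                     ["meth_profile", "metagene_profile"], **kw)


@cli.command()
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@_add_options(_common)
def tecov(input_dir: str, output_dir: str, **kw) -> None:
    """Emit the TE coverage profile table."""
    _staged_analysis(input_dir, output_dir, ["te_profile"], **kw)


@cli.command()
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@_add_options(_common)
def screen(input_dir: str, output_dir: str, **kw) -> None:
    """Emit per-species screen tables and the pooled consensus table."""
    _staged_analysis(input_dir, output_dir,
                     ["meth_screen", "te_screen", "pooled_consensus"], **kw)


@cli.command()
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "output_dir", type=click.Path(), required=True)
@_add_options(_common)
def overlap(input_dir: str, output_dir: str, **kw) -> None:
    """Emit the methylation x TE overlap table."""
    _staged_analysis(input_dir, output_dir, ["overlap"], **kw)


if __name__ == "__main__":  # pragma: no cover
    cli()
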