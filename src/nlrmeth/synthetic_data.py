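"""Synthetic multi-species datasets with planted epigenomic structure.

The generator emulates the statistical shape of a multi-species NLR
methylation study without any real genomes: per species it lays out
non-overlapping genes on one chromosome, organises them into families
whose copy numbers follow a heavy low-copy law with a high-copy tail,
plants transposon insertions upstream of genes (more often near
high-copy, type I genes), and simulates per-cytosine bisulfite read
counts whose methylation probability rises near transposons with an
exponential distance decay:

    p(site) = clip(mu[context] + delta[context] * exp(-d_TE / L), 0, 1)

where ``d_TE`` is the distance to the nearest TE in bp and ``L`` the decay
length.  Read counts are beta-binomial: per-site success probability ~
Beta(mean p, precision kappa), depth ~ Poisson(lambda), methylated count ~
Binomial(depth, p_site).  Protein similarity tables come from per-family
star phylogenies: every copy mutates independently from a family ancestor
at a per-site rate that is higher for high-copy families, so within-family
identity is lower where copy number is high.

Everything derives from a single ``numpy`` Generator seeded once, and
file output uses fixed formatting, so regeneration from (config, seed) is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneRecord,
    GenomicInterval,
    SpeciesQC,
    write_gff_genes,
)
from .te_coverage import merge_intervals

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_REVCOMP = str.maketrans("ACGT", "TGCA")
CONTEXT_NAMES = ("CG", "CHG", "CHH")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a modest WGBS survey: 3 species, 40 expanded-family
    (type I) and 40 low-copy (type II) genes each, ~10x Poisson depth,
    background weighted methylation of 0.30/0.10/0.03 (CG/CHG/CHH) and a
    planted TE-proximal non-CG boost of 0.12 decaying over 1 kb.
    """

    n_species: int = 3
    chrom_length: int = 1_000_000
    gene_length: int = 2_000
    flank_clearance: int = 8_000
    n_genes_typeI: int = 40
    n_genes_typeII: int = 40
    type_cutoff: int = 5
    copy_number_law: Mapping[int, float] = field(default_factory=lambda: {
        1: 0.55, 2: 0.20, 3: 0.10, 4: 0.06, 5: 0.04,
        6: 0.02, 8: 0.02, 12: 0.01,
    })
    te_insertion_prob_typeI: float = 0.8
    te_insertion_prob_typeII: float = 0.1
    te_length: int = 3_000
    te_max_tss_distance: int = 5_000
    te_background_per_mb: float = 20.0
    mu_background: Mapping[str, float] = field(default_factory=lambda: {
        "CG": 0.30, "CHG": 0.10, "CHH": 0.03,
    })
    te_effect: Mapping[str, float] = field(default_factory=lambda: {
        "CG": 0.0, "CHG": 0.12, "CHH": 0.12,
    })
    decay_length: float = 1_000.0
    beta_precision: float = 50.0
    depth_lambda: float = 10.0
    protein_length: int = 150
    divergence_high: float = 0.30
    divergence_low: float = 0.05
    wgbs_mapping_rate: float = 0.75

    def __post_init__(self) -> None:
        for name in ("te_insertion_prob_typeI", "te_insertion_prob_typeII"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if any(d < 0 for d in self.te_effect.values()):
            raise ValueError("te_effect deltas must be >= 0")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        if abs(sum(self.copy_number_law.values()) - 1.0) > 1e-9:
            raise ValueError("copy_number_law must sum to 1")

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["copy_number_law"] = {str(k): v for k, v
                                      in self.copy_number_law.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CytosineTable:
    """Column-oriented per-cytosine data for one chromosome."""

    chrom: str
    pos: np.ndarray          # int64, sorted ascending
    strand: np.ndarray       # uint8: 0 = '+', 1 = '-'
    m: np.ndarray            # int64 methylated counts
    u: np.ndarray            # int64 unmethylated counts
    context: np.ndarray      # uint8 index into CONTEXT_NAMES

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class SpeciesDataset:
    species: str
    chrom: str
    chrom_length: int
    sequence: str
    genes: list[GeneRecord]
    te_intervals: list[GenomicInterval]
    planted_te: dict[str, tuple[int, int] | None]  # gene_id -> TE interval
    cytosines: CytosineTable
    family_rows: list[tuple[str, str, str]]        # (species, gene, family)
    similarity_rows: list[tuple[str, str, float, int]]
    qc: SpeciesQC


@dataclass
class TruthRecord:
    """Planted structure sufficient to score pipeline recovery."""

    dataset_id: str
    seed: int
    config: SyntheticConfig
    genes: pd.DataFrame  # species, gene_id, family_id, copy_number, nlr_type,
                         # te_planted, te_start, te_end


@dataclass
class SyntheticDataset:
    dataset_id: str
    seed: int
    config: SyntheticConfig
    species: list[SpeciesDataset]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Family structure
# ---------------------------------------------------------------------------

def _draw_family_sizes(rng: np.random.Generator, law: Mapping[int, float],
                       cutoff: int, target: int, high: bool) -> list[int]:
    """Draw family sizes from the conditional copy-number law until they
    total ``target`` genes; the last family is adjusted to hit the target
    exactly while staying on the right side of the cutoff."""
    ks = np.array([k for k in sorted(law) if (k > cutoff) == high])
    ps = np.array([law[k] for k in ks], dtype=float)
    if len(ks) == 0 or target == 0:
        return []
    ps /= ps.sum()
    sizes: list[int] = []
    total = 0
    while total < target:
        k = int(rng.choice(ks, p=ps))
        sizes.append(k)
        total += k
    excess = total - target
    if excess:
        sizes[-1] -= excess
        floor = cutoff + 1 if high else 1
        if sizes[-1] < floor:
            short = sizes[-1]
            sizes.pop()
            if not sizes:
                raise ValueError(
                    f"cannot build a family set totalling {target} genes "
                    f"with cutoff {cutoff}"
                )
            sizes[-1] += short
    return sizes


# ---------------------------------------------------------------------------
# Per-cytosine simulation
# ---------------------------------------------------------------------------

def _scan_cytosines(code: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised context scan of a coded sequence (A0 C1 G2 T3).

    Returns (pos, strand, context) arrays; cytosines whose context runs
    off the sequence end are dropped, matching the rule that such sites
    have no defined context.
    """
    L = len(code)
    # plus strand: C at pos, need pos+1 (CG) or pos+2 (CHG/CHH)
    plus = np.flatnonzero(code == 1)
    plus = plus[plus + 1 < L]
    n1 = code[plus + 1]
    is_cg_p = n1 == 2
    rest = plus[~is_cg_p]
    rest = rest[rest + 2 < L]
    n2 = code[rest + 2]
    pos_p = np.concatenate([plus[is_cg_p], rest])
    ctx_p = np.concatenate([
        np.zeros(int(is_cg_p.sum()), dtype=np.uint8),
        np.where(n2 == 2, 1, 2).astype(np.uint8),
    ])
    # minus strand: G at pos, 5'->3' runs leftwards; complement(C) = G
    minus = np.flatnonzero(code == 2)
    minus = minus[minus - 1 >= 0]
    p1 = code[minus - 1]
    is_cg_m = p1 == 1
    rest_m = minus[~is_cg_m]
    rest_m = rest_m[rest_m - 2 >= 0]
    p2 = code[rest_m - 2]
    pos_m = np.concatenate([minus[is_cg_m], rest_m])
    ctx_m = np.concatenate([
        np.zeros(int(is_cg_m.sum()), dtype=np.uint8),
        np.where(p2 == 1, 1, 2).astype(np.uint8),
    ])
    pos = np.concatenate([pos_p, pos_m])
    strand = np.concatenate([
        np.zeros(len(pos_p), dtype=np.uint8),
        np.ones(len(pos_m), dtype=np.uint8),
    ])
    ctx = np.concatenate([ctx_p, ctx_m])
    order = np.lexsort((strand, pos))
    return pos[order].astype(np.int64), strand[order], ctx[order]


def _distance_to_intervals(pos: np.ndarray,
                           intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """bp distance from each position to the nearest interval (0 inside)."""
    if not intervals:
        return np.full(len(pos), np.inf)
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    ends = np.array([iv.end for iv in intervals], dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    prev_end = np.where(idx >= 0, ends[np.clip(idx, 0, None)], np.iinfo(np.int64).min)
    inside = (idx >= 0) & (pos < prev_end)
    d_left = np.where(idx >= 0, pos - prev_end + 1, np.iinfo(np.int64).max)
    nxt = np.searchsorted(starts, pos, side="right")
    d_right = np.where(nxt < len(starts),
                       starts[np.clip(nxt, None, len(starts) - 1)] - pos,
                       np.iinfo(np.int64).max)
    dist = np.minimum(d_left, d_right).astype(float)
    dist[inside] = 0.0
    return dist


def _simulate_counts(rng: np.random.Generator, ctx: np.ndarray,
                     dist: np.ndarray, cfg: SyntheticConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    mu = np.array([cfg.mu_background[c] for c in CONTEXT_NAMES])
    delta = np.array([cfg.te_effect[c] for c in CONTEXT_NAMES])
    with np.errstate(over="ignore"):
        decay = np.exp(-dist / cfg.decay_length)
    p_mean = np.clip(mu[ctx] + delta[ctx] * decay, 0.0, 1.0)
    kappa = cfg.beta_precision
    a = np.maximum(p_mean * kappa, 1e-12)
    b = np.maximum((1.0 - p_mean) * kappa, 1e-12)
    p_site = rng.beta(a, b)
    p_site[p_mean == 0.0] = 0.0
    p_site[p_mean == 1.0] = 1.0
    depth = rng.poisson(cfg.depth_lambda, size=len(ctx))
    m = rng.binomial(depth, p_site)
    return m.astype(np.int64), (depth - m).astype(np.int64)


# ---------------------------------------------------------------------------
# Protein similarity
# ---------------------------------------------------------------------------

def _family_similarity(rng: np.random.Generator, gene_ids: Sequence[str],
                       divergence: float, length: int
                       ) -> list[tuple[str, str, float, int]]:
    """Within-family pairwise identities from a star phylogeny."""
    ancestor = rng.integers(0, len(_AA), size=length)
    seqs = []
    for _ in gene_ids:
        mutate = rng.random(length) < divergence
        shift = rng.integers(1, len(_AA), size=length)
        seq = np.where(mutate, (ancestor + shift) % len(_AA), ancestor)
        seqs.append(seq)
    rows = []
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            ident = 100.0 * float(np.mean(seqs[i] == seqs[j]))
            rows.append((gene_ids[i], gene_ids[j], round(ident, 2), length))
    return rows


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _generate_species(rng: np.random.Generator, cfg: SyntheticConfig,
                      species: str) -> SpeciesDataset:
    cutoff = cfg.type_cutoff
    sizes_I = _draw_family_sizes(rng, cfg.copy_number_law, cutoff,
                                 cfg.n_genes_typeI, high=True)
    sizes_II = _draw_family_sizes(rng, cfg.copy_number_law, cutoff,
                                  cfg.n_genes_typeII, high=False)
    n_genes = sum(sizes_I) + sum(sizes_II)
    pitch = cfg.gene_length + cfg.flank_clearance
    margin = cfg.te_max_tss_distance + cfg.te_length + 1_000
    required = 2 * margin + n_genes * pitch
    if required > cfg.chrom_length:
        raise ValueError(
            f"{n_genes} genes need >= {required} bp with the configured "
            f"clearance; increase chrom_length (currently {cfg.chrom_length})"
        )
    chrom = "chr1"

    # family labels and per-gene type, shuffled along the chromosome
    fam_of_gene: list[tuple[str, str]] = []  # (family_id, type)
    for fi, size in enumerate(sizes_I):
        fam = f"{species}_famI{fi + 1:02d}"
        fam_of_gene += [(fam, "I")] * size
    for fi, size in enumerate(sizes_II):
        fam = f"{species}_famII{fi + 1:02d}"
        fam_of_gene += [(fam, "II")] * size
    order = rng.permutation(n_genes)
    fam_of_gene = [fam_of_gene[i] for i in order]

    genes: list[GeneRecord] = []
    family_rows: list[tuple[str, str, str]] = []
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    jitter = rng.integers(0, cfg.flank_clearance // 4 + 1, size=n_genes)
    for i, (fam, _type) in enumerate(fam_of_gene):
        start = margin + i * pitch + int(jitter[i])
        gid = f"{species}_g{i + 1:03d}"
        genes.append(GeneRecord(
            gene_id=gid, species=species,
            interval=GenomicInterval(chrom, start, start + cfg.gene_length,
                                     str(strands[i])),
        ))
        family_rows.append((species, gid, fam))

    # transposon placement: planted upstream TEs plus uniform background
    te_intervals: list[GenomicInterval] = []
    planted: dict[str, tuple[int, int] | None] = {}
    probs = {"I": cfg.te_insertion_prob_typeI, "II": cfg.te_insertion_prob_typeII}
    for gene, (fam, _type) in zip(genes, fam_of_gene):
        if rng.random() >= probs[_type]:
            planted[gene.gene_id] = None
            continue
        offset = int(rng.integers(0, cfg.te_max_tss_distance - cfg.te_length + 1))
        iv = gene.interval
        if iv.strand == "+":
            s = iv.start - offset - cfg.te_length
        else:
            s = iv.end + offset
        s = max(0, min(s, cfg.chrom_length - cfg.te_length))
        te_intervals.append(GenomicInterval(chrom, s, s + cfg.te_length))
        planted[gene.gene_id] = (s, s + cfg.te_length)
    n_background = int(round(cfg.te_background_per_mb * cfg.chrom_length / 1e6))
    for _ in range(n_background):
        s = int(rng.integers(0, cfg.chrom_length - cfg.te_length))
        te_intervals.append(GenomicInterval(chrom, s, s + cfg.te_length))
    merged_te = merge_intervals(te_intervals) if te_intervals else []

    # genome sequence and methylome
    code = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
    sequence = _BASES[code].tobytes().decode()
    pos, strand, ctx = _scan_cytosines(code)
    dist = _distance_to_intervals(pos, merged_te)
    m, u = _simulate_counts(rng, ctx, dist, cfg)
    cytosines = CytosineTable(chrom=chrom, pos=pos, strand=strand,
                              m=m, u=u, context=ctx)

    # protein similarity per multi-copy family
    similarity_rows: list[tuple[str, str, float, int]] = []
    by_family: dict[str, list[str]] = {}
    for (sp, gid, fam) in family_rows:
        by_family.setdefault(fam, []).append(gid)
    for fam in sorted(by_family):
        ids = by_family[fam]
        if len(ids) < 2:
            continue
        divergence = (cfg.divergence_high if "famI" in fam and "famII" not in fam
                      else cfg.divergence_low)
        similarity_rows += _family_similarity(rng, ids, divergence,
                                              cfg.protein_length)

    qc = SpeciesQC(species, cfg.depth_lambda, cfg.wgbs_mapping_rate)
    return SpeciesDataset(
        species=species, chrom=chrom, chrom_length=cfg.chrom_length,
        sequence=sequence, genes=genes, te_intervals=merged_te,
        planted_te=planted, cytosines=cytosines, family_rows=family_rows,
        similarity_rows=similarity_rows, qc=qc,
    )


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate an in-memory multi-species dataset from (config, seed).

    A single seeded Generator drives every draw in a fixed order, so the
    result — and any files written from it — is reproducible bit for bit.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    species_data = [
        _generate_species(rng, cfg, f"sp{i + 1:02d}")
        for i in range(cfg.n_species)
    ]
    dataset_id = f"{cfg.digest()}-{seed}"
    truth_rows = []
    for sd in species_data:
        fam_of = {gid: fam for (_, gid, fam) in sd.family_rows}
        fam_sizes: dict[str, int] = {}
        for (_, gid, fam) in sd.family_rows:
            fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
        for gene in sd.genes:
            fam = fam_of[gene.gene_id]
            te = sd.planted_te[gene.gene_id]
            truth_rows.append({
                "species": sd.species, "gene_id": gene.gene_id,
                "family_id": fam, "copy_number": fam_sizes[fam],
                "nlr_type": "I" if fam_sizes[fam] > cfg.type_cutoff else "II",
                "te_planted": te is not None,
                "te_start": te[0] if te else -1,
                "te_end": te[1] if te else -1,
            })
    truth = TruthRecord(dataset_id=dataset_id, seed=seed, config=cfg,
                        genes=pd.DataFrame(truth_rows))
    return SyntheticDataset(dataset_id=dataset_id, seed=seed, config=cfg,
                            species=species_data, truth=truth)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _write_fasta(sequence: str, chrom: str, path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


_COMP_TABLE = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


def _trinucleotides(sequence: str, pos: np.ndarray,
                    strand: np.ndarray) -> np.ndarray:
    """Strand-oriented trinucleotide (cytosine + 2 downstream) per site."""
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    L = len(seq)
    n_char = np.uint8(ord("N"))
    tri = np.empty((len(pos), 3), dtype=np.uint8)
    plus = strand == 0
    pp = pos[plus]
    tri[plus, 0] = seq[pp]
    tri[plus, 1] = np.where(pp + 1 < L, seq[np.clip(pp + 1, 0, L - 1)], n_char)
    tri[plus, 2] = np.where(pp + 2 < L, seq[np.clip(pp + 2, 0, L - 1)], n_char)
    minus = ~plus
    pm = pos[minus]
    tri[minus, 0] = _COMP_TABLE[seq[pm]]
    tri[minus, 1] = np.where(pm - 1 >= 0,
                             _COMP_TABLE[seq[np.clip(pm - 1, 0, L - 1)]], n_char)
    tri[minus, 2] = np.where(pm - 2 >= 0,
                             _COMP_TABLE[seq[np.clip(pm - 2, 0, L - 1)]], n_char)
    return tri.view("S3").ravel().astype("U3")


def write_species_files(sd: SpeciesDataset, outdir: Path) -> dict[str, Path]:
    """Write one species' FASTA, GFF3, TE BED and CX report."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "te": outdir / "te.bed",
        "cx": outdir / "cx_report.tsv",
    }
    _write_fasta(sd.sequence, sd.chrom, paths["genome"])
    write_gff_genes(sd.genes, paths["genes"])
    with open(paths["te"], "w") as fh:
        for i, iv in enumerate(sd.te_intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tTE{i + 1:04d}\t0\t.\n")
    cyt = sd.cytosines
    tri = _trinucleotides(sd.sequence, cyt.pos, cyt.strand)
    cx_df = pd.DataFrame({
        "chrom": cyt.chrom,
        "pos": cyt.pos + 1,
        "strand": np.where(cyt.strand == 0, "+", "-"),
        "m": cyt.m,
        "u": cyt.u,
        "context": np.array(CONTEXT_NAMES)[cyt.context],
        "tri": tri,
    })
    cx_df.to_csv(paths["cx"], sep="\t", header=False, index=False)
    return paths


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the whole dataset: per-species files plus shared tables.

    Returns a manifest-style dict of paths.  Shared tables: family
    assignments, protein similarity, species QC, and the planted truth
    (TSV + JSON sidecar with config and dataset id).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"dataset_id": dataset.dataset_id, "species": {}}
    fam_path = outdir / "families.tsv"
    sim_path = outdir / "similarity.tsv"
    qc_path = outdir / "qc.tsv"
    with open(fam_path, "w") as fam_fh, open(sim_path, "w") as sim_fh, \
            open(qc_path, "w") as qc_fh:
        fam_fh.write("species\tgene_id\tfamily_id\n")
        qc_fh.write("species\twgbs_depth\tmapping_rate\n")
        for sd in dataset.species:
            paths = write_species_files(sd, outdir / sd.species)
            manifest["species"][sd.species] = {k: str(v) for k, v in paths.items()}
            for sp, gid, fam in sd.family_rows:
                fam_fh.write(f"{sp}\t{gid}\t{fam}\n")
            for q, s, ident, length in sd.similarity_rows:
                sim_fh.write(f"{q}\t{s}\t{ident:.2f}\t{length}\n")
            qc_fh.write(f"{sd.qc.species}\t{sd.qc.wgbs_depth:g}\t"
                        f"{sd.qc.mapping_rate:g}\n")
    truth_path = outdir / "truth.tsv"
    dataset.truth.genes.to_csv(truth_path, sep="\t", index=False)
    sidecar = outdir / "truth.json"
    cfg_payload = dataclasses.asdict(dataset.config)
    cfg_payload["copy_number_law"] = {
        str(k): v for k, v in dataset.config.copy_number_law.items()
    }
    with open(sidecar, "w") as fh:
        json.dump({"dataset_id": dataset.dataset_id, "seed": dataset.seed,
                   "config": cfg_payload}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.update({
        "families": str(fam_path), "similarity": str(sim_path),
        "qc": str(qc_path), "truth": str(truth_path),
        "truth_sidecar": str(sidecar),
    })
    return manifest


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    dataset_id: str
    type_assignment_accuracy: float
    chh_flank_detected: bool
    chh_direction_correct: bool
    detected_strata: tuple[tuple[str, str, str], ...]
    cg_false_positive_rate: float | None
    cutoff_recovered: int
    cutoff_planted: int


def score_recovery(pipeline_output: Mapping, truth: TruthRecord,
                   alpha: float = 0.01) -> RecoveryReport:
    """Score a pipeline run against the planted truth.

    ``pipeline_output`` must carry ``dataset_id``, the per-species
    methylation screen (``meth_screen``), the NLR ``assignments`` and the
    selected ``cutoff``.  CHH flank detection means some species flags the
    upstream or downstream CHH stratum at ``alpha`` — with the planted
    TE-proximal effect this is the signal the dataset was built around.
    CG strata carry no planted effect and serve as the null for the
    false-positive rate.
    """
    if pipeline_output.get("dataset_id") != truth.dataset_id:
        raise ValueError(
            f"pipeline output is from dataset "
            f"{pipeline_output.get('dataset_id')!r}, truth from "
            f"{truth.dataset_id!r}"
        )
    screen: pd.DataFrame = pipeline_output["meth_screen"]
    assignments = pipeline_output["assignments"]
    true_type = dict(zip(zip(truth.genes["species"], truth.genes["gene_id"]),
                         truth.genes["nlr_type"]))
    correct = sum(
        1 for a in assignments
        if true_type.get((a.species, a.gene_id)) == a.nlr_type
    )
    accuracy = correct / len(assignments) if assignments else float("nan")

    sig = screen[screen["testable"] & (screen["p_value"] < alpha)]
    chh_flank = sig[(sig["feature"] == "mCHH")
                    & sig["region_label"].isin(["upstream", "downstream"])]
    detected = tuple(
        (r.species, r.feature, r.region_label)
        for r in sig.itertuples()
    )
    direction_ok = bool(len(chh_flank)) and bool(
        (chh_flank["mean_typeI"] > chh_flank["mean_typeII"]).all()
    )
    cg = screen[screen["testable"] & (screen["feature"] == "mCG")]
    fp = (float((cg["p_value"] < alpha).mean()) if len(cg) else None)
    return RecoveryReport(
        dataset_id=truth.dataset_id,
        type_assignment_accuracy=accuracy,
        chh_flank_detected=bool(len(chh_flank)),
        chh_direction_correct=direction_ok,
        detected_strata=detected,
        cg_false_positive_rate=fp,
        cutoff_recovered=int(pipeline_output.get("cutoff", -1)),
        cutoff_planted=truth.config.type_cutoff,
    )
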