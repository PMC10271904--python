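# nlrmeth

Comparative epigenomics of plant disease-resistance gene families:
DNA methylation and transposon context around **expanded (type I)**
versus **conserved (type II)** NLR genes.

## The problem

Plant NLR (nucleotide-binding site, leucine-rich repeat) genes evolve
under strong pathogen pressure. Within a species, some NLR families
expand to many diverged copies (type I) while others stay at one or a
few conserved copies (type II). A standing question is how genomes
tolerate such expansions, given that overexpressed NLRs are costly.
One candidate mechanism is epigenetic: transposable-element (TE)
insertions near expanded NLRs attract non-CG DNA methylation
(CHG/CHH; H ∈ {A, T, C}), which spreads into the gene neighbourhood
and dampens expression.

`nlrmeth` implements the full comparative analysis as a tested,
reusable pipeline for multi-species whole-genome bisulfite sequencing
(WGBS) surveys:

1. **QC filter** — retain species with WGBS depth > 5 and mapping
   rate > 60 % (both strict).
2. **Copy-number classification** — per species, count genes per NLR
   family; select the high/low-copy cutoff *c* where the first-order
   difference of the copy-number frequency distribution stabilises
   (normalised |f(k) − f(k+1)| / f(k_min) < τ from *k* onward; default
   τ = 0.01, fallback *c* = 5); type I ⇔ copy number > *c*.
3. **Similarity contrast** — within-family mean pairwise protein
   identity, high-copy vs low-copy families (Welch's t-test on group
   means).
4. **Weighted methylation** — per gene × region × context,
   level = Σmᵢ / Σ(mᵢ + uᵢ) over all covered cytosines of that
   context (count-weighted, exactly additive under region
   partitions). Regions: gene body plus four 5 kb bins per 20 kb
   flank (strand-aware), and a 100-bin metagene with 100 × 50 bp
   flank bins for profiles.
5. **TE coverage** — percent of each region covered by the union of
   TE annotations.
6. **Screens** — per species × feature (mCG/mCHG/mCHH/TE) ×
   region (upstream/body/downstream), type I vs type II Welch tests;
   pooled "consensus-region" tests over the significant species;
   and the overlap statistic: the fraction of non-CG-methylation-
   significant species that are also TE-significant.

A first-class **synthetic-data generator** plants all of this
structure (copy-number law with a high-copy tail, TE insertions
enriched upstream of type I genes, TE-proximal non-CG hypermethylation
decaying as exp(−d/L), beta-binomial WGBS counts) so every stage is
testable without downloading genomes. See `docs/methods.md` for the
model and its parameters.

## Worked example

```python
import nlrmeth as n

dataset = n.generate_dataset(seed=42)        # 3 species, 40+40 genes each
result  = n.analyze_dataset(dataset, n.PipelineConfig(alpha=0.01))

print("cutoff:", result["cutoff"])
ms = result["tables"]["meth_screen"]
print(ms[(ms.feature == "mCHH") & (ms.region_label == "upstream")]
      [["species", "mean_typeI", "mean_typeII", "p_value", "significant"]])
```

prints

```
cutoff: 5
species  mean_typeI  mean_typeII  p_value  significant
   sp01    0.073132     0.066770 0.174006        False
   sp02    0.073605     0.059250 0.001705         True
   sp03    0.078674     0.067145 0.011403        False
```

The selected cutoff (5) reproduces the ">5 copies = type I" rule from
the planted copy-number distribution. Upstream CHH weighted
methylation is higher for type I genes in all three species — the
planted TE-proximity effect — and reaches the α = 0.01 screen
threshold in sp02 here; the detection rate across seeded replicates
is one of the quantities `scripts/acceptance.py` recomputes.
The same run reports within-family identity of ~48 % for high-copy
vs ~91 % for low-copy families (direction "high < low",
p ≈ 3 × 10⁻⁴²), the expanded-family divergence signature.

From the shell:

```bash
nlrmeth simulate --seed 7 --out data/
nlrmeth run --input data/ --out results/ --alpha 0.01
```

writes ten TSV tables (assignments, profiles, screens, pooled tests,
overlap), a `manifest.json` with input/output checksums, and — because
synthetic datasets carry their planted truth — a `recovery.json`
scoring type-assignment accuracy and effect recovery. Stage
subcommands (`classify`, `methylate`, `tecov`, `screen`, `overlap`)
emit the same tables byte-for-byte.

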