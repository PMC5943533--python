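# mcpdiv

Amplicon diversity analysis for T4-like cyanophage (myocyanophage)
communities surveyed with a short degenerate-primer marker: a ~145-nt
fragment of the g23 major capsid protein (MCP) gene amplified by the pair
mcp-821F (`CTKGCDGARATYAACMGIGAART`) and mcp-966R
(`ADDAGWCCYTTGAAYTTYTCAAC`). Short MCP amplicons make it possible to assay
cyanophage diversity not just in water columns but in sediments, where
ancient DNA survives only in short fragments.

The package implements the full analysis chain as a tested library plus CLI:

- **`seqio`** — FASTA/FASTQ I/O with Phred decoding.
- **`primer_tools`** — degenerate-primer matching (IUPAC codes plus inosine,
  a universal base), in-silico PCR against references, barcode
  demultiplexing and primer trimming.
- **`read_filters`** — mean-quality filtering (Phred ≥ 25), and the
  frame-aware length filter: because the amplicon is protein-coding, genuine
  length variants differ from the canonical 145 nt by whole codons
  (145 ± 3n, window 136–154 nt), and any read whose translation contains a
  stop codon is discarded. The surviving 142/145/148-nt classes are
  summarized, and the 142/145 read-count ratio serves as an index of
  terrestrial vs. aquatic phage input.
- **`otu_cluster`** — abundance-ordered greedy centroid clustering into
  OTUs at configurable identity thresholds (80/90/95/97% by default),
  singleton removal, dominant-OTU (>2% relative abundance) and shared-OTU
  analysis. Identity is global-alignment matches over alignment columns.
- **`diversity`** — exact hypergeometric rarefaction
  E[S_n] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), Good's coverage C = 1 − F₁/n,
  UPGMA/NJ distance trees, unweighted and weighted UniFrac, PCoA, and
  UPGMA sample clustering with jackknife support percentages.
- **`synthetic_data`** — a seeded generator of ground-truth studies
  (divergent stop-free haplotypes, planted length-class mixtures and
  abundance tails, substitution errors, barcodes) so the entire pipeline is
  testable without downloads.
- **`pipeline` / `cli`** — orchestration with a JSON manifest.

## Worked example

Simulate an eight-sample, two-biome study (four lake-like, four ocean-like
samples; two of the lake samples are "KS-like" sediments where the 148-nt
class dominates) and run the full pipeline:

```bash
mcpdiv simulate --out-dir sim --seed 1 --reads-per-sample 600
mcpdiv run-all --config run.yaml     # inputs: sim/*.fastq
```

or in Python:

```python
from mcpdiv.synthetic_data import default_study_specs, generate_study
from mcpdiv.pipeline import PipelineConfig, run_pipeline

generate_study(default_study_specs(reads_per_sample=600, seed=1),
               seed=1, out_dir="sim")
manifest = run_pipeline(PipelineConfig(
    output_dir="out",
    inputs={s: f"sim/{s}.fastq" for s in
            ["L1", "L2", "L3", "L4", "O1", "O2", "O3", "O4"]},
    seed=1,
))
print(manifest["stages"]["cluster"]["0.90"])
print(manifest["stages"]["source_ratio"])
```

which prints (seed 1):

```
{'otus': 32, 'otus_no_singletons': 32, 'reads': 4382}
{'L1': 0.02, 'L2': 0.52, 'L3': 0.617, 'L4': 0.031, 'O1': 0.03,
 'O2': 0.021, 'O3': 0.019, 'O4': 0.013}
```
(source ratios rounded to three decimals here)

All 32 planted haplotypes are recovered as OTUs at 90% identity; the
142/145 source ratio is ~0.02–0.03 in the aquatic-profile samples and high
in the KS-like pair, with the "deeper" L3 (0.62) above the "surface" L2
(0.52) as planted. The output directory contains per-sample filtered FASTA,
the discard ledger, OTU tables per threshold, representative sequences, the
OTU tree, UniFrac matrices, PCoA coordinates, rarefaction/coverage tables,
and the jackknifed sample tree in Newick, e.g.

```
(((L2,L3)75,(L1,L4)39)100,(O2,(O1,(O3,O4)54)47)100);
```
(branch lengths elided)

where the biome split carries 100% jackknife support.

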