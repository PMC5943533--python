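# Methods

## The marker and the analysis problem

T4-like cyanophages (myocyanophages) are surveyed by amplifying a short,
variable fragment of the g23 major capsid protein gene with the degenerate
primer pair mcp-821F / mcp-966R. The amplicon is ~145 nt primer-inclusive
(the pair embraces a 146-nt span on a g23 reference gene, positions
748–893; reported lengths in real libraries center on 145). Because the
fragment is protein-coding, authentic length variants differ from the
canonical length by whole codons; sequencing and amplification artifacts
typically do not. That observation drives the central filtering rule and
the 142/145/148-nt length classes around which the analysis is organized.

A note on "amplicon length": the 748–893 span is 146 nt while amplicons are
reported as ~145 nt; whether published read lengths include both primers is
ambiguous. This pipeline treats read length as primer-inclusive and keeps
145 as the canonical value; the discrepancy is surfaced here rather than
silently resolved.

## Pipeline stages and their parameters

1. **Quality filter** — keep reads with *mean* Phred ≥ 25 (inclusive at the
   boundary). The threshold-25 rule could also be read as a per-base
   minimum; mean-based filtering matches the way per-library average
   quality is usually reported, and a `mode="min"` flag provides the
   stricter reading. Reads without qualities (Sanger clone FASTA) pass
   through with a logged notice so clone libraries flow down the same path.
2. **Demultiplex/trim** — barcodes matched within a configurable Hamming
   tolerance; ambiguous assignments go to an `undetermined` bin rather
   than the nearest sample. The read layout (adapter/pad/barcode/linker/
   primer) is a configurable descriptor; the default is a single-index
   layout with the barcode immediately before the forward primer.
   Reference-side `N` bases count as matches during primer comparison —
   absence of information is not evidence of mismatch. Inosine in a primer
   matches all four bases and is its own complement.
3. **Frame filter** — discard reads outside 136–154 nt, reads whose length
   is not ≡ 145 (mod 3) (admissible set exactly
   {136, 139, 142, 145, 148, 151, 154}), and reads whose translation
   contains a stop codon. The reading frame is a single configurable
   offset, default 0 on the trimmed read: with primers attached the
   145-nt amplicon begins at a codon boundary by construction in the
   generator, and with primers trimmed the 96/99/102-nt inserts are codon
   multiples, so offset 0 is the natural default either way. An
   `any_frame_open` mode keeps reads that are stop-free in any of the
   three frames, for data whose frame is unknown. The filter is idempotent
   and keeps a per-reason discard ledger so alternative accountings of the
   discard rate (with or without window discards) can be read off directly.
4. **OTU clustering** — dereplicate, order unique sequences by descending
   abundance (input-order tie-break; a pure input-order mode exists for
   order-sensitivity experiments), and greedily assign each to the first
   centroid at identity ≥ threshold, else found a new centroid. This is
   behavioral, not bit-exact, equivalence with classic greedy centroid
   clustering tools. Identity = alignment matches / alignment columns
   (gap columns included), from a global alignment with match +1,
   mismatch −1, gap open −2, gap extend −0.5, end gaps penalized; an
   end-gap-free switch exists because clustering across mixed 142/145/148
   lengths is sensitive to terminal-gap policy. A singleton is an OTU with
   total count 1 across *all* samples; dominance is strict (>2% relative
   abundance within a sample).
5. **Alpha diversity** — exact rarefaction uses the closed-form
   hypergeometric expectation with log-gamma arithmetic for the binomial
   ratios, stable at 10⁵-read depths; Monte-Carlo mode subsamples without
   replacement (multivariate hypergeometric draws). Good's coverage is
   1 − F₁/n with F₁ the singleton count at depth n; at reduced depth both
   an exact-expectation and a Monte-Carlo estimate are available.
6. **Beta diversity** — trees over OTU representatives come from pairwise
   alignment distances (d = 1 − identity): UPGMA (default, ultrametric)
   or neighbor joining midpoint-rooted so UniFrac has a root. Aligner-based
   ML phylogenetics is deliberately not reproduced: the analysis surface
   here is UniFrac and sample-cluster topology, which distance trees
   support. Unweighted UniFrac is unique branch length over the branch
   length of the union of the two communities; weighted UniFrac is
   Σ bᵢ·|p_iA − p_iB| over branches, normalized by default by
   Σ_j d_j (p_jA + p_jB) over leaves (root-to-leaf depth d_j), bounding it
   to [0, 1]; the raw form is available by flag. PCoA is classical
   Torgerson scaling; negative eigenvalues of non-Euclidean inputs are
   reported, never silently dropped. Sample clustering is UPGMA on UniFrac
   with jackknife support: each replicate rarefies every sample without
   replacement to a common depth (default 75% of the smallest sample
   total — replicate counts are usually published without a depth, so the
   depth is an explicit, logged parameter) and support is the percentage
   of replicates recovering the same leaf bipartition.

## The synthetic-data generator

The generator emulates the structure of real MCP amplicon libraries so the
pipeline's statistical behavior can be verified against planted truth:

- **Haplotypes** are full amplicons (concrete forward primer expansion +
  codon-structured insert + concrete reverse binding site) of 142/145/148
  nt, stop-free in the canonical frame by construction (codon rejection
  sampling, never post-hoc filtering), and pairwise below an identity
  ceiling (default ≤ 80%, i.e. ≥ 20% divergence).
- **Length-class profiles** follow the two observed regimes: aquatic-like
  samples at (142, 145, 148) ≈ (1.5%, 97%, 1.5%) — the 145-nt class
  dominant at the ~95–99% level — and "KS-like" sediment samples with the
  148-nt class dominant (~52%) and roughly 30%/18% in the 145/142 classes;
  the deeper member of the KS-like pair is planted at a higher 142/145
  ratio than the surface member, so the terrestrial-input ordering is
  recoverable.
- **Abundances** default to lognormal(μ=1, σ=1.5) weights truncated to the
  read budget, plus a pinned singleton fraction (default 15% of
  haplotypes at exactly one read) to exercise Good's coverage and
  singleton removal. Exact-recovery experiments (planted k haplotypes →
  exactly k OTUs) instead use σ=0.5 and no pinned singletons, since exact
  recovery is only a well-posed target when every haplotype receives ≥ 2
  reads.
- **Errors** are substitution-only by default: the analysis signal is the
  length-class structure, and indel noise would conflate generator error
  with biological length variation. Qualities are Gaussian per base
  (mean 31, sd 3, clipped to [2, 41]), matching the ~30 average of deep
  amplicon runs, with a small fraction (2%) of degraded-quality reads
  (mean 18) so the quality filter has work to do. Quality values are not
  coupled to error positions — realistic miscall matrices are a non-goal.
- **The study design** is eight samples in two "biome" groups of four with
  group-disjoint dominant haplotype pools and a shared rare tail, so
  between-group UniFrac exceeds within-group UniFrac and the biome split
  is the planted sample-tree topology. Default depth is ~2,000 reads per
  sample — the shallow-sequencing scale of real studies of this design —
  and tests/acceptance runs use 250–1,200 reads per sample to keep exact
  clustering tractable; deep-sequencing depths are reachable by parameter.
  Fixed seeds give byte-identical outputs.

What passing tests on this generator do **not** show: robustness to indels,
chimeras, context-dependent miscalls, or primer-site variation in real
templates; and OTU counts at real deep-sequencing scale (tens of thousands
of OTUs), which the desk-scale runs only echo structurally (the OTU count
gradient across 97→80% identity, rising coverage with depth, concave
non-plateauing rarefaction curves).

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive in every report; amplicon length
  includes both primers.
- Quality threshold keeps reads exactly at the boundary; length windows
  are inclusive; dominance is strict.
- Zero 145-nt reads makes the 142/145 ratio an error, not infinity; empty
  read sets make compositions an error, not NaN.
- Ties in greedy clustering fall back to input order, making every table
  deterministic given input order; in-silico PCR reports *all* qualifying
  primer pairings sorted by mismatches then span, never a silent best hit.
- UPGMA node heights are half the average-linkage merge distance, so
  root-to-leaf paths are equal by construction; NJ branch lengths are
  clamped at zero.
- An OTU id appearing more than once among tree leaves is an error, never
  a silent merge.

## Known limitations

- Greedy clustering is O(uniques × centroids) pairwise alignments; it is
  meant for the ~10³–10⁴-read scale used here, not raw deep-sequencing
  libraries (dereplication absorbs much, but not all, of the cost).
- The in-silico PCR coordinate check runs against a synthetic g23-like
  template with planted binding sites; it validates coordinate arithmetic
  and primer semantics, not primer specificity on real genomes.
- Trees are distance trees; deep phylogenetic structure among OTU
  representatives is approximate, which is acceptable for UniFrac but not
  for phylogenetic inference per se.
- The paired-sample t-test on coverage values reported alongside such
  analyses is a standard statistic available from any stats package and is
  not reimplemented here.
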