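"""Synthetic amplicon study generator with full ground truth.

Emulates the statistical structure of degenerate-primer major-capsid-protein
amplicon libraries so every pipeline stage is testable without external
data:

- haplotypes are amplicons of 142/145/148 nt (forward primer site, a
  codon-structured insert free of in-frame stops, reverse primer binding
  site), mutually divergent below a configurable identity ceiling;
- most samples are "aquatic-like": the 145-nt class dominates (~97% of
  reads); "KS-like" sediment samples instead have a dominant 148-nt class
  (~52%) with substantial 142- and 145-nt fractions and an elevated 142/145
  ratio in the deeper of the pair;
- read abundances follow a truncated lognormal with a planted singleton
  tail; reads carry per-base substitution errors and Phred-consistent
  quality strings (mean ~31, matching deep-sequencing quality levels), and
  can be decorated with barcodes for demultiplexing tests.

Everything is deterministic under a seed, and emitted truth tables map each
read to its source haplotype and each haplotype to its length class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .primer_tools import MCP_821F, MCP_966R, expand, revcomp_pattern, IUPAC_EXPANSION
from .read_filters import translate
from .otu_cluster import pairwise_identity
from .seqio import SequenceRecord, write_fastq, write_fasta

__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "StudyResult",
    "generate_haplotypes",
    "generate_reads",
    "generate_study",
    "default_study_specs",
    "synthetic_g23_reference",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# aquatic profile: 145-nt class ~97% of reads; KS-like sediment profiles:
# 148 dominant with the deeper sample carrying a higher 142/145 ratio
AQUATIC_CLASS_PROBS = {142: 0.015, 145: 0.97, 148: 0.015}
KS_SURFACE_CLASS_PROBS = {142: 0.15, 145: 0.33, 148: 0.52}
KS_DEEP_CLASS_PROBS = {142: 0.20, 145: 0.28, 148: 0.52}


@dataclass
class CommunitySpec:
    """Design of one sample's synthetic community.

    ``length_class_probs`` gives the read-level probability of each amplicon
    length class; ``abundance_model`` is ``lognormal`` (mu, sigma of the
    underlying normal) or ``geometric`` (parameter p); a
    ``singleton_fraction`` of haplotypes is pinned to exactly one read to
    plant the rare tail that Good's coverage and singleton removal exercise.
    """

    sample: str
    n_haplotypes: int = 20
    length_class_probs: dict[int, float] = field(
        default_factory=lambda: dict(AQUATIC_CLASS_PROBS)
    )
    abundance_model: str = "lognormal"
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.5
    geometric_p: float = 0.3
    singleton_fraction: float = 0.15
    reads_per_sample: int = 2000
    substitution_error_rate: float = 0.01
    quality_mean: float = 31.0
    quality_sd: float = 3.0
    low_quality_fraction: float = 0.02
    barcode: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.length_class_probs.values())
        # measured composition profiles are often rounded; renormalize small
        # discrepancies, reject anything clearly inconsistent
        if abs(total - 1.0) > 0.05:
            raise ValueError(f"length class probabilities sum to {total}, not 1")
        if total != 1.0:
            self.length_class_probs = {
                c: p / total for c, p in self.length_class_probs.items()
            }
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.abundance_model not in ("lognormal", "geometric"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")


@dataclass
class GroundTruth:
    """Generator-side truth: haplotypes, classes, and per-read provenance."""

    haplotypes: dict[str, str]  # haplotype id -> sequence
    haplotype_class: dict[str, int]  # haplotype id -> length class
    read_haplotype: dict[str, str]  # read id -> haplotype id
    read_sample: dict[str, str]  # read id -> sample

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        with open(directory / "truth_haplotypes.tsv", "w") as fh:
            fh.write("haplotype_id\tlength_class\tsequence\n")
            for hid, seq in self.haplotypes.items():
                fh.write(f"{hid}\t{self.haplotype_class[hid]}\t{seq}\n")
        with open(directory / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\tsample\thaplotype_id\n")
            for rid, hid in self.read_haplotype.items():
                fh.write(f"{rid}\t{self.read_sample[rid]}\t{hid}\n")


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), 3))
        if codon not in _STOP_CODONS:
            return codon


def _concrete(pattern: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate pattern, uniform per position."""
    return "".join(rng.choice(sorted(IUPAC_EXPANSION[c])) for c in pattern)


def _make_amplicon(length: int, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Amplicon: forward primer site + codon insert + reverse binding site.

    Length must satisfy the 145 +/- 3n frame rule; the insert is built from
    non-stop codons and the whole amplicon is rejected until its frame-0
    translation is stop-free (junction codons straddle the primer borders).
    """
    flen, rlen = len(MCP_821F), len(MCP_966R)
    insert_len = length - flen - rlen
    if insert_len < 0 or insert_len % 3 != 0:
        raise ValueError(
            f"length {length} incompatible with primer-inclusive codon layout"
        )
    rev_site_pattern = revcomp_pattern(MCP_966R.pattern)
    for _ in range(max_tries):
        fwd = _concrete(MCP_821F.pattern, rng)
        rev = _concrete(rev_site_pattern, rng)
        insert = "".join(_random_codon(rng) for _ in range(insert_len // 3))
        amplicon = fwd + insert + rev
        if "*" not in translate(amplicon, 0):
            return amplicon
    raise RuntimeError(f"could not build a stop-free amplicon of length {length}")


def _assign_classes(spec: CommunitySpec) -> list[int]:
    """Distribute haplotypes across length classes, >= 1 per active class."""
    active = [c for c, p in sorted(spec.length_class_probs.items()) if p > 0]
    if spec.n_haplotypes < len(active):
        raise ValueError(
            f"{spec.n_haplotypes} haplotypes cannot cover {len(active)} classes"
        )
    probs = np.array([spec.length_class_probs[c] for c in active])
    alloc = np.maximum(1, np.round(probs * spec.n_haplotypes).astype(int))
    while alloc.sum() > spec.n_haplotypes:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < spec.n_haplotypes:
        alloc[np.argmax(probs)] += 1
    out: list[int] = []
    for c, k in zip(active, alloc):
        out.extend([c] * int(k))
    return out


def generate_haplotypes(
    spec: CommunitySpec,
    min_pairwise_divergence: float = 0.20,
    rng: np.random.Generator | None = None,
    max_tries: int = 400,
    id_prefix: str = "hap",
) -> tuple[dict[str, str], dict[str, int]]:
    """Mutually divergent, stop-free haplotype amplicons for one community.

    Every pair of haplotypes has alignment identity <= 1 - divergence.
    Deterministic under the spec's seed.  Raises after bounded retries if
    the divergence constraint cannot be met (too many haplotypes for the
    requested divergence at this amplicon length).
    """
    rng = rng or np.random.default_rng(spec.seed)
    classes = _assign_classes(spec)
    ceiling = 1.0 - min_pairwise_divergence
    haplotypes: dict[str, str] = {}
    haplotype_class: dict[str, int] = {}
    accepted: list[str] = []
    for i, cls in enumerate(classes):
        for _ in range(max_tries):
            candidate = _make_amplicon(cls, rng)
            if all(pairwise_identity(candidate, h) <= ceiling for h in accepted):
                break
        else:
            raise RuntimeError(
                f"no haplotype at <= {ceiling:.2f} identity after {max_tries} tries; "
                "reduce n_haplotypes or min_pairwise_divergence"
            )
        hid = f"{id_prefix}_{i + 1:03d}"
        haplotypes[hid] = candidate
        haplotype_class[hid] = cls
        accepted.append(candidate)
    return haplotypes, haplotype_class


def _abundance_weights(spec: CommunitySpec, k: int, rng: np.random.Generator) -> np.ndarray:
    if k == 0:
        return np.array([])
    if spec.abundance_model == "lognormal":
        w = np.exp(rng.normal(spec.lognormal_mu, spec.lognormal_sigma, size=k))
    else:
        w = spec.geometric_p * (1 - spec.geometric_p) ** np.arange(k)
    return w / w.sum()


def _quality_string(n: int, mean: float, sd: float, rng: np.random.Generator) -> list[int]:
    q = np.clip(np.round(rng.normal(mean, sd, size=n)), 2, 41)
    return [int(v) for v in q]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
    return "".join(chars)


def generate_reads(
    haplotypes: dict[str, str],
    spec: CommunitySpec,
    haplotype_class: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
    decorate: bool = False,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Draw reads from haplotypes under the community's abundance design.

    A ``singleton_fraction`` of haplotypes is pinned to exactly one read;
    the remaining reads choose a length class by its probability and a
    haplotype within the class by the abundance model.  Per-base
    substitutions are applied at the stated rate and a
    ``low_quality_fraction`` of reads receives a degraded quality profile
    (mean ~18) to exercise the quality filter.  With ``decorate=True`` the
    sample's barcode is prepended (the amplicon already carries both primer
    sites).
    """
    rng = rng or np.random.default_rng(spec.seed)
    if haplotype_class is None:
        haplotype_class = {h: len(s) for h, s in haplotypes.items()}
    if decorate and not spec.barcode:
        raise ValueError("decorate=True requires spec.barcode")

    by_class: dict[int, list[str]] = {}
    for hid in haplotypes:
        by_class.setdefault(haplotype_class[hid], []).append(hid)

    hap_ids = list(haplotypes)
    n_singleton = int(round(spec.singleton_fraction * len(hap_ids)))
    # pin the rarest tail: choose singleton haplotypes uniformly
    singleton_ids = list(rng.choice(hap_ids, size=n_singleton, replace=False)) if n_singleton else []
    singleton_set = set(singleton_ids)

    weights: dict[int, tuple[list[str], np.ndarray]] = {}
    for cls, ids in by_class.items():
        free = [h for h in ids if h not in singleton_set]
        w = _abundance_weights(spec, len(free), rng)
        weights[cls] = (free, w)

    n_bulk = spec.reads_per_sample - len(singleton_ids)
    if n_bulk < 0:
        raise ValueError("reads_per_sample smaller than planted singleton count")

    # restrict to classes the haplotype set actually provides
    class_list = sorted(
        c for c, p in spec.length_class_probs.items() if p > 0 and c in by_class
    )
    if not class_list:
        raise ValueError("no haplotypes in any class with positive probability")
    class_p = np.array([spec.length_class_probs[c] for c in class_list])
    class_p = class_p / class_p.sum()

    source: list[str] = list(singleton_ids)
    draws = rng.choice(len(class_list), size=n_bulk, p=class_p)
    for ci in draws:
        cls = class_list[ci]
        free, w = weights[cls]
        if not free:  # class fully pinned to singletons; fall back to any member
            source.append(str(rng.choice(by_class[cls])))
            continue
        source.append(free[int(rng.choice(len(free), p=w))])
    perm = rng.permutation(len(source))

    records: list[SequenceRecord] = []
    read_hap: dict[str, str] = {}
    read_sample: dict[str, str] = {}
    for k, idx in enumerate(perm):
        hid = source[int(idx)]
        seq = _mutate(haplotypes[hid], spec.substitution_error_rate, rng)
        if decorate:
            seq = spec.barcode + seq
        low = rng.random() < spec.low_quality_fraction
        mean = 18.0 if low else spec.quality_mean
        qual = _quality_string(len(seq), mean, spec.quality_sd, rng)
        rid = f"{spec.sample}_read{k + 1:06d}"
        records.append(
            SequenceRecord(id=rid, seq=seq, qual=qual, sample=None if decorate else spec.sample)
        )
        read_hap[rid] = hid
        read_sample[rid] = spec.sample
    truth = GroundTruth(
        haplotypes=dict(haplotypes),
        haplotype_class=dict(haplotype_class),
        read_haplotype=read_hap,
        read_sample=read_sample,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Multi-sample study design


_BARCODES = ["ACGTACGT", "CGTACGTA", "GTACGTAC", "TACGTACG",
             "AACCGGTT", "CCGGTTAA", "GGTTAACC", "TTAACCGG"]


def default_study_specs(
    reads_per_sample: int = 2000,
    n_dominant: int = 12,
    seed: int | None = None,
) -> list[CommunitySpec]:
    """Eight-sample, two-biome design: four lake-like and four ocean-like.

    L2/L3 form a "KS-like" sediment pair (148-nt class dominant) with the
    deeper L3 planted at a higher 142/145 ratio than L2.  Read depth
    defaults to the shallow-sequencing scale (~2,000 reads/sample).
    """
    lake = [("L1", AQUATIC_CLASS_PROBS), ("L2", KS_SURFACE_CLASS_PROBS),
            ("L3", KS_DEEP_CLASS_PROBS), ("L4", AQUATIC_CLASS_PROBS)]
    ocean = [(f"O{i}", AQUATIC_CLASS_PROBS) for i in range(1, 5)]
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(8)
    specs = []
    for k, (name, probs) in enumerate(lake + ocean):
        specs.append(
            CommunitySpec(
                sample=name,
                n_haplotypes=n_dominant,
                length_class_probs=dict(probs),
                reads_per_sample=reads_per_sample,
                barcode=_BARCODES[k],
                seed=int(child[k].generate_state(1)[0] % (2**31)),
            )
        )
    return specs


@dataclass
class StudyResult:
    """All artifacts of a generated study."""

    specs: list[CommunitySpec]
    reads: dict[str, list[SequenceRecord]]  # sample -> reads
    truth: GroundTruth
    group_of: dict[str, str]  # sample -> biome group


def generate_study(
    specs: list[CommunitySpec] | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    n_shared_rare: int = 8,
    shared_rare_reads: int = 20,
    decorate: bool = False,
) -> StudyResult:
    """Generate the full multi-sample study with planted beta-diversity.

    The first half of the samples forms biome group "lake", the second
    "ocean"; each group draws its dominant haplotypes from a group-private
    pool (disjoint between groups) while ``n_shared_rare`` extra haplotypes
    form a rare tail (~``shared_rare_reads`` reads/sample) shared by all
    samples, so between-group UniFrac exceeds within-group UniFrac by
    construction.  Optionally writes per-sample FASTQ and TSV truth tables.
    """
    if specs is None:
        specs = default_study_specs(seed=seed)
    rng = np.random.default_rng(seed if seed is not None else specs[0].seed)
    half = len(specs) // 2
    groups = {s.sample: ("lake" if i < half else "ocean") for i, s in enumerate(specs)}

    # group-private dominant pools, mutually divergent *across* pools too:
    # generate one big divergent set, then split it stratified by length
    # class so every pool can serve every class probability profile
    n_dom = specs[0].n_haplotypes
    pool_spec = CommunitySpec(
        sample="pool",
        n_haplotypes=2 * n_dom + n_shared_rare,
        length_class_probs={142: 0.25, 145: 0.5, 148: 0.25},
        reads_per_sample=1,
        seed=int(rng.integers(2**31)),
    )
    all_haps, all_cls = generate_haplotypes(pool_spec, rng=rng, id_prefix="pool")
    pools: dict[str, list[str]] = {"lake": [], "ocean": [], "shared": []}
    capacity = {"lake": n_dom, "ocean": n_dom, "shared": n_shared_rare}
    for cls in sorted({c for c in all_cls.values()}):
        members = [h for h, c in all_cls.items() if c == cls]
        for pool in pools:  # one of each class per pool first
            if members and len(pools[pool]) < capacity[pool]:
                pools[pool].append(members.pop(0))
        while members:  # then fill by remaining capacity
            pool = max(pools, key=lambda p: capacity[p] - len(pools[p]))
            if capacity[pool] - len(pools[pool]) <= 0:
                break
            pools[pool].append(members.pop(0))

    reads: dict[str, list[SequenceRecord]] = {}
    merged_truth = GroundTruth(
        haplotypes=dict(all_haps),
        haplotype_class=dict(all_cls),
        read_haplotype={},
        read_sample={},
    )
    for s in specs:
        group = groups[s.sample]
        hap_ids = pools[group]
        haps = {h: all_haps[h] for h in hap_ids}
        cls = {h: all_cls[h] for h in hap_ids}
        # class probabilities must cover only classes this pool provides
        present = {all_cls[h] for h in hap_ids}
        probs = {c: p for c, p in s.length_class_probs.items() if c in present}
        norm = sum(probs.values())
        probs = {c: p / norm for c, p in probs.items()}
        local = CommunitySpec(
            **{**asdict(s), "length_class_probs": probs,
               "reads_per_sample": s.reads_per_sample - shared_rare_reads}
        )
        recs, truth = generate_reads(
            haps, local, cls, rng=np.random.default_rng(s.seed), decorate=decorate
        )
        # shared rare tail: one or two reads per shared haplotype
        tail_rng = np.random.default_rng((s.seed or 0) + 7)
        tail_spec = CommunitySpec(
            **{**asdict(s),
               "length_class_probs": {145: 1.0},
               "reads_per_sample": shared_rare_reads,
               "singleton_fraction": 0.0}
        )
        shared_haps = {h: all_haps[h] for h in pools["shared"]}
        shared_cls_probs = {}
        for h in pools["shared"]:
            shared_cls_probs[all_cls[h]] = shared_cls_probs.get(all_cls[h], 0) + 1
        total = sum(shared_cls_probs.values())
        tail_spec.length_class_probs = {c: v / total for c, v in shared_cls_probs.items()}
        tail_recs, tail_truth = generate_reads(
            shared_haps,
            tail_spec,
            {h: all_cls[h] for h in pools["shared"]},
            rng=tail_rng,
            decorate=decorate,
        )
        # re-id tail reads so they do not collide with bulk reads
        fixed_tail = []
        for i, rec in enumerate(tail_recs):
            rid = f"{s.sample}_tail{i + 1:04d}"
            old = rec.id
            fixed_tail.append(
                SequenceRecord(id=rid, seq=rec.seq, qual=rec.qual, sample=rec.sample)
            )
            merged_truth.read_haplotype[rid] = tail_truth.read_haplotype[old]
            merged_truth.read_sample[rid] = s.sample
        merged_truth.read_haplotype.update(truth.read_haplotype)
        merged_truth.read_sample.update(truth.read_sample)
        reads[s.sample] = recs + fixed_tail

    result = StudyResult(specs=specs, reads=reads, truth=merged_truth, group_of=groups)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in specs:
            write_fastq(reads[s.sample], out_dir / f"{s.sample}.fastq")
        merged_truth.write_tsv(out_dir)
        design = {
            "seed": seed,
            "groups": groups,
            "samples": [
                {**asdict(sp)} for sp in specs
            ],
        }
        (out_dir / "design.json").write_text(json.dumps(design, indent=2))
    return result


def synthetic_g23_reference(flank5: int = 747, flank3: int = 400, seed: int = 20) -> SequenceRecord:
    """SYNTHETIC stand-in for a g23 major-capsid-protein gene reference.

    A random-codon gene with concrete forward/reverse primer binding sites
    planted so that in-silico PCR with mcp-821F/mcp-966R spans positions
    748-893 (1-based), the coordinates the primer pair occupies on the
    Synechococcus phage S-PM2 g23 gene.  This is generated data for testing
    coordinate arithmetic, not the real S-PM2 sequence.
    """
    rng = np.random.default_rng(seed)
    # 146 nt between the outer primer ends: positions 748..893 inclusive
    fwd = _concrete(MCP_821F.pattern, rng)
    rev_site = _concrete(revcomp_pattern(MCP_966R.pattern), rng)
    insert = "".join(rng.choice(list(_BASES), 146 - len(fwd) - len(rev_site)))
    amplicon = fwd + insert + rev_site
    upstream = "".join(rng.choice(list(_BASES), flank5))
    downstream = "".join(rng.choice(list(_BASES), flank3))
    return SequenceRecord(id="synthetic_g23", seq=upstream + amplicon + downstream)
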