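"""Degenerate-primer matching, in-silico PCR, and demultiplexing.

The amplicon target here is the ~145-nt fragment of the T4-like phage g23
major capsid protein gene amplified by the degenerate pair mcp-821F
(``CTKGCDGARATYAACMGIGAART``) and mcp-966R (``ADDAGWCCYTTGAAYTTYTCAAC``).
Primer patterns are IUPAC ambiguity strings plus ``I`` for inosine, a
universal base that pairs with all four nucleotides.

Coordinates in all reported matches and amplicon hits are 1-based inclusive
on the plus strand of the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import SequenceRecord

__all__ = [
    "IUPAC_EXPANSION",
    "DegeneratePrimer",
    "PrimerMatch",
    "AmpliconHit",
    "DemuxResult",
    "ReadLayout",
    "MCP_821F",
    "MCP_966R",
    "iupac_match",
    "expansion_count",
    "revcomp_pattern",
    "find_matches",
    "insilico_pcr",
    "demultiplex_and_trim",
]

# IUPAC nucleotide ambiguity codes, plus inosine (I) which pairs universally.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

# Code-level complements; W, S, N are self-complementary and inosine stays
# inosine (it is universal on both strands).
_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "W": "W", "S": "S", "N": "N", "I": "I",
}


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named degenerate primer: an IUPAC/inosine pattern, 5'→3'."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"primer {self.name!r}: empty pattern")
        pattern = self.pattern.upper()
        bad = set(pattern) - set(IUPAC_EXPANSION)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: unknown codes {sorted(bad)} in pattern"
            )
        object.__setattr__(self, "pattern", pattern)

    def __len__(self) -> int:
        return len(self.pattern)


MCP_821F = DegeneratePrimer("mcp-821F", "CTKGCDGARATYAACMGIGAART")
MCP_966R = DegeneratePrimer("mcp-966R", "ADDAGWCCYTTGAAYTTYTCAAC")


@dataclass(frozen=True)
class PrimerMatch:
    """One primer binding window on the plus strand of a reference.

    ``start``/``end`` are 1-based inclusive positions of the first and last
    matched base; ``strand`` is '+' if the primer itself matches the plus
    strand, '-' if its reverse complement does.
    """

    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")


@dataclass(frozen=True)
class AmpliconHit:
    """A forward/reverse primer pairing delimiting a putative amplicon."""

    ref_id: str
    span_start: int
    span_end: int
    length: int
    insert_seq: str
    forward_mismatches: int = 0
    reverse_mismatches: int = 0

    @property
    def total_mismatches(self) -> int:
        return self.forward_mismatches + self.reverse_mismatches


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` is in the expansion of IUPAC/inosine ``code``.

    A reference base of N is treated as matching every code: N is absence of
    information, not evidence of mismatch.
    """
    try:
        expansion = IUPAC_EXPANSION[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC/inosine code {code!r}") from None
    base = base.upper()
    if base == "N":
        return True
    if base not in "ACGT":
        raise ValueError(f"reference base must be A/C/G/T/N, got {base!r}")
    return base in expansion


def expansion_count(primer: DegeneratePrimer | str) -> int:
    """Number of concrete sequences the degenerate pattern represents.

    The product of per-position degeneracies; inosine counts as 4.
    """
    pattern = primer.pattern if isinstance(primer, DegeneratePrimer) else primer.upper()
    return math.prod(len(IUPAC_EXPANSION[c]) for c in pattern)


def expand(pattern: str) -> list[str]:
    """All concrete A/C/G/T sequences matching the pattern (small patterns only)."""
    seqs = [""]
    for code in pattern.upper():
        bases = sorted(IUPAC_EXPANSION[code])
        seqs = [s + b for s in seqs for b in bases]
    return seqs


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of a degenerate pattern at the code level."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"unknown code {exc.args[0]!r} in pattern") from None


def _window_mismatches(pattern: str, window: str, limit: int) -> int:
    """Mismatch count of pattern vs window, short-circuiting past ``limit``."""
    mm = 0
    for code, base in zip(pattern, window):
        if base != "N" and base not in IUPAC_EXPANSION[code]:
            mm += 1
            if mm > limit:
                break
    return mm


def find_matches(
    primer: DegeneratePrimer,
    ref: SequenceRecord,
    max_mismatches: int = 0,
    search_strand: str = "both",
) -> list[PrimerMatch]:
    """All windows of the reference where the primer binds within tolerance.

    Minus-strand binding sites are found by scanning the reverse-complemented
    pattern along the plus strand; coordinates are always reported on the
    plus strand.  Results are sorted by (mismatches, start).
    """
    if search_strand not in ("+", "-", "both"):
        raise ValueError(f"search_strand must be '+', '-' or 'both', got {search_strand!r}")
    k = len(primer)
    seq = ref.seq
    patterns = []
    if search_strand in ("+", "both"):
        patterns.append((primer.pattern, "+"))
    if search_strand in ("-", "both"):
        patterns.append((revcomp_pattern(primer.pattern), "-"))
    hits: list[PrimerMatch] = []
    for pattern, strand in patterns:
        for i in range(len(seq) - k + 1):
            mm = _window_mismatches(pattern, seq[i : i + k], max_mismatches)
            if mm <= max_mismatches:
                hits.append(
                    PrimerMatch(
                        ref_id=ref.id, start=i + 1, end=i + k,
                        strand=strand, mismatches=mm,
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def insilico_pcr(
    forward: DegeneratePrimer,
    reverse: DegeneratePrimer,
    ref: SequenceRecord,
    max_mismatches: int = 0,
    min_len: int = 1,
    max_len: int = 10_000,
) -> list[AmpliconHit]:
    """Predict amplicons: a plus-strand forward match paired with a
    downstream minus-strand reverse-primer binding site.

    The amplicon span runs from the first base of the forward match to the
    last base of the reverse binding site, so its length includes both
    primers.  All qualifying non-overlapping pairs with length in
    [min_len, max_len] are reported, sorted by total mismatches then span
    length.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    fwd_hits = find_matches(forward, ref, max_mismatches, search_strand="+")
    rev_hits = find_matches(reverse, ref, max_mismatches, search_strand="-")
    amplicons: list[AmpliconHit] = []
    for f in fwd_hits:
        for r in rev_hits:
            if r.start <= f.end:  # reverse site must lie strictly downstream
                continue
            length = r.end - f.start + 1
            if not (min_len <= length <= max_len):
                continue
            amplicons.append(
                AmpliconHit(
                    ref_id=ref.id,
                    span_start=f.start,
                    span_end=r.end,
                    length=length,
                    insert_seq=ref.seq[f.end : r.start - 1],
                    forward_mismatches=f.mismatches,
                    reverse_mismatches=r.mismatches,
                )
            )
    amplicons.sort(key=lambda a: (a.total_mismatches, a.length, a.span_start))
    return amplicons


@dataclass(frozen=True)
class ReadLayout:
    """5'→3' layout of a multiplexed read.

    ``adapter``/``pad``/``linker`` are fixed-length technical spacers trimmed
    by length; the barcode sits between pad and linker, followed by the
    forward primer and the amplicon insert.  The default matches a
    single-index layout with the barcode immediately before the forward
    primer.
    """

    adapter: str = ""
    pad: str = ""
    linker: str = ""


@dataclass
class DemuxResult:
    """Per-sample read bins plus bookkeeping from demultiplexing."""

    samples: dict[str, list[SequenceRecord]]
    undetermined: list[SequenceRecord]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.samples.values()) + len(self.undetermined)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_and_trim(
    records: list[SequenceRecord],
    barcode_map: dict[str, str],
    forward: DegeneratePrimer | None = None,
    reverse: DegeneratePrimer | None = None,
    barcode_mismatches: int = 0,
    primer_mismatches: int = 2,
    trim_primers: bool = False,
    layout: ReadLayout = ReadLayout(),
) -> DemuxResult:
    """Assign reads to samples by barcode and strip technical sequence.

    ``barcode_map`` maps barcode string → sample name; barcodes must be of
    uniform length.  A read is assigned to the unique sample whose barcode
    matches within ``barcode_mismatches``; ties and non-matches go to the
    undetermined bin.  Adapter, pad, linker and barcode are always removed
    from assigned reads; when ``trim_primers`` is true the forward primer
    prefix (verified within ``primer_mismatches``) and, if present, the
    reverse-primer binding-site suffix are removed as well.

    Demultiplexing is a partition: every input read lands in exactly one bin.
    """
    if not barcode_map:
        raise ValueError("barcode_map is empty")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must be of uniform length, got lengths {sorted(lengths)}")
    bc_len = lengths.pop()
    prefix = len(layout.adapter) + len(layout.pad)
    post = len(layout.linker)

    samples: dict[str, list[SequenceRecord]] = {s: [] for s in barcode_map.values()}
    undetermined: list[SequenceRecord] = []
    counts = {s: 0 for s in barcode_map.values()}
    counts["undetermined"] = 0

    rev_site = revcomp_pattern(reverse.pattern) if reverse is not None else None

    for rec in records:
        observed = rec.seq[prefix : prefix + bc_len]
        best: list[str] = []
        best_mm = barcode_mismatches + 1
        for barcode, sample in barcode_map.items():
            mm = _hamming(barcode, observed)
            if mm < best_mm:
                best, best_mm = [sample], mm
            elif mm == best_mm:
                best.append(sample)
        if len(best) != 1 or best_mm > barcode_mismatches:
            undetermined.append(rec)
            counts["undetermined"] += 1
            continue
        sample = best[0]
        start = prefix + bc_len + post
        end = len(rec.seq)
        if trim_primers:
            if forward is None:
                raise ValueError("trim_primers=True requires a forward primer")
            window = rec.seq[start : start + len(forward)]
            if (
                len(window) < len(forward)
                or _window_mismatches(forward.pattern, window, primer_mismatches)
                > primer_mismatches
            ):
                undetermined.append(rec)
                counts["undetermined"] += 1
                continue
            start += len(forward)
            if rev_site is not None and end - start >= len(rev_site):
                suffix = rec.seq[end - len(rev_site) : end]
                if (
                    _window_mismatches(rev_site, suffix, primer_mismatches)
                    <= primer_mismatches
                ):
                    end -= len(rev_site)
        qual = rec.qual[start:end] if rec.qual is not None else None
        samples[sample].append(
            SequenceRecord(id=rec.id, seq=rec.seq[start:end], qual=qual, sample=sample)
        )
        counts[sample] += 1
    return DemuxResult(samples=samples, undetermined=undetermined, counts=counts)
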