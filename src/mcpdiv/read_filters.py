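"""Quality filtering and the frame-aware amplicon length filter.

The major-capsid-protein amplicon encodes protein, so genuine variants of
the canonical 145-nt fragment differ from it by whole codons: admissible
lengths are 145 ± 3n.  Reads whose length breaks the codon frame, or whose
translation contains a stop codon, are treated as artefacts and discarded.
The three admissible lengths that dominate real libraries are 142, 145 and
148 nt, and the 142/145 read ratio serves as a rough index of terrestrial
versus aquatic phage input (the 142-nt class is enriched in soil-derived,
non-cyanophage templates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FrameFilterConfig",
    "SampleReadSet",
    "quality_filter",
    "translate",
    "frame_filter",
    "length_class_composition",
    "source_ratio",
    "admissible_lengths",
]

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass
class FrameFilterConfig:
    """Parameters of the frame-aware length filter.

    canonical_length : int
        Length (nt) of the canonical amplicon; variants must differ from it
        by a multiple of 3.  Default 145.
    length_window : (int, int)
        Inclusive admissible length range.  Default (136, 154), i.e.
        canonical ± 3 codons.
    frame_offset : int
        Reading-frame offset (0–2) at which survivors are translated for the
        stop-codon screen.
    quality_threshold : float
        Minimum mean Phred score for `quality_filter`; reads below are
        discarded.  Default 25.
    any_frame_open : bool
        When true, a read is kept if *any* of the three frames is stop-free
        (for data whose frame is unknown); default uses `frame_offset` only.
    """

    canonical_length: int = 145
    length_window: tuple[int, int] = (136, 154)
    frame_offset: int = 0
    quality_threshold: float = 25.0
    any_frame_open: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.length_window
        if not lo <= self.canonical_length <= hi:
            raise ValueError(
                f"canonical_length {self.canonical_length} outside window {self.length_window}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")


@dataclass
class SampleReadSet:
    """Filtered, length-classified reads for one sample with a discard ledger.

    Invariant: ``len(records) + sum(discarded.values())`` equals the number
    of reads that entered the filter.
    """

    sample: str
    records: list[SequenceRecord] = field(default_factory=list)
    length_histogram: dict[int, int] = field(default_factory=dict)
    discarded: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.records)

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())


def admissible_lengths(config: FrameFilterConfig) -> set[int]:
    """All lengths in the window congruent to the canonical length mod 3."""
    lo, hi = config.length_window
    c = config.canonical_length
    return {n for n in range(lo, hi + 1) if (n - c) % 3 == 0}


def quality_filter(
    records: list[SequenceRecord],
    threshold: float = 25.0,
    mode: str = "mean",
) -> tuple[list[SequenceRecord], int]:
    """Keep reads whose mean (or minimum) Phred score is >= threshold.

    Reads without qualities (e.g. Sanger clone FASTA) bypass the filter with
    a logged notice — the clone libraries run through the same downstream
    stages without per-base scores.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"mode must be 'mean' or 'min', got {mode!r}")
    kept: list[SequenceRecord] = []
    discarded = 0
    n_unscored = 0
    for rec in records:
        if rec.qual is None:
            n_unscored += 1
            kept.append(rec)
            continue
        score = rec.mean_quality() if mode == "mean" else min(rec.qual)
        if score >= threshold:
            kept.append(rec)
        else:
            discarded += 1
    if n_unscored:
        logger.info(
            "quality_filter: %d reads without qualities passed through unfiltered",
            n_unscored,
        )
    return kept, discarded


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate with the standard genetic code.

    The trailing partial codon is ignored; codons containing N become 'X';
    stop codons are rendered '*'.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = seq.upper()
    aa = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def frame_filter(
    records: list[SequenceRecord],
    config: FrameFilterConfig | None = None,
    sample: str = "",
) -> SampleReadSet:
    """Apply the codon-frame length filter and stop-codon screen.

    Discard reasons, in order of precedence:

    - ``out_of_window``: length outside the admissible window;
    - ``non_codon_length``: length not congruent to the canonical length
      modulo 3 (no complete-codon relationship to the 145-nt fragment);
    - ``stop_codon``: the translation at the configured frame contains '*'.

    Idempotent: re-filtering a surviving set discards nothing.
    """
    config = config or FrameFilterConfig()
    lo, hi = config.length_window
    c = config.canonical_length
    out = SampleReadSet(sample=sample)
    discards = {"out_of_window": 0, "non_codon_length": 0, "stop_codon": 0}
    for rec in records:
        n = len(rec.seq)
        if not lo <= n <= hi:
            discards["out_of_window"] += 1
            continue
        if (n - c) % 3 != 0:
            discards["non_codon_length"] += 1
            continue
        if config.any_frame_open:
            open_frame = any("*" not in translate(rec.seq, f) for f in (0, 1, 2))
        else:
            open_frame = "*" not in translate(rec.seq, config.frame_offset)
        if not open_frame:
            discards["stop_codon"] += 1
            continue
        out.records.append(rec)
        out.length_histogram[n] = out.length_histogram.get(n, 0) + 1
    out.discarded = {k: v for k, v in discards.items() if v}
    return out


def length_class_composition(
    readset: SampleReadSet, classes: tuple[int, ...] = (142, 145, 148)
) -> dict[int | str, float]:
    """Proportion of surviving reads in each named length class, plus 'other'.

    Proportions sum to 1.  Raises on an empty read set (proportions would be
    undefined).
    """
    total = readset.n_kept
    if total == 0:
        raise ValueError(f"sample {readset.sample!r}: no surviving reads")
    comp: dict[int | str, float] = {}
    accounted = 0
    for cls in classes:
        count = readset.length_histogram.get(cls, 0)
        comp[cls] = count / total
        accounted += count
    comp["other"] = (total - accounted) / total
    return comp


def source_ratio(readset: SampleReadSet) -> float:
    """142/145 read-count ratio — terrestrial input relative to aquatic production.

    Raises rather than returning infinity when the sample has no 145-nt reads.
    """
    n145 = readset.length_histogram.get(145, 0)
    if n145 == 0:
        raise ValueError(
            f"sample {readset.sample!r}: no 145-nt reads; 142/145 ratio undefined"
        )
    return readset.length_histogram.get(142, 0) / n145
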