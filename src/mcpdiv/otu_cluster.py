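"""Greedy centroid OTU clustering of amplicon reads.

Operational taxonomic units are formed by the abundance-ordered greedy scan
used by classic amplicon pipelines: dereplicate exact duplicates, sort unique
sequences by descending abundance, then assign each to the first existing
centroid it matches at or above the identity threshold, founding a new
centroid otherwise.  The contract is behavioural equivalence with that
strategy, not a bit-exact reproduction of any particular tool.

Identity between two sequences is computed from a global alignment
(match +1, mismatch −1, gap open −2, gap extend −0.5, end gaps penalized)
as matches divided by alignment columns, gap columns included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .seqio import SequenceRecord, write_fasta

__all__ = [
    "OtuTable",
    "pairwise_identity",
    "cluster_greedy",
    "remove_singletons",
    "dominant_otus",
    "shared_otus",
]


def _make_aligner(end_gaps_free: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    if end_gaps_free:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


_ALIGNERS = {False: _make_aligner(False), True: _make_aligner(True)}


def pairwise_identity(a: str, b: str, end_gaps_free: bool = False) -> float:
    """Global-alignment identity of two sequences, in [0, 1].

    Identity = matched columns / total alignment columns (gaps count as
    columns).  ``end_gaps_free`` switches to an overlap alignment in which
    terminal gaps are unpenalized — relevant when clustering mixed 142/145/148
    length classes.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _ALIGNERS[end_gaps_free].align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


@dataclass
class OtuTable:
    """Samples × OTUs count matrix with representative sequences.

    ``counts[i, j]`` is the read count of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``.  Each OTU's representative is its founding (first
    assigned, most abundant) sequence.  ``membership`` maps each clustered
    read id to its OTU.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    representatives: dict[str, SequenceRecord]
    threshold: float
    membership: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sample_ids)}, {len(self.otu_ids)})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def otu_totals(self) -> np.ndarray:
        """Total count of each OTU across all samples."""
        return self.counts.sum(axis=0)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_counts(self, sample: str) -> dict[str, int]:
        """OTU → count mapping for one sample (nonzero entries only)."""
        i = self._sample_index(sample)
        row = self.counts[i]
        return {o: int(c) for o, c in zip(self.otu_ids, row) if c > 0}

    def _sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")

    def write_representatives(self, path: str | Path) -> None:
        write_fasta([self.representatives[o] for o in self.otu_ids], path)

    def write_membership(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\totu_id\n")
            for read_id, otu_id in self.membership.items():
                fh.write(f"{read_id}\t{otu_id}\n")


def cluster_greedy(
    records: list[SequenceRecord],
    threshold: float,
    order: str = "abundance",
    end_gaps_free: bool = False,
) -> OtuTable:
    """Cluster reads into OTUs at the given identity threshold.

    Dereplicates exact duplicates, orders unique sequences (descending
    abundance with input-order tie-break, or pure input order), and greedily
    assigns each to the first centroid with identity >= threshold, else
    founds a new OTU.  Deterministic given input order.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if order not in ("abundance", "input"):
        raise ValueError(f"order must be 'abundance' or 'input', got {order!r}")

    sample_ids: list[str] = []
    for rec in records:
        s = rec.sample or "unassigned"
        if s not in sample_ids:
            sample_ids.append(s)
    sample_index = {s: i for i, s in enumerate(sample_ids)}

    # dereplication: unique sequence -> (first index, first record, per-sample counts, read ids)
    uniques: dict[str, dict] = {}
    for idx, rec in enumerate(records):
        entry = uniques.setdefault(
            rec.seq,
            {"first": idx, "rec": rec, "per_sample": {}, "ids": []},
        )
        s = rec.sample or "unassigned"
        entry["per_sample"][s] = entry["per_sample"].get(s, 0) + 1
        entry["ids"].append(rec.id)

    entries = list(uniques.values())
    if order == "abundance":
        entries.sort(key=lambda e: (-len(e["ids"]), e["first"]))
    else:
        entries.sort(key=lambda e: e["first"])

    centroids: list[str] = []  # centroid sequences, in founding order
    otu_ids: list[str] = []
    representatives: dict[str, SequenceRecord] = {}
    membership: dict[str, str] = {}
    count_rows: list[dict[int, int]] = []  # per OTU: sample index -> count

    for entry in entries:
        seq = entry["rec"].seq
        assigned = None
        for j, centroid in enumerate(centroids):
            if seq == centroid or pairwise_identity(seq, centroid, end_gaps_free) >= threshold:
                assigned = j
                break
        if assigned is None:
            assigned = len(centroids)
            centroids.append(seq)
            otu_id = f"OTU_{assigned + 1:05d}"
            otu_ids.append(otu_id)
            rep = entry["rec"]
            # representative carries the OTU id so trees built from
            # representatives share labels with the table
            representatives[otu_id] = SequenceRecord(
                id=otu_id, seq=rep.seq, qual=rep.qual, sample=rep.sample
            )
            count_rows.append({})
        row = count_rows[assigned]
        for s, c in entry["per_sample"].items():
            i = sample_index[s]
            row[i] = row.get(i, 0) + c
        otu_id = otu_ids[assigned]
        for read_id in entry["ids"]:
            membership[read_id] = otu_id

    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=int)
    for j, row in enumerate(count_rows):
        for i, c in row.items():
            counts[i, j] = c
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=counts,
        representatives=representatives,
        threshold=threshold,
        membership=membership,
    )


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across *all* samples is exactly 1."""
    keep = [j for j, t in enumerate(table.otu_totals()) if t != 1]
    otu_ids = [table.otu_ids[j] for j in keep]
    dropped = set(table.otu_ids) - set(otu_ids)
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=list(table.sample_ids),
        counts=table.counts[:, keep] if keep else np.zeros((table.n_samples, 0), dtype=int),
        representatives={o: table.representatives[o] for o in otu_ids},
        threshold=table.threshold,
        membership={r: o for r, o in table.membership.items() if o not in dropped},
    )


def dominant_otus(
    table: OtuTable, min_rel_abundance: float = 0.02
) -> dict[str, set[str]]:
    """Per-sample sets of OTUs with relative abundance strictly above threshold.

    An OTU at exactly the threshold is *not* dominant (strict inequality).
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    out: dict[str, set[str]] = {}
    for i, sample in enumerate(table.sample_ids):
        rel = table.counts[i] / totals[i]
        out[sample] = {o for o, r in zip(table.otu_ids, rel) if r > min_rel_abundance}
    return out


def shared_otus(
    table: OtuTable,
    sample_group_a: list[str],
    sample_group_b: list[str],
    dominant_only: bool = False,
    min_rel_abundance: float = 0.02,
) -> tuple[int, int]:
    """Count OTUs shared between two sample groups, as (shared, union).

    An OTU is counted for a group if it is present (or, with
    ``dominant_only``, dominant) in at least one sample of the group.
    """
    if not sample_group_a or not sample_group_b:
        raise ValueError("sample groups must be non-empty")
    if set(sample_group_a) & set(sample_group_b):
        raise ValueError("sample groups must be disjoint")
    for s in list(sample_group_a) + list(sample_group_b):
        table._sample_index(s)  # raises KeyError on unknown sample

    if dominant_only:
        dom = dominant_otus(table, min_rel_abundance)
        set_a = set().union(*(dom[s] for s in sample_group_a))
        set_b = set().union(*(dom[s] for s in sample_group_b))
    else:
        def present(samples: list[str]) -> set[str]:
            rows = [table._sample_index(s) for s in samples]
            mask = table.counts[rows].sum(axis=0) > 0
            return {o for o, m in zip(table.otu_ids, mask) if m}

        set_a = present(sample_group_a)
        set_b = present(sample_group_b)
    return len(set_a & set_b), len(set_a | set_b)
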