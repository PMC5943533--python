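"""End-to-end pipeline: quality filter → demultiplex/trim → frame filter →
OTU clustering → alpha diversity → beta diversity, with a run manifest.

Every stage writes its standard artifact (per-sample filtered FASTA, discard
ledgers, OTU tables per threshold, representative FASTA, Newick trees,
distance matrices, rarefaction/coverage tables, ordination coordinates) and
reports read counts, so stage-level conservation (reads in = kept +
discarded) can be audited from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, otu_cluster, read_filters, seqio
from .primer_tools import (
    MCP_821F,
    MCP_966R,
    DegeneratePrimer,
    demultiplex_and_trim,
)
from .read_filters import FrameFilterConfig

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    ``inputs`` maps sample name → demultiplexed FASTQ/FASTA path; or set
    ``multiplexed_input`` plus ``barcode_map`` (barcode → sample) to start
    from a pooled file.  ``clustering_thresholds`` defaults to the standard
    80/90/95/97% identity series; ``primary_threshold`` selects the table
    used for diversity analyses.
    """

    output_dir: str | Path = "mcpdiv_out"
    inputs: dict[str, str] = field(default_factory=dict)
    multiplexed_input: str | None = None
    barcode_map: dict[str, str] = field(default_factory=dict)
    forward_primer: str = MCP_821F.pattern
    reverse_primer: str = MCP_966R.pattern
    trim_primers: bool = False
    barcode_mismatches: int = 0
    frame_filter: FrameFilterConfig = field(default_factory=FrameFilterConfig)
    clustering_thresholds: tuple[float, ...] = (0.80, 0.90, 0.95, 0.97)
    primary_threshold: float = 0.90
    remove_singletons: bool = True
    rarefaction_depths: tuple[int, ...] = ()  # default: auto grid
    unifrac_weighted: bool = False
    jackknife_reps: int = 100
    jackknife_depth_fraction: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        for t in list(self.clustering_thresholds) + [self.primary_threshold]:
            if not 0 < t <= 1:
                raise ValueError(f"identity threshold {t} outside (0, 1]")
        if self.primary_threshold not in self.clustering_thresholds:
            raise ValueError("primary_threshold must be one of clustering_thresholds")
        if self.multiplexed_input is None and not self.inputs:
            raise ValueError("no inputs configured")
        paths = list(self.inputs.values())
        if self.multiplexed_input:
            if not self.barcode_map:
                raise ValueError("multiplexed input requires a barcode_map")
            paths.append(self.multiplexed_input)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input files not found: {missing}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file into a :class:`PipelineConfig`."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "frame_filter" in raw:
        ff = raw["frame_filter"]
        if "length_window" in ff:
            ff["length_window"] = tuple(ff["length_window"])
        raw["frame_filter"] = FrameFilterConfig(**ff)
    for key in ("clustering_thresholds", "rarefaction_depths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _read_records(path: str) -> list[seqio.SequenceRecord]:
    p = Path(path)
    suffixes = {s.lower() for s in p.suffixes}
    if {".fastq", ".fq"} & suffixes:
        return seqio.read_fastq(p)
    return seqio.read_fasta(p)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON).

    On a stage failure the manifest is still written, with a FAILED marker
    naming the stage, and the exception is re-raised.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "forward_primer": config.forward_primer,
            "reverse_primer": config.reverse_primer,
            "trim_primers": config.trim_primers,
            "clustering_thresholds": list(config.clustering_thresholds),
            "primary_threshold": config.primary_threshold,
            "quality_threshold": config.frame_filter.quality_threshold,
            "canonical_length": config.frame_filter.canonical_length,
            "length_window": list(config.frame_filter.length_window),
            "jackknife_reps": config.jackknife_reps,
            "jackknife_depth_fraction": config.jackknife_depth_fraction,
            "seed": config.seed,
        },
        "stages": {},
        "artifacts": {},
    }
    stage = "load"
    try:
        fwd = DegeneratePrimer("forward", config.forward_primer)
        rev = DegeneratePrimer("reverse", config.reverse_primer)

        if config.multiplexed_input:
            raw = {None: _read_records(config.multiplexed_input)}
        else:
            raw = {}
            for s, p in config.inputs.items():
                records = _read_records(p)
                for rec in records:
                    rec.sample = s
                raw[s] = records
        manifest["stages"]["load"] = {k or "multiplexed": len(v) for k, v in raw.items()}

        stage = "quality_filter"
        qstats = {}
        filtered: dict[str | None, list] = {}
        for key, records in raw.items():
            kept, discarded = read_filters.quality_filter(
                records, threshold=config.frame_filter.quality_threshold
            )
            filtered[key] = kept
            qstats[key or "multiplexed"] = {
                "in": len(records), "kept": len(kept), "discarded": discarded,
            }
        manifest["stages"]["quality_filter"] = qstats

        stage = "demultiplex"
        if config.multiplexed_input:
            demux = demultiplex_and_trim(
                filtered[None],
                config.barcode_map,
                forward=fwd,
                reverse=rev,
                barcode_mismatches=config.barcode_mismatches,
                trim_primers=config.trim_primers,
            )
            per_sample = demux.samples
            manifest["stages"]["demultiplex"] = dict(demux.counts)
        else:
            per_sample = {s: recs for s, recs in filtered.items()}

        stage = "frame_filter"
        readsets = {}
        fstats = {}
        for sample, records in per_sample.items():
            rs = read_filters.frame_filter(records, config.frame_filter, sample=sample)
            readsets[sample] = rs
            fstats[sample] = {
                "in": len(records), "kept": rs.n_kept, "discarded": dict(rs.discarded),
            }
            fasta = out / f"{sample}.filtered.fasta"
            seqio.write_fasta(rs.records, fasta)
            manifest["artifacts"][f"filtered_fasta:{sample}"] = str(fasta)
        manifest["stages"]["frame_filter"] = fstats
        ledger = pd.DataFrame(
            {
                s: {**{"kept": st["kept"]}, **st["discarded"]}
                for s, st in fstats.items()
            }
        ).fillna(0).astype(int).T
        ledger.to_csv(out / "discard_ledger.tsv", sep="\t", index_label="sample")
        manifest["artifacts"]["discard_ledger"] = str(out / "discard_ledger.tsv")

        comp = {}
        ratios = {}
        for sample, rs in readsets.items():
            if rs.n_kept:
                comp[sample] = read_filters.length_class_composition(rs)
                try:
                    ratios[sample] = read_filters.source_ratio(rs)
                except ValueError:
                    ratios[sample] = float("nan")
        pd.DataFrame(comp).T.to_csv(out / "length_classes.tsv", sep="\t", index_label="sample")
        pd.Series(ratios, name="ratio_142_145").to_csv(
            out / "source_ratio.tsv", sep="\t", index_label="sample"
        )
        manifest["stages"]["length_classes"] = {
            s: {str(k): v for k, v in c.items()} for s, c in comp.items()
        }
        manifest["stages"]["source_ratio"] = ratios

        stage = "cluster"
        pooled = [r for rs in readsets.values() for r in rs.records]
        tables = {}
        cstats = {}
        for t in config.clustering_thresholds:
            table = otu_cluster.cluster_greedy(pooled, threshold=t)
            if config.remove_singletons:
                table_out = otu_cluster.remove_singletons(table)
            else:
                table_out = table
            tables[t] = table_out
            cstats[f"{t:.2f}"] = {
                "otus": table.n_otus,
                "otus_no_singletons": table_out.n_otus,
                "reads": int(table.counts.sum()),
            }
            path = out / f"otu_table_{int(round(t * 100))}.tsv"
            table_out.write_tsv(path)
            manifest["artifacts"][f"otu_table:{t:.2f}"] = str(path)
        manifest["stages"]["cluster"] = cstats
        primary = tables[config.primary_threshold]
        rep_path = out / "representatives.fasta"
        primary.write_representatives(rep_path)
        manifest["artifacts"]["representatives"] = str(rep_path)

        stage = "alpha"
        totals = primary.sample_totals()
        min_total = int(totals.min())
        depths = list(config.rarefaction_depths) or [
            max(1, int(round(f * min_total))) for f in (0.1, 0.25, 0.5, 0.75, 1.0)
        ]
        alpha_rows = []
        for i, sample in enumerate(primary.sample_ids):
            counts = primary.counts[i][primary.counts[i] > 0]
            for res in diversity.rarefaction_curve(
                counts, [d for d in depths if d <= counts.sum()],
                mode="exact", sample=sample,
            ):
                alpha_rows.append(
                    {
                        "sample": res.sample, "depth": res.depth,
                        "observed_otus": res.observed_otus,
                        "goods_coverage": res.goods_coverage,
                    }
                )
        alpha_df = pd.DataFrame(alpha_rows)
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        manifest["artifacts"]["alpha_diversity"] = str(out / "alpha_diversity.tsv")
        manifest["stages"]["alpha"] = {"depths": depths, "rows": len(alpha_rows)}

        stage = "beta"
        reps = [primary.representatives[o] for o in primary.otu_ids]
        tree = diversity.build_tree(reps, method="upgma")
        tree.write_newick(out / "otu_tree.nwk")
        manifest["artifacts"]["otu_tree"] = str(out / "otu_tree.nwk")
        beta = {}
        for weighted, tag in ((False, "unweighted"), (True, "weighted")):
            dm = diversity.unifrac(primary, tree, weighted=weighted)
            dm.write_tsv(out / f"unifrac_{tag}.tsv")
            manifest["artifacts"][f"unifrac:{tag}"] = str(out / f"unifrac_{tag}.tsv")
            ordination = diversity.pcoa(dm)
            ordination.write_tsv(out / f"pcoa_{tag}.tsv")
            manifest["artifacts"][f"pcoa:{tag}"] = str(out / f"pcoa_{tag}.tsv")
            beta[tag] = {
                "mean_distance": float(
                    dm.data[np.triu_indices(len(dm.labels), 1)].mean()
                )
            }
        manifest["stages"]["beta"] = beta

        stage = "jackknife"
        if primary.n_samples >= 3 and config.jackknife_reps >= 0:
            jk = diversity.sample_upgma_with_jackknife(
                primary,
                tree,
                reps=config.jackknife_reps,
                depth_fraction=config.jackknife_depth_fraction,
                seed=config.seed,
                weighted=config.unifrac_weighted,
            )
            jk.write_newick(out / "sample_tree_jackknife.nwk")
            manifest["artifacts"]["sample_tree"] = str(out / "sample_tree_jackknife.nwk")

        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["checksums"] = {
        name: _md5(Path(p)) for name, p in manifest["artifacts"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
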