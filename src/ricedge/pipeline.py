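"""End-to-end orchestration: simulate -> index -> map -> test -> classify -> enrich.

One seeded stream drives the whole run, with fixed per-stage substreams, so
re-running a stage in isolation reproduces its output. All tables are
tab-separated UTF-8 with one header row; the machine-readable run report
records each stage's parameters and the SHA-256 of every file it wrote, so
two runs with the same config are bit-identical exactly when their reports
agree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import dominance, enrichment, mapping, simulate, tags
from .diffexpr import DEFAULT_FDR, DEFAULT_RATIO, call_degs


@dataclass
class RunConfig:
    synthetic: simulate.SyntheticConfig = field(default_factory=simulate.SyntheticConfig)
    fdr: float = DEFAULT_FDR
    log2_threshold: float = DEFAULT_RATIO
    max_mismatch: int = 1
    outdir: str = "ricedge_run"

    def __post_init__(self) -> None:
        if self.fdr <= 0 or self.log2_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn_raw = raw.pop("synthetic", {})
        if "transcript_length" in syn_raw:
            syn_raw["transcript_length"] = tuple(syn_raw["transcript_length"])
        if "category_proportions" in syn_raw:
            syn_raw["category_proportions"] = dict(syn_raw["category_proportions"])
        return cls(synthetic=simulate.SyntheticConfig(**syn_raw), **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full synthetic analysis; returns the machine-readable report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "parameters": {
            "synthetic": dataclasses.asdict(config.synthetic),
            "fdr": config.fdr,
            "log2_threshold": config.log2_threshold,
            "max_mismatch": config.max_mismatch,
        },
        "stages": [],
    }
    syn = config.synthetic

    def record(stage: str, files: Dict[str, Path], extra: Optional[Dict] = None) -> None:
        report["stages"].append(
            {
                "stage": stage,
                "outputs": {name: _sha256(p) for name, p in files.items()},
                **({"summary": extra} if extra else {}),
            }
        )

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - named-stage abort
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- simulate ---------------------------------------------------------
    def _simulate():
        transcripts = simulate.generate_transcriptome(syn)
        truth = simulate.generate_expression_profiles(syn)
        annotation = simulate.generate_pathway_annotation(syn, truth)
        simulate.write_fasta(transcripts, out / "transcripts.fasta")
        simulate.write_truth_tsv(truth, out / "truth.tsv")
        simulate.write_annotation_tsv(annotation, out / "annotation.tsv")
        libs = {}
        for name, ab, sub in (
            ("p1", truth.p1, 11),
            ("p2", truth.p2, 12),
            ("f1", truth.f1, 13),
        ):
            df = simulate.sample_tag_library(
                transcripts, ab, syn.depth, syn.error_rate, seed=syn.seed * 1000 + sub
            )
            df.to_csv(out / f"library_{name}.tsv", sep="\t", index=False)
            libs[name] = df
        record(
            "simulate",
            {
                "transcripts": out / "transcripts.fasta",
                "truth": out / "truth.tsv",
                "annotation": out / "annotation.tsv",
                **{f"library_{k}": out / f"library_{k}.tsv" for k in libs},
            },
        )
        return transcripts, truth, annotation

    transcripts, truth, annotation = stage("simulate")(_simulate)

    # --- build index ------------------------------------------------------
    def _index():
        index, untaggable = tags.index_transcripts(transcripts)
        tags.write_index_tsv(index, out / "tag_index.tsv")
        record(
            "build-index",
            {"tag_index": out / "tag_index.tsv"},
            {"distinct_tags": len(index), "untaggable_genes": len(untaggable)},
        )
        return index

    index = stage("build-index")(_index)

    # --- map --------------------------------------------------------------
    def _map():
        mapped, stats_rows = {}, []
        for name in ("p1", "p2", "f1"):
            observed = mapping.ObservedTagSet.from_tsv(
                out / f"library_{name}.tsv", library_id=name
            )
            counts, stats = mapping.map_tags(observed, index, config.max_mismatch)
            mapping.write_gene_counts_tsv(counts, out / f"gene_counts_{name}.tsv")
            mapped[name] = counts
            stats_rows.append({"library": name, **stats.as_dict()})
        pd.DataFrame(stats_rows).to_csv(out / "mapping_stats.tsv", sep="\t", index=False)
        record(
            "map",
            {
                **{f"gene_counts_{k}": out / f"gene_counts_{k}.tsv" for k in mapped},
                "mapping_stats": out / "mapping_stats.tsv",
            },
        )
        return mapped

    mapped = stage("map")(_map)

    # --- differential expression (pairwise) -------------------------------
    def _de():
        pair_counts = {}
        for a, b in (("p1", "f1"), ("p2", "f1"), ("p1", "p2")):
            de = call_degs(
                mapped[a], mapped[b], fdr_threshold=config.fdr,
                ratio_threshold=config.log2_threshold,
            )
            de.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t", index=False)
            sig = de[de["significant"]]
            pair_counts[f"{a}_vs_{b}"] = {
                "up": int((sig["log2_ratio"] > 0).sum()),
                "down": int((sig["log2_ratio"] < 0).sum()),
            }
        pd.DataFrame(
            [
                {"comparison": k, "up": v["up"], "down": v["down"]}
                for k, v in pair_counts.items()
            ]
        ).to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        record(
            "de",
            {
                **{
                    f"de_{a}_vs_{b}": out / f"de_{a}_vs_{b}.tsv"
                    for a, b in (("p1", "f1"), ("p2", "f1"), ("p1", "p2"))
                },
                "deg_counts": out / "deg_counts.tsv",
            },
            pair_counts,
        )

    stage("de")(_de)

    # --- dominance classification -----------------------------------------
    def _classify():
        calls = dominance.classify_counts(
            mapped["p1"], mapped["p2"], mapped["f1"],
            threshold=config.log2_threshold, fdr_threshold=config.fdr,
        )
        calls.to_csv(out / "dominance_calls.tsv", sep="\t", index=False)
        summary = dominance.summarize_categories(calls)
        pd.DataFrame(
            [{"category": k, "count": v} for k, v in summary.items()]
        ).to_csv(out / "category_summary.tsv", sep="\t", index=False)
        record(
            "classify",
            {
                "dominance_calls": out / "dominance_calls.tsv",
                "category_summary": out / "category_summary.tsv",
            },
            {str(k): v for k, v in summary.items()},
        )
        return calls

    calls = stage("classify")(_classify)

    # --- enrichment --------------------------------------------------------
    def _enrich():
        degs = calls.loc[calls["nonadditive_call"], "gene_id"]
        expressed = calls["gene_id"]
        table = enrichment.enrich(degs, annotation, expressed)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        record(
            "enrich",
            {"enrichment": out / "enrichment.tsv"},
            {"n_degs": int(len(degs)), "n_pathways": int(len(table))},
        )

    stage("enrich")(_enrich)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
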