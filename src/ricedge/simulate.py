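"""Synthetic parent/parent/hybrid tag-DGE data with known ground truth.

The generator emulates the structure of a two-parent/hybrid rice tag
profiling experiment: a transcriptome in which every cDNA carries at least
one CATG site with 17 nt downstream (so every gene has a canonical tag),
heavy-tailed parental expression, a hybrid whose per-gene expression
follows one of five inheritance modes, multinomial tag sampling with
optional per-base substitution noise, and a KEGG-style gene-to-pathway
annotation with optional enrichment spiking.

Hybrid construction, on un-normalized parental abundances (MP, HP, LP are
the mid/high/low parent):

    additive        F1 = MP
    above_mid       F1 = MP * 2^e
    below_mid       F1 = MP * 2^-e
    overdominant    F1 = HP * 2^e
    underdominant   F1 = LP * 2^-e

with effect size e >= 1 so the truth is recoverable under the |log2| >= 1
classification rule. Each library is then renormalized to sum to one;
default category proportions keep the non-additive mass small (as in real
hybrid data), so renormalization perturbs ratios by only ~0.02-0.03 log2
units. Default proportions derive from the published category counts over
~19,500 detected genes (below-mid-only 490, above-mid-only 173,
overdominant 298, underdominant 129).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .tags import SITE, TAG_LENGTH, Transcript, extract_reference_tags

CATEGORIES = ("additive", "above_mid", "below_mid", "overdominant", "underdominant")

DEFAULT_PROPORTIONS = {
    "additive": 0.9441,
    "above_mid": 0.0089,
    "below_mid": 0.0251,
    "overdominant": 0.0153,
    "underdominant": 0.0066,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic trio."""

    n_genes: int = 2000
    transcript_length: Tuple[int, int] = (200, 2000)
    depth: int = 200_000
    error_rate: float = 0.001
    category_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_log2: float = 1.5
    abundance_sigma: float = 1.5  # natural-log scale of the parental log-normal
    n_pathways: int = 50
    spiked_pathways: int = 2
    annotated_fraction: float = 0.86
    spike_fraction: float = 0.5  # fraction of a spiked pathway drawn from non-additive genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.transcript_length
        if hi < 25:
            raise ValueError(
                "transcript_length max must be >= 25 to host a CATG+17 tag"
            )
        if not 0 < lo <= hi:
            raise ValueError("transcript_length must satisfy 0 < min <= max")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if set(self.category_proportions) != set(CATEGORIES):
            raise ValueError(f"category_proportions must cover {CATEGORIES}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_proportions sum to {total}, not 1")
        if self.effect_log2 < 1.0:
            raise ValueError("effect_log2 must be >= 1 for recoverable truths")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must lie in [0, 1]")
        if self.spiked_pathways > self.n_pathways:
            raise ValueError("spiked_pathways cannot exceed n_pathways")


@dataclass
class GroundTruth:
    """Per-gene truth table plus normalized abundance vectors."""

    table: pd.DataFrame  # gene_id, category, abundance_*, true_log2_*
    p1: np.ndarray
    p2: np.ndarray
    f1: np.ndarray


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent, reproducible substream per generator stage; the stream
    # key must not depend on PYTHONHASHSEED, hence the explicit byte sum
    key = int.from_bytes(stream.encode(), "big") % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def _gene_ids(n: int) -> List[str]:
    width = max(5, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def generate_transcriptome(config: SyntheticConfig) -> List[Transcript]:
    """Random ACGT transcripts, each guaranteed one eligible CATG site.

    If a drawn sequence lacks a CATG with 17 nt downstream, a CATG+17
    window is injected at a random eligible position. Transcripts are
    re-drawn (rarely) until all their 21-mer tags are unique across the
    transcriptome, so noise-free libraries map without ambiguity.
    """
    rng = _rng(config, "transcriptome")
    lo, hi = config.transcript_length
    seen_tags: set = set()
    transcripts: List[Transcript] = []
    for gene_id in _gene_ids(config.n_genes):
        for _ in range(100):
            length = int(rng.integers(lo, hi + 1))
            seq_arr = _BASES[rng.integers(0, 4, size=length)]
            seq = "".join(seq_arr)
            tags = extract_reference_tags(Transcript(gene_id, seq))
            if not tags:
                pos = int(rng.integers(0, length - TAG_LENGTH + 1))
                window = SITE + "".join(_BASES[rng.integers(0, 4, size=TAG_LENGTH - len(SITE))])
                seq = seq[:pos] + window + seq[pos + TAG_LENGTH :]
                tags = extract_reference_tags(Transcript(gene_id, seq))
            tag_seqs = {t.tag for t in tags}
            if tags and len(tag_seqs) == len(tags) and not (tag_seqs & seen_tags):
                seen_tags.update(tag_seqs)
                transcripts.append(Transcript(gene_id, seq))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not draw a unique-tag transcript for {gene_id}")
    return transcripts


def generate_expression_profiles(config: SyntheticConfig) -> GroundTruth:
    """Parental and hybrid abundance vectors with a category truth table.

    Parental abundances are log-normal (heavy-tailed, many-low/few-high);
    the hybrid is built per category on un-normalized values and every
    library is renormalized to sum to one. True log2 ratios versus mid-,
    high- and low-parent are recorded pre-normalization.
    """
    rng = _rng(config, "expression")
    n = config.n_genes
    labels = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in labels])
    categories = rng.choice(labels, size=n, p=probs)
    p1 = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    p2 = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    mp = (p1 + p2) / 2.0
    hp = np.maximum(p1, p2)
    lp = np.minimum(p1, p2)
    e = config.effect_log2
    f1 = mp.copy()
    f1[categories == "above_mid"] = (mp * 2.0**e)[categories == "above_mid"]
    f1[categories == "below_mid"] = (mp * 2.0**-e)[categories == "below_mid"]
    f1[categories == "overdominant"] = (hp * 2.0**e)[categories == "overdominant"]
    f1[categories == "underdominant"] = (lp * 2.0**-e)[categories == "underdominant"]
    table = pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "category": categories,
            "true_log2_mid": np.log2(f1 / mp),
            "true_log2_high": np.log2(f1 / hp),
            "true_log2_low": np.log2(f1 / lp),
            "abundance_p1": p1 / p1.sum(),
            "abundance_p2": p2 / p2.sum(),
            "abundance_f1": f1 / f1.sum(),
        }
    )
    return GroundTruth(
        table=table, p1=p1 / p1.sum(), p2=p2 / p2.sum(), f1=f1 / f1.sum()
    )


def canonical_tags(transcripts: List[Transcript]) -> List[str]:
    """The 3'-most CATG+17 tag of each transcript, in transcript order."""
    out = []
    for tr in transcripts:
        tags = extract_reference_tags(tr)
        if not tags:
            raise ValueError(f"transcript {tr.gene_id} has no canonical tag")
        out.append(tags[0].tag)
    return out


def sample_tag_library(
    transcripts: List[Transcript],
    abundance: np.ndarray,
    depth: int,
    error_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Multinomial draw of ``depth`` canonical tags with substitution noise.

    Each sampled tag independently substitutes each base with total
    probability ``error_rate`` (uniform over the three alternatives).
    Returns a (tag, count) table whose counts sum to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    abundance = np.asarray(abundance, dtype=float)
    if len(abundance) != len(transcripts):
        raise ValueError("abundance vector and transcript set differ in length")
    rng = np.random.default_rng(seed)
    tags = canonical_tags(transcripts)
    draws = rng.multinomial(depth, abundance / abundance.sum())
    counts: Dict[str, int] = {}
    if error_rate == 0.0:
        for tag, c in zip(tags, draws):
            if c:
                counts[tag] = counts.get(tag, 0) + int(c)
    else:
        p_clean = (1.0 - error_rate) ** TAG_LENGTH
        for tag, c in zip(tags, draws):
            if not c:
                continue
            n_mut = int(rng.binomial(c, 1.0 - p_clean))
            if c - n_mut:
                counts[tag] = counts.get(tag, 0) + int(c - n_mut)
            base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
            arr = np.array([base_idx[b] for b in tag])
            for _ in range(n_mut):
                # substitution pattern conditional on >= 1 substituted base
                while True:
                    hits = rng.random(TAG_LENGTH) < error_rate
                    if hits.any():
                        break
                mutated = arr.copy()
                shifts = rng.integers(1, 4, size=int(hits.sum()))
                mutated[hits] = (mutated[hits] + shifts) % 4
                mtag = "".join(_BASES[mutated])
                counts[mtag] = counts.get(mtag, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["tag", "count"]
    )


def generate_pathway_annotation(
    config: SyntheticConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Gene-to-pathway map with skewed sizes and optional spiked pathways.

    Only a configurable fraction of genes carries any annotation (real
    annotated universes are smaller than the detected transcriptome).
    Spiked pathways draw a fraction of their members from the non-additive
    gene pool, making their enrichment recoverable downstream.
    """
    rng = _rng(config, "annotation")
    genes = truth.table["gene_id"].to_numpy()
    n_annotated = int(round(config.annotated_fraction * len(genes)))
    annotated = rng.choice(genes, size=n_annotated, replace=False)
    annotated_set = set(annotated)
    nonadditive = truth.table.loc[
        truth.table["category"] != "additive", "gene_id"
    ].to_numpy()
    nonadd_pool = np.array([g for g in nonadditive if g in annotated_set])
    rows = []
    for i in range(config.n_pathways):
        pathway_id = f"path{i + 1:03d}"
        # skewed pathway sizes, emulating few large / many small pathways
        size = int(np.clip(rng.lognormal(np.log(0.02 * max(n_annotated, 1)), 1.0), 5, None))
        size = min(size, n_annotated)
        if i < config.spiked_pathways and len(nonadd_pool) > 0:
            n_spike = min(int(round(config.spike_fraction * size)), len(nonadd_pool))
            spiked = rng.choice(nonadd_pool, size=n_spike, replace=False)
            rest_pool = np.array([g for g in annotated if g not in set(spiked)])
            rest = rng.choice(rest_pool, size=size - n_spike, replace=False)
            members = np.concatenate([spiked, rest])
        else:
            members = rng.choice(annotated, size=size, replace=False)
        for g in members:
            rows.append({"gene_id": g, "pathway_id": pathway_id, "pathway_name": pathway_id})
    return pd.DataFrame(rows)


def write_fasta(transcripts: List[Transcript], path) -> None:
    with open(path, "w") as fh:
        for tr in transcripts:
            fh.write(f">{tr.gene_id}\n")
            for i in range(0, len(tr.sequence), 70):
                fh.write(tr.sequence[i : i + 70] + "\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)
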