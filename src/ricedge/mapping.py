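"""Observed-tag mapping with at most one mismatch and multi-gene filtering.

Mapping semantics follow the tag-DGE convention: an observed tag is first
looked up exactly; only if there is no exact entry are all 63 single-base
variants queried, and the candidate gene set is the union over those hits.
A tag whose candidate set contains more than one gene is discarded as
ambiguous (it still counts toward the library size N), a tag with no
candidates is unmapped. Ambiguity is judged at the gene level: several
distance-1 reference tags of the *same* gene leave the tag unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .tags import TAG_LENGTH, TagIndex

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class ObservedTagSet:
    """Distinct observed tag sequences with their library counts."""

    library_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path, library_id: str | None = None) -> "ObservedTagSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            library_id=library_id or str(path),
            counts=dict(zip(df["tag"], df["count"].astype(int))),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["tag", "count"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MappedCounts:
    """Per-gene unambiguous tag counts and the clean-tag library size N.

    N counts every clean tag, including ambiguous and unmapped ones:
    "per million clean tags" is defined on clean tags, not mapped tags.
    """

    library_id: str
    counts: Dict[str, int]
    library_size: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.library_id).sort_index()


@dataclass
class MappingStats:
    """Distinct-tag partition of the mapping outcome."""

    total_tags: int = 0  # summed counts (library size N)
    distinct_tags: int = 0
    exact_mapped: int = 0
    mismatch_mapped: int = 0
    ambiguous_filtered: int = 0
    unmapped: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def one_mismatch_variants(tag: str) -> List[str]:
    """The 63 sequences at Hamming distance exactly 1 from a 21-mer."""
    out = []
    for i, base in enumerate(tag):
        for alt in _BASES:
            if alt != base:
                out.append(tag[:i] + alt + tag[i + 1 :])
    return out


def map_tags(
    observed: ObservedTagSet, index: TagIndex, max_mismatch: int = 1
) -> Tuple[MappedCounts, MappingStats]:
    """Assign observed tag counts to genes, filtering multi-gene hits.

    Exact matches take precedence over 1-mismatch candidates, so a
    sequencing error in one gene's tag cannot alias another gene's exact
    tag. Tags with non-ACGT characters are counted as unmapped with a
    warning; a tag of the wrong length is an input error.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    gene_counts: Dict[str, int] = {g: 0 for g in index.per_gene}
    stats = MappingStats()
    for tag, count in observed.counts.items():
        if count < 0:
            raise ValueError(f"negative count for tag {tag!r}")
        if len(tag) != TAG_LENGTH:
            raise ValueError(f"observed tag of length {len(tag)} != {TAG_LENGTH}: {tag!r}")
        stats.total_tags += count
        stats.distinct_tags += 1
        if any(b not in _BASES for b in tag):
            logger.warning("tag with non-ACGT character treated as unmapped: %s", tag)
            stats.unmapped += 1
            continue
        candidates = index.genes_for(tag)
        exact = bool(candidates)
        if not exact and max_mismatch == 1:
            hit: set = set()
            for variant in one_mismatch_variants(tag):
                hit.update(index.genes_for(variant))
            candidates = frozenset(hit)
        if len(candidates) == 1:
            gene_counts[next(iter(candidates))] += count
            if exact:
                stats.exact_mapped += 1
            else:
                stats.mismatch_mapped += 1
        elif len(candidates) > 1:
            stats.ambiguous_filtered += 1
        else:
            stats.unmapped += 1
    return (
        MappedCounts(observed.library_id, gene_counts, stats.total_tags),
        stats,
    )


def normalize_tpm(counts: MappedCounts) -> pd.Series:
    """Tags per million clean tags: count * 1e6 / N, zeros preserved."""
    if counts.library_size <= 0:
        raise ValueError("library size N must be positive for TPM")
    series = counts.as_series().astype(float)
    return (series * 1e6 / counts.library_size).rename(counts.library_id)


def write_gene_counts_tsv(counts: MappedCounts, path) -> None:
    # N (clean-tag total incl. ambiguous/unmapped) is not recoverable from
    # the per-gene rows, so it rides along in a comment line.
    tpm = normalize_tpm(counts)
    df = pd.DataFrame(
        {"gene_id": tpm.index, "count": counts.as_series().values, "tpm": tpm.values}
    )
    with open(path, "w") as fh:
        fh.write(f"# library_size={counts.library_size}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gene_counts_tsv(path, library_id: str | None = None) -> MappedCounts:
    library_size = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# library_size="):
            library_size = int(first.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    counts = dict(zip(df["gene_id"], df["count"].astype(int)))
    if library_size is None:
        library_size = int(np.sum(list(counts.values())))
    return MappedCounts(library_id or str(path), counts, library_size=library_size)
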