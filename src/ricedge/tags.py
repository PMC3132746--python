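"""Reference tag extraction by virtual NlaIII + MmeI digestion of cDNA.

NlaIII recognizes CATG; MmeI, anchored at the adaptor/CATG junction, cuts
17 bp downstream. Each eligible CATG site on the sense strand therefore
defines a 21-mer tag (CATG + 17 nt). The 3'-most eligible site yields the
*canonical* tag: the bead protocol retains only the 3' cDNA fragment, so
sequenced tags come from that site. All eligible sites still enter the
mapping index, because incomplete digestion and internal priming produce
non-canonical tags in real libraries.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List

from Bio import SeqIO

TAG_LENGTH = 21
SITE = "CATG"
DOWNSTREAM = TAG_LENGTH - len(SITE)  # 17 nt released by MmeI


@dataclass(frozen=True)
class Transcript:
    """A sense-strand cDNA sequence (5'->3')."""

    gene_id: str
    sequence: str


@dataclass(frozen=True)
class ReferenceTag:
    """A 21-mer CATG+17 tag owned by one gene.

    ``rank_from_3prime`` counts eligible sites from the 3' end; rank 0 is
    the canonical (sequenced) tag.
    """

    tag: str
    gene_id: str
    rank_from_3prime: int
    canonical: bool

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH or not self.tag.startswith(SITE):
            raise ValueError(f"not a CATG+17 tag: {self.tag!r}")


@dataclass
class TagIndex:
    """Exact-match lookup from 21-mer to owning gene set."""

    lookup: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    per_gene: Dict[str, List[ReferenceTag]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lookup)

    def genes_for(self, tag: str) -> FrozenSet[str]:
        return self.lookup.get(tag, frozenset())

    def canonical_tag(self, gene_id: str) -> str | None:
        for t in self.per_gene.get(gene_id, []):
            if t.canonical:
                return t.tag
        return None


def extract_reference_tags(transcript: Transcript) -> List[ReferenceTag]:
    """All CATG+17 tags of a transcript, 3'-most first (rank 0, canonical).

    Sites with fewer than 17 nt downstream are not cut by MmeI and are
    discarded, as are windows containing N. A transcript with no eligible
    site yields an empty list (the gene is untaggable, not an error).
    """
    seq = transcript.sequence.upper()
    sites: List[int] = []
    pos = seq.find(SITE)
    while pos != -1:
        if pos + TAG_LENGTH <= len(seq) and "N" not in seq[pos : pos + TAG_LENGTH]:
            sites.append(pos)
        pos = seq.find(SITE, pos + 1)
    tags = []
    for rank, site in enumerate(reversed(sites)):
        tags.append(
            ReferenceTag(
                tag=seq[site : site + TAG_LENGTH],
                gene_id=transcript.gene_id,
                rank_from_3prime=rank,
                canonical=(rank == 0),
            )
        )
    return tags


def build_index(tags: Iterable[ReferenceTag]) -> TagIndex:
    """Group extracted tags into an exact-lookup index.

    Genes sharing an identical 21-mer both appear in that entry; the
    ambiguity is resolved (filtered) at mapping time, not here.
    """
    lookup: Dict[str, set] = {}
    per_gene: Dict[str, List[ReferenceTag]] = {}
    for t in tags:
        lookup.setdefault(t.tag, set()).add(t.gene_id)
        per_gene.setdefault(t.gene_id, []).append(t)
    return TagIndex(
        lookup={k: frozenset(v) for k, v in lookup.items()}, per_gene=per_gene
    )


def index_transcripts(transcripts: Iterable[Transcript]) -> tuple[TagIndex, List[str]]:
    """Extract and index every transcript; also report untaggable gene ids."""
    all_tags: List[ReferenceTag] = []
    untaggable: List[str] = []
    for tr in transcripts:
        tags = extract_reference_tags(tr)
        if not tags:
            untaggable.append(tr.gene_id)
        all_tags.extend(tags)
    return build_index(all_tags), untaggable


def read_fasta(path) -> List[Transcript]:
    return [Transcript(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_index_tsv(index: TagIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tgene_id\trank_from_3prime\tcanonical\n")
        for gene_id in sorted(index.per_gene):
            for t in index.per_gene[gene_id]:
                fh.write(
                    f"{t.tag}\t{t.gene_id}\t{t.rank_from_3prime}\t{int(t.canonical)}\n"
                )


def _main_check(path: str) -> None:  # pragma: no cover - debugging aid
    idx, untag = index_transcripts(read_fasta(path))
    print(f"{len(idx)} distinct tags, {len(untag)} untaggable genes", file=sys.stderr)
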