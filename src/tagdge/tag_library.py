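"""Virtual reference tag library for NlaIII/MmeI tag profiling.

Digital gene expression sequencing counts 21 nt tags: the NlaIII
recognition site ``CATG`` plus the 17 nt released by MmeI cutting 17 bp
downstream.  To annotate observed tags, a *virtual* library is built from
the reference transcriptome: every occurrence of ``CATG`` on the sense
strand of a transcript that still has 17 nt downstream contributes one
reference tag.  Tags whose hit list names exactly one gene form the
*unambiguous* subset used for expression counting.

Coordinates are 0-based; ``site_offset`` points at the C of CATG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAG_LEN = 21
ANCHOR = "CATG"
ANCHOR_LEN = 4
DOWNSTREAM_LEN = TAG_LEN - ANCHOR_LEN  # 17 nt released by MmeI

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_tag_sites(sequence: str) -> list[int]:
    """0-based offsets of every CATG with >=17 nt downstream.

    Overlapping occurrences each yield a site.  The returned list is
    ascending, so the last element is the 3'-most site.
    """
    sites = []
    pos = sequence.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LEN <= len(sequence):
            sites.append(pos)
        pos = sequence.find(ANCHOR, pos + 1)
    return sites


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    organism: str  # "host" | "pathogen"
    sequence: str  # sense strand, alphabet ACGTN


@dataclass
class ReferenceTranscriptome:
    """One sense-strand sequence per gene, for one or both organisms."""

    records: list[GeneRecord]

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {}
        for rec in self.records:
            if not rec.sequence:
                raise ValueError(f"empty sequence for {rec.gene_id}")
            ids = seen.setdefault(rec.organism, set())
            if rec.gene_id in ids:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in {rec.organism}")
            ids.add(rec.gene_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, organism: str) -> "ReferenceTranscriptome":
        return ReferenceTranscriptome([r for r in self.records if r.organism == organism])

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description=f"organism={r.organism}")
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, organism: str | None = None) -> "ReferenceTranscriptome":
        """Read a transcript FASTA.

        Organism is taken from an ``organism=...`` token in the description,
        falling back to the ``organism`` argument (default ``"host"``).
        """
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            org = organism
            for token in rec.description.split():
                if token.startswith("organism="):
                    org = token.split("=", 1)[1]
            records.append(GeneRecord(rec.id, org or "host", str(rec.seq).upper()))
        return cls(records)


@dataclass
class VirtualTagLibrary:
    """Map 21 nt CATG-anchored tag -> list of (gene_id, site_offset) hits."""

    tags: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def __len__(self) -> int:
        return len(self.tags)

    def get(self, tag: str) -> list[tuple[str, int]]:
        return self.tags.get(tag, [])

    def genes_of(self, tag: str) -> set[str]:
        return {g for g, _ in self.tags.get(tag, ())}

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def unambiguous_tags(self) -> set[str]:
        return {t for t, hits in self.tags.items() if len({g for g, _ in hits}) == 1}

    @property
    def genes_with_site(self) -> int:
        return len({g for hits in self.tags.values() for g, _ in hits})

    def summary(self) -> dict[str, int]:
        return {
            "all_tags": self.n_tags,
            "unambiguous_tags": len(self.unambiguous_tags),
            "genes_with_site": self.genes_with_site,
        }

    def to_tsv(self, path: str | Path, summary_path: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tgene_id\tsite_offset\n")
            for tag in sorted(self.tags):
                for gene, off in self.tags[tag]:
                    fh.write(f"{tag}\t{gene}\t{off}\n")
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VirtualTagLibrary":
        tags: dict[str, list[tuple[str, int]]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise ValueError("not a tag-library TSV")
            for line in fh:
                tag, gene, off = line.rstrip("\n").split("\t")
                tags.setdefault(tag, []).append((gene, int(off)))
        return cls(tags)


def build_virtual_tag_library(transcriptome: ReferenceTranscriptome | Iterable[GeneRecord]) -> VirtualTagLibrary:
    """Build the CATG+17 nt reference tag database from sense-strand transcripts.

    Every CATG occurrence with a full 17 nt downstream yields a tag hit;
    overlapping sites each count.  Windows containing N are skipped (they can
    never match a clean tag, which excludes N).  The result is independent of
    record order up to hit-list ordering by (gene order, offset).
    """
    lib = VirtualTagLibrary()
    for rec in transcriptome:
        for off in find_tag_sites(rec.sequence):
            window = rec.sequence[off : off + TAG_LEN]
            if "N" in window:
                continue
            lib.tags.setdefault(window, []).append((rec.gene_id, off))
    return lib


def unambiguous_subset(lib: VirtualTagLibrary) -> VirtualTagLibrary:
    """Keep only tags hitting exactly one distinct gene (multiple sites in the
    same gene are allowed)."""
    keep = lib.unambiguous_tags
    return VirtualTagLibrary({t: list(lib.tags[t]) for t in lib.tags if t in keep})
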