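"""Clean-tag to gene assignment, strand-aware, with host/pathogen partition.

Matching rules: exact matches first (a tag equal to a reference tag is a
sense hit; a tag whose reverse complement equals a reference tag is an
antisense hit); only if neither strand matches exactly is a single mismatch
considered, and only within the 17 nt variable region — the CATG anchor is
of enzymatic origin and must be intact.  Exact hits suppress mismatch hits.

Per-tag category precedence:

1. host gene hits — one distinct gene => ``gene_unambiguous``, several =>
   ``gene_ambiguous`` (multi-gene tags are filtered from expression);
2. else an exact pathogen-gene hit => ``pathogen_gene`` (host precedence
   reflects that the RNA pool is overwhelmingly host-derived);
3. else an exact genome substring hit on either strand => ``genome_only``
   (diagnostic category, feeds no statistics);
4. else ``unknown``.

Per-gene expression sums copies of unambiguous *sense* tags; antisense
copies are tallied separately and excluded from TPM
(= count x 10^6 / total clean tags of the library).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .tag_library import ANCHOR, ANCHOR_LEN, TAG_LEN, VirtualTagLibrary, revcomp
from .tag_processing import CleanTagTable

CATEGORIES = ("gene_unambiguous", "gene_ambiguous", "genome_only", "pathogen_gene", "unknown")
_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _validate_tag(tag: str) -> None:
    if len(tag) != TAG_LEN or any(c not in "ACGT" for c in tag):
        raise ValueError(f"malformed tag {tag!r}: need 21 nt over ACGT")


def _one_mismatch_genes(tag: str, lib: VirtualTagLibrary) -> set[str]:
    """Genes hit by any 1-mismatch variant of ``tag`` (variable region only).

    ``tag`` must already be CATG-anchored on the queried strand.
    """
    genes: set[str] = set()
    for i in range(ANCHOR_LEN, TAG_LEN):
        for b in _ALT[tag[i]]:
            variant = tag[:i] + b + tag[i + 1 :]
            if variant in lib:
                genes |= lib.genes_of(variant)
    return genes


def match_tag(tag: str, lib: VirtualTagLibrary) -> list[tuple[str, str, int]]:
    """Hits of one clean tag against a virtual tag library.

    Returns (gene_id, strand, mismatches) triples, deduplicated by
    (gene, strand).  Exact hits (0 mismatches, both strands) suppress
    1-mismatch hits entirely.
    """
    _validate_tag(tag)
    hits: list[tuple[str, str, int]] = []
    if tag in lib:
        hits += [(g, "sense", 0) for g in sorted(lib.genes_of(tag))]
    rc = revcomp(tag)
    if rc in lib:
        hits += [(g, "antisense", 0) for g in sorted(lib.genes_of(rc))]
    if hits:
        return hits
    if tag.startswith(ANCHOR):
        hits += [(g, "sense", 1) for g in sorted(_one_mismatch_genes(tag, lib))]
    if rc.startswith(ANCHOR):
        hits += [(g, "antisense", 1) for g in sorted(_one_mismatch_genes(rc, lib))]
    return hits


class GenomeIndex:
    """Exact 21-mer index over genome sequence(s), both strands."""

    def __init__(self, sequences: str | dict[str, str] | Iterable[str]):
        if isinstance(sequences, str):
            sequences = [sequences]
        elif isinstance(sequences, dict):
            sequences = list(sequences.values())
        kmers: set[str] = set()
        for seq in sequences:
            seq = seq.upper()
            for strand_seq in (seq, revcomp(seq)):
                for i in range(len(strand_seq) - TAG_LEN + 1):
                    k = strand_seq[i : i + TAG_LEN]
                    if "N" not in k:
                        kmers.add(k)
        self._kmers = kmers

    def __contains__(self, tag: str) -> bool:
        return tag in self._kmers


def assign_tags(
    table: CleanTagTable,
    host_lib: VirtualTagLibrary,
    pathogen_lib: VirtualTagLibrary | None = None,
    genome: GenomeIndex | str | dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign every distinct clean tag to exactly one category.

    Returns a DataFrame (tag, category, strand, gene_id, mismatches, copies);
    strand is 'both' when sense and antisense exactly hit the same gene
    (counted as sense downstream), 'n/a' for ambiguous/genome/unknown tags.
    """
    if genome is not None and not isinstance(genome, GenomeIndex):
        genome = GenomeIndex(genome)
    rows = []
    for tag in sorted(table.counts):
        copies = table.counts[tag]
        hits = match_tag(tag, host_lib)
        category = None
        strand = "n/a"
        gene = None
        mism = 0
        if hits:
            genes = {g for g, _, _ in hits}
            if len(genes) == 1:
                category = "gene_unambiguous"
                gene = next(iter(genes))
                strands = {s for _, s, _ in hits}
                strand = "both" if len(strands) == 2 else next(iter(strands))
                mism = min(m for _, _, m in hits)
            else:
                category = "gene_ambiguous"
        elif pathogen_lib is not None:
            p_hits = []
            if tag in pathogen_lib:
                p_hits += [(g, "sense") for g in sorted(pathogen_lib.genes_of(tag))]
            rc = revcomp(tag)
            if rc in pathogen_lib:
                p_hits += [(g, "antisense") for g in sorted(pathogen_lib.genes_of(rc))]
            if p_hits:
                p_genes = {g for g, _ in p_hits}
                if len(p_genes) == 1:
                    category = "pathogen_gene"
                    gene = next(iter(p_genes))
                    strands = {s for _, s in p_hits}
                    strand = "both" if len(strands) == 2 else next(iter(strands))
                else:
                    # a gene_id is required for pathogen_gene; multi-gene
                    # pathogen hits are filtered like host multi-gene tags
                    category = "gene_ambiguous"
        if category is None and genome is not None and tag in genome:
            category = "genome_only"
        if category is None:
            category = "unknown"
        rows.append((tag, category, strand, gene, mism, copies))
    return pd.DataFrame(
        rows, columns=["tag", "category", "strand", "gene_id", "mismatches", "copies"]
    )


def assignment_summary(assignments: pd.DataFrame, table: CleanTagTable) -> dict:
    """Library-level mapping summary: per category, distinct tags, copies and
    their shares of clean tags."""
    total = table.total_clean
    distinct = table.distinct_clean
    out: dict = {"library_id": table.library_id, "total_clean": total, "distinct_clean": distinct}
    for cat in CATEGORIES:
        sub = assignments[assignments.category == cat]
        copies = int(sub.copies.sum())
        out[cat] = {
            "distinct": int(len(sub)),
            "copies": copies,
            "copies_pct_of_clean": 100.0 * copies / total if total else 0.0,
            "distinct_pct_of_clean": 100.0 * len(sub) / distinct if distinct else 0.0,
        }
    return out


@dataclass
class ExpressionProfile:
    """Per-gene unambiguous tag counts and TPM for one library."""

    library_id: str
    total_clean: int
    table: pd.DataFrame  # gene_id, organism-agnostic; sense_count, antisense_count, tpm

    def genes(self) -> set[str]:
        return set(self.table.gene_id)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str, total_clean: int) -> "ExpressionProfile":
        return cls(library_id, total_clean, pd.read_csv(path, sep="\t"))


def gene_counts(
    assignments: pd.DataFrame,
    table: CleanTagTable,
    categories: tuple[str, ...] = ("gene_unambiguous", "pathogen_gene"),
) -> ExpressionProfile:
    """Sum unambiguous tag copies per gene and normalize to TPM.

    Sense counts include tags with strand 'both'; antisense copies are kept
    separately and excluded from TPM.  Rejects an empty library (TPM
    undefined at total_clean = 0).
    """
    total = table.total_clean
    if total == 0:
        raise ValueError("total_clean is 0: TPM undefined")
    sub = assignments[assignments.category.isin(categories)]
    if len(sub) == 0:
        df = pd.DataFrame(columns=["gene_id", "sense_count", "antisense_count", "tpm"])
        return ExpressionProfile(table.library_id, total, df)
    sense = np.where(sub.strand.isin(["sense", "both"]), sub.copies, 0)
    anti = np.where(sub.strand == "antisense", sub.copies, 0)
    df = (
        sub.assign(sense_count=sense, antisense_count=anti)
        .groupby("gene_id", as_index=False)[["sense_count", "antisense_count"]]
        .sum()
        .sort_values("gene_id", ignore_index=True)
    )
    df["tpm"] = df.sense_count * 1e6 / total
    return ExpressionProfile(table.library_id, total, df)


@dataclass
class StrandSummary:
    genes_with_sense: int
    genes_with_antisense: int
    genes_bidirectional: int
    sense_copies: int
    antisense_copies: int
    sense_to_antisense_transcript_ratio: float  # inf when no antisense copies


def strand_summary(assignments: pd.DataFrame | Iterable[pd.DataFrame]) -> StrandSummary:
    """Sense/antisense transcription summary over one or several libraries.

    A gene counts "with sense" if it has at least one unambiguous sense (or
    'both') tag, analogously for antisense; the transcript ratio compares
    total copies.
    """
    if isinstance(assignments, pd.DataFrame):
        assignments = [assignments]
    frames = [a[a.category == "gene_unambiguous"] for a in assignments]
    sub = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(sub) == 0:
        return StrandSummary(0, 0, 0, 0, 0, math.inf)
    sense_mask = sub.strand.isin(["sense", "both"])
    anti_mask = sub.strand.isin(["antisense", "both"])
    sense_genes = set(sub.gene_id[sense_mask])
    anti_genes = set(sub.gene_id[anti_mask])
    sense_copies = int(sub.copies[sense_mask].sum())
    anti_copies = int(sub.copies[anti_mask].sum())
    ratio = sense_copies / anti_copies if anti_copies else math.inf
    return StrandSummary(
        len(sense_genes),
        len(anti_genes),
        len(sense_genes & anti_genes),
        sense_copies,
        anti_copies,
        ratio,
    )
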