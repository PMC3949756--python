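"""Raw-read cleaning: from 49 nt reads to clean-tag count tables.

The filter cascade, applied in this fixed order per library:

1. locate the 3' adaptor by exact substring search and trim from its start
   (a read that is adaptor from position 0 is an "empty" / adaptor-only read);
2. drop tags containing N;
3. drop tags whose trimmed length differs from 21 nt;
4. tally the remaining tags, then drop tags with copy number 1 (singletons).

Surviving counts are all >=2; "distinct" counts unique tag sequences and
"total" counts copies.  ``tag_statistics`` bins the surviving distinct/total
tags by copy-number class ([2,5], (5,50], (50,100], (100,inf)) — the class
boundaries in the source protocol overlap ("2 to 5", "5 and 50"), so the
half-open convention used here is documented rather than canonical.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tag_library import TAG_LEN

FILTER_REASONS = ("adaptor_only", "contains_N", "bad_length", "singleton")

COPY_BINS = (
    ("[2,5]", 2, 5),
    ("(5,50]", 6, 50),
    ("(50,100]", 51, 100),
    ("(100,inf)", 101, None),
)


@dataclass
class RawReadSet:
    """A library of raw reads.

    ``sequences`` may be a list of str or a numpy bytes array (the simulator
    produces the latter for speed); qualities are optional and unused by the
    filters, which act on sequence only.
    """

    library_id: str
    sequences: Sequence[str] | np.ndarray
    qualities: Sequence[str] | None = None
    quality_char: str = "I"  # Phred+33 Q40, used when qualities is None

    def __len__(self) -> int:
        return len(self.sequences)

    def iter_reads(self):
        for i, seq in enumerate(self.sequences):
            s = seq.decode() if isinstance(seq, bytes) else str(seq)
            q = self.qualities[i] if self.qualities is not None else self.quality_char * len(s)
            yield s, q

    def write_fastq(self, path: str | Path) -> None:
        """4-line FASTQ records, Phred+33; byte-deterministic for a given read set."""
        lib = self.library_id
        with open(path, "w") as fh:
            buf: list[str] = []
            for i, (s, q) in enumerate(self.iter_reads()):
                buf.append(f"@{lib}_{i}\n{s}\n+\n{q}\n")
                if len(buf) >= 10000:
                    fh.write("".join(buf))
                    buf.clear()
            fh.write("".join(buf))

    @classmethod
    def from_fastq(cls, path: str | Path, library_id: str | None = None) -> "RawReadSet":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        seqs: list[str] = []
        quals: list[str] = []
        with open(path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                seqs.append(seq.upper())
                quals.append(qual)
        if library_id is None:
            library_id = Path(path).stem
        return cls(library_id, seqs, qualities=quals)


@dataclass
class CleanTagTable:
    """Distinct 21 nt tag -> copy number (>=2) for one library."""

    library_id: str
    counts: dict[str, int]
    dropped: dict[str, int] = field(default_factory=lambda: {r: 0 for r in FILTER_REASONS})

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)

    def summary(self) -> dict:
        return {
            "library_id": self.library_id,
            "raw_reads": self.total_clean + sum(self.dropped.values()),
            "total_clean": self.total_clean,
            "distinct_clean": self.distinct_clean,
            "dropped": dict(self.dropped),
        }

    def to_tsv(self, path: str | Path, summary_path: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcount\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str | None = None) -> "CleanTagTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise ValueError("not a clean-tag TSV")
            for line in fh:
                tag, n = line.rstrip("\n").split("\t")
                counts[tag] = int(n)
        if library_id is None:
            library_id = Path(path).stem
        return cls(library_id, counts)


def clean_reads(raw: RawReadSet, adaptor3: str) -> CleanTagTable:
    """Apply the clean-tag filter cascade to a raw read set.

    Read conservation holds exactly: total_clean + sum(dropped) equals the
    raw read count.  Distinct raw sequences are processed once and weighted
    by their multiplicity, so runtime scales with library complexity rather
    than depth.
    """
    if not adaptor3:
        raise ValueError("adaptor3 must be non-empty")
    seqs = raw.sequences
    if len(seqs) == 0:
        return CleanTagTable(raw.library_id, {})
    arr = np.asarray(seqs, dtype=bytes)
    uniq, copies = np.unique(arr, return_counts=True)

    adaptor = adaptor3.upper()
    dropped = {r: 0 for r in FILTER_REASONS}
    tally: Counter[str] = Counter()
    for useq, n in zip(uniq.tolist(), copies.tolist()):
        s = useq.decode()
        cut = s.find(adaptor)
        tag = s[:cut] if cut >= 0 else s
        if cut == 0:
            dropped["adaptor_only"] += n
        elif "N" in tag:
            dropped["contains_N"] += n
        elif len(tag) != TAG_LEN:
            dropped["bad_length"] += n
        else:
            tally[tag] += n

    singles = [t for t, n in tally.items() if n == 1]
    for t in singles:
        del tally[t]
    dropped["singleton"] = len(singles)

    table = CleanTagTable(raw.library_id, dict(tally), dropped)
    assert table.total_clean + sum(dropped.values()) == len(seqs)
    return table


@dataclass
class TagDistribution:
    """Copy-number class shares over distinct and total clean tags."""

    library_id: str
    distinct_share: dict[str, float]
    total_share: dict[str, float]
    distinct_counts: dict[str, int]
    total_counts: dict[str, int]


def tag_statistics(table: CleanTagTable) -> TagDistribution:
    """Bin clean tags by copy-number class (the abundance profile of a
    library; heavy-tailed expression shows up as a large [2,5] distinct share
    and a large (100,inf) total share)."""
    d_counts = {label: 0 for label, *_ in COPY_BINS}
    t_counts = {label: 0 for label, *_ in COPY_BINS}
    for n in table.counts.values():
        for label, lo, hi in COPY_BINS:
            if n >= lo and (hi is None or n <= hi):
                d_counts[label] += 1
                t_counts[label] += n
                break
    nd = sum(d_counts.values())
    nt = sum(t_counts.values())
    d_share = {k: (v / nd if nd else 0.0) for k, v in d_counts.items()}
    t_share = {k: (v / nt if nt else 0.0) for k, v in t_counts.items()}
    return TagDistribution(table.library_id, d_share, t_share, d_counts, t_counts)
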