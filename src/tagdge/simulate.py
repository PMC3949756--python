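"""Synthetic dual-organism tag-sequencing data generator.

Emulates a host-pathogen infection time course profiled by NlaIII/MmeI tag
sequencing: six libraries (infected/control at 8, 15 and 24 h
post-inoculation), each a pool of 49 nt reads laid out as a 21 nt CATG+17 nt
tag followed by a fixed 3' adaptor.  The generator draws per-gene read
counts multinomially from a heavy-tailed (log-normal) abundance program, so
a small number of transcripts carry most of the mass while the majority are
rare; infected libraries additionally apply per-gene fold changes and admix
a small fraction of pathogen-derived tags.  Sequencing artifacts —
substitution/N errors, adaptor-only reads and random singleton noise tags —
are injected at configured rates.

A fixed seed gives bit-identical output (per numpy version); every library
is reproducible independently of the others.  Ground truth (per-gene
abundances, fold changes, antisense flags; per-library emitted tag tallies)
is returned alongside the reads so downstream stages can be tested by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tag_library import (
    TAG_LEN,
    GeneRecord,
    ReferenceTranscriptome,
    find_tag_sites,
    revcomp,
)
from .tag_processing import RawReadSet

READ_LEN = 49
#: fixed 3' adaptor filling the read after the 21 nt tag (21 + 28 = 49 nt)
DEFAULT_ADAPTOR3 = "TCGTATGCCGTCTTCTGCTTGAAACAAG"

TIMEPOINTS = (8, 15, 24)  # hours post-inoculation
FC_COLUMNS = {8: "fc_8h", 15: "fc_15h", 24: "fc_24h"}
#: ZT = infected (tested), ZC = control, numbered by timepoint
LIBRARY_IDS = {
    (8, "control"): "ZC1",
    (8, "infected"): "ZT1",
    (15, "control"): "ZC2",
    (15, "infected"): "ZT2",
    (24, "control"): "ZC3",
    (24, "infected"): "ZT3",
}

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
# for each original base code (A,C,G,T,N), the 4 possible error outcomes
_ERR_ALTS = np.array(
    [[c for c in _BASES if c != orig] for orig in _BASES], dtype=np.uint8
)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(_BASES):
    _BASE_INDEX[_c] = _i


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated experiment.

    Defaults emulate the library composition of a tag-sequencing infection
    time course: ~2 M tags per library (the depth at which gene detection
    saturates), log-normal abundances with sigma 2.0 (top 5% of genes carry
    more than half the mass), 5% of host genes differentially expressed per
    timepoint with a 2:1 up:down skew, ~55% of genes with antisense
    transcription contributing ~1.6:1 sense:antisense tag copies overall,
    and pathogen admixture between 0.05% and 0.68% of gene-derived tags.
    """

    n_host_genes: int = 1000
    n_pathogen_genes: int = 200
    transcript_length_range: tuple[int, int] = (200, 1500)
    gc_content: float = 0.5
    depth_per_library: int = 2_000_000
    frac_de_per_timepoint: float = 0.05
    fold_change_range: tuple[float, float] = (2.0, 8.0)
    de_up_fraction: float = 2 / 3  # 2:1 up:down
    antisense_gene_fraction: float = 0.55
    antisense_read_fraction: float = 0.7
    pathogen_tag_fraction_per_timepoint: tuple[float, float, float] = (0.0005, 0.0068, 0.0030)
    internal_site_usage: float = 0.1
    per_base_error_rate: float = 0.001
    singleton_noise_fraction: float = 0.01
    adaptor_only_fraction: float = 0.01
    abundance_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = {
            "gc_content": self.gc_content,
            "frac_de_per_timepoint": self.frac_de_per_timepoint,
            "de_up_fraction": self.de_up_fraction,
            "antisense_gene_fraction": self.antisense_gene_fraction,
            "antisense_read_fraction": self.antisense_read_fraction,
            "internal_site_usage": self.internal_site_usage,
            "per_base_error_rate": self.per_base_error_rate,
            "singleton_noise_fraction": self.singleton_noise_fraction,
            "adaptor_only_fraction": self.adaptor_only_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for f in self.pathogen_tag_fraction_per_timepoint:
            if not 0.0 <= f <= 1.0:
                raise ValueError("pathogen tag fractions must be in [0,1]")
        if len(self.pathogen_tag_fraction_per_timepoint) != len(TIMEPOINTS):
            raise ValueError("need one pathogen tag fraction per timepoint")
        lo, hi = self.transcript_length_range
        if lo < TAG_LEN + 4:
            raise ValueError(
                f"transcript_length_range lower bound {lo} cannot host a CATG+17 nt site"
            )
        if hi < lo:
            raise ValueError("transcript_length_range must be ascending")
        if self.fold_change_range[0] <= 1.0:
            raise ValueError("fold_change_range lower bound must be > 1")
        if self.fold_change_range[1] < self.fold_change_range[0]:
            raise ValueError("fold_change_range must be ascending")
        if self.n_host_genes < 1 or self.n_pathogen_genes < 0:
            raise ValueError("gene counts out of range")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        if self.adaptor_only_fraction + self.singleton_noise_fraction >= 1.0:
            raise ValueError("artifact fractions leave no room for gene-derived reads")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("transcript_length_range", "fold_change_range", "pathogen_tag_fraction_per_timepoint"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Per-gene ground truth: organism, abundance, fold changes, antisense flag.

    ``table`` columns: gene_id, organism, abundance, fc_8h, fc_15h, fc_24h,
    antisense.  Abundances sum to 1 within each organism; a fold change of 1
    means non-DE.
    """

    table: pd.DataFrame

    def host(self) -> pd.DataFrame:
        return self.table[self.table.organism == "host"].reset_index(drop=True)

    def pathogen(self) -> pd.DataFrame:
        return self.table[self.table.organism == "pathogen"].reset_index(drop=True)

    def de_genes(self, timepoint: int) -> dict[str, str]:
        """DE host genes at a timepoint -> direction ('up' / 'down')."""
        col = FC_COLUMNS[int(timepoint)]
        h = self.host()
        out = {}
        for gid, fc in zip(h.gene_id, h[col]):
            if fc > 1:
                out[gid] = "up"
            elif fc < 1:
                out[gid] = "down"
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimulationTruth":
        return cls(pd.read_csv(path, sep="\t"))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[:4][codes].tobytes().decode()


def simulate_transcriptome(config: SyntheticConfig) -> ReferenceTranscriptome:
    """Random host and pathogen transcript sets on the sense strand.

    Every gene is guaranteed at least one CATG site with a full 17 nt
    downstream: if random composition yields none, a CATG is written 21 nt
    from the 3' end.  Gene ids are namespaced by organism (bm_/bb_).
    """
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.transcript_length_range
    records: list[GeneRecord] = []
    for organism, prefix, n in (
        ("host", "bm_g", config.n_host_genes),
        ("pathogen", "bb_g", config.n_pathogen_genes),
    ):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length, config.gc_content)
            if not find_tag_sites(seq):
                pos = length - TAG_LEN
                seq = seq[:pos] + "CATG" + seq[pos + 4 :]
            records.append(GeneRecord(f"{prefix}{i + 1:04d}", organism, seq))
    return ReferenceTranscriptome(records)


def simulate_truth(config: SyntheticConfig, transcriptome: ReferenceTranscriptome) -> SimulationTruth:
    """Draw the expression program: log-normal abundances, per-timepoint DE
    assignments (exactly round(frac_de * n_host) genes, 2:1 up:down), and
    antisense flags for exactly round(antisense_gene_fraction * n_host) genes."""
    rng = np.random.default_rng([config.seed, 202])
    rows = []
    for organism in ("host", "pathogen"):
        genes = [r.gene_id for r in transcriptome if r.organism == organism]
        if not genes:
            continue
        w = rng.lognormal(0.0, config.abundance_sigma, size=len(genes))
        w /= w.sum()
        rows.append(pd.DataFrame({"gene_id": genes, "organism": organism, "abundance": w}))
    table = pd.concat(rows, ignore_index=True)
    for col in FC_COLUMNS.values():
        table[col] = 1.0
    table["antisense"] = False

    host_idx = np.flatnonzero(table.organism.to_numpy() == "host")
    n_host = len(host_idx)

    n_as = round(config.antisense_gene_fraction * n_host)
    as_pick = rng.choice(host_idx, size=n_as, replace=False)
    table.loc[as_pick, "antisense"] = True

    n_de = round(config.frac_de_per_timepoint * n_host)
    if config.frac_de_per_timepoint > 0 and n_de == 0:
        warnings.warn("frac_de_per_timepoint * n_host_genes < 0.5: no DE genes generated")
    lo, hi = config.fold_change_range
    for tp in TIMEPOINTS:
        col = FC_COLUMNS[tp]
        if n_de == 0:
            continue
        pick = rng.choice(host_idx, size=n_de, replace=False)
        n_up = round(config.de_up_fraction * n_de)
        mags = rng.uniform(lo, hi, size=n_de)
        fc = mags.copy()
        fc[n_up:] = 1.0 / mags[n_up:]
        table.loc[pick, col] = fc
    return SimulationTruth(table)


@dataclass
class LibraryEmission:
    """What the simulator actually emitted for one library (pre-error truth).

    ``per_tag``: tag, gene_id, organism, strand, site_offset, copies.
    ``per_gene``: gene_id, organism, sense_reads, antisense_reads.
    """

    library_id: str
    timepoint: int
    condition: str
    per_tag: pd.DataFrame
    n_adaptor_only: int
    n_noise: int
    n_host_reads: int
    n_pathogen_reads: int

    @property
    def per_gene(self) -> pd.DataFrame:
        if len(self.per_tag) == 0:
            return pd.DataFrame(columns=["gene_id", "organism", "sense_reads", "antisense_reads"])
        t = self.per_tag
        out = (
            t.assign(
                sense_reads=np.where(t.strand == "sense", t.copies, 0),
                antisense_reads=np.where(t.strand == "antisense", t.copies, 0),
            )
            .groupby(["gene_id", "organism"], as_index=False)[["sense_reads", "antisense_reads"]]
            .sum()
        )
        return out


def _site_counts(rng: np.random.Generator, c: int, n_sites: int, internal_usage: float) -> np.ndarray:
    """Distribute c reads over tag sites: the 3'-most site (last) gets each
    read with probability 1 - internal_usage, the rest spread uniformly over
    internal sites."""
    counts = np.zeros(n_sites, dtype=np.int64)
    if c == 0:
        return counts
    if n_sites == 1 or internal_usage == 0.0:
        counts[-1] = c
        return counts
    n_int = int(rng.binomial(c, internal_usage))
    counts[-1] = c - n_int
    if n_int:
        counts[:-1] += rng.multinomial(n_int, np.full(n_sites - 1, 1.0 / (n_sites - 1)))
    return counts


def simulate_library(
    transcriptome: ReferenceTranscriptome,
    truth: SimulationTruth,
    config: SyntheticConfig,
    timepoint: int,
    condition: str,
    replicate: int = 0,
    library_id: str | None = None,
) -> tuple[RawReadSet, LibraryEmission]:
    """Sample one raw tag library of exactly ``depth_per_library`` reads.

    Reads are drawn gene-proportionally (fold changes applied and
    renormalized in infected libraries); each gene read takes the 3'-most
    CATG+17 tag unless routed to an internal site; antisense-flagged genes
    emit the reverse complement of a sense tag for ``antisense_read_fraction``
    of their reads; pathogen reads are admixed only in infected libraries.
    Adaptor-only reads, uniform-random 21-mer noise tags and per-base errors
    (substitution to one of the three other bases or N) are injected at the
    configured rates.  ``replicate`` selects an independent sampling stream
    for parallel libraries from the same truth.
    """
    timepoint = int(timepoint)
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
    if condition not in ("infected", "control"):
        raise ValueError("condition must be 'infected' or 'control'")
    t_idx = TIMEPOINTS.index(timepoint)
    infected = condition == "infected"
    if library_id is None:
        lib_id = LIBRARY_IDS[(timepoint, condition)]
        if replicate:
            lib_id = f"{lib_id}r{replicate}"
        library_id = lib_id
    rng = np.random.default_rng([config.seed, 303, t_idx, int(infected), replicate])

    depth = config.depth_per_library
    p_a = config.adaptor_only_fraction
    p_n = config.singleton_noise_fraction
    rest = 1.0 - p_a - p_n
    f_path = config.pathogen_tag_fraction_per_timepoint[t_idx] if infected else 0.0
    n_adapt, n_noise, n_path, n_host = rng.multinomial(
        depth, [p_a, p_n, rest * f_path, rest * (1.0 - f_path)]
    )

    # per-gene read counts
    host_tab = truth.host()
    w = host_tab.abundance.to_numpy().copy()
    if infected:
        w = w * host_tab[FC_COLUMNS[timepoint]].to_numpy()
        w = w / w.sum()
    host_counts = rng.multinomial(n_host, w) if n_host else np.zeros(len(w), dtype=np.int64)

    path_tab = truth.pathogen()
    if n_path and len(path_tab):
        path_counts = rng.multinomial(n_path, path_tab.abundance.to_numpy())
    else:
        path_counts = np.zeros(len(path_tab), dtype=np.int64)

    seq_by_gene = {r.gene_id: r.sequence for r in transcriptome}
    antisense_flag = dict(zip(host_tab.gene_id, host_tab.antisense))

    templates: list[str] = []
    template_counts: list[int] = []
    tag_rows: list[tuple[str, str, str, str, int, int]] = []

    def emit_gene(gene_id: str, organism: str, c: int, as_frac: float) -> None:
        if c == 0:
            return
        seq = seq_by_gene[gene_id]
        sites = find_tag_sites(seq)
        c_anti = int(rng.binomial(c, as_frac)) if as_frac > 0 else 0
        for strand, n_reads in (("sense", c - c_anti), ("antisense", c_anti)):
            if n_reads == 0:
                continue
            per_site = _site_counts(rng, n_reads, len(sites), config.internal_site_usage)
            for off, k in zip(sites, per_site.tolist()):
                if k == 0:
                    continue
                tag = seq[off : off + TAG_LEN]
                if strand == "antisense":
                    tag = revcomp(tag)
                templates.append(tag)
                template_counts.append(k)
                tag_rows.append((tag, gene_id, organism, strand, off, k))

    as_read_frac = config.antisense_read_fraction
    for gene_id, c in zip(host_tab.gene_id, host_counts.tolist()):
        emit_gene(gene_id, "host", c, as_read_frac if antisense_flag[gene_id] else 0.0)
    for gene_id, c in zip(path_tab.gene_id, path_counts.tolist()):
        emit_gene(gene_id, "pathogen", c, 0.0)

    fill = (DEFAULT_ADAPTOR3 * 3)[: READ_LEN - TAG_LEN]
    adaptor_only_read = (DEFAULT_ADAPTOR3 * 3)[:READ_LEN]
    if n_adapt:
        templates.append(adaptor_only_read)
        template_counts.append(int(n_adapt))

    n_total = int(depth)
    matrix = np.empty((n_total, READ_LEN), dtype=np.uint8)

    if templates:
        tmpl = np.frombuffer(
            "".join(t if len(t) == READ_LEN else t + fill for t in templates).encode(),
            dtype=np.uint8,
        ).reshape(len(templates), READ_LEN)
        idx = np.repeat(np.arange(len(templates)), template_counts)
        matrix[: len(idx)] = tmpl[idx]
        n_templated = len(idx)
    else:
        n_templated = 0

    if n_noise:
        noise_tags = _BASES[:4][rng.integers(0, 4, size=(int(n_noise), TAG_LEN))]
        fill_row = np.frombuffer(fill.encode(), dtype=np.uint8)
        matrix[n_templated:, :TAG_LEN] = noise_tags
        matrix[n_templated:, TAG_LEN:] = fill_row
    assert n_templated + int(n_noise) == n_total

    if n_total:
        matrix = matrix[rng.permutation(n_total)]

    e = config.per_base_error_rate
    if e > 0 and n_total:
        n_bases = n_total * READ_LEN
        n_err = int(rng.binomial(n_bases, e))
        if n_err:
            # positions sampled with replacement; collisions are negligible at
            # realistic rates and keep the draw O(n_err)
            pos = rng.integers(0, n_bases, size=n_err)
            alt = rng.integers(0, 4, size=n_err)
            flat = matrix.reshape(-1)
            flat[pos] = _ERR_ALTS[_BASE_INDEX[flat[pos]], alt]

    sequences = matrix.reshape(n_total, READ_LEN).view(f"S{READ_LEN}").ravel()
    reads = RawReadSet(library_id, sequences)

    per_tag = pd.DataFrame(
        tag_rows, columns=["tag", "gene_id", "organism", "strand", "site_offset", "copies"]
    )
    if len(per_tag):
        per_tag = (
            per_tag.groupby(["tag", "gene_id", "organism", "strand", "site_offset"], as_index=False)[
                "copies"
            ]
            .sum()
            .sort_values(["gene_id", "site_offset", "strand"], kind="stable")
            .reset_index(drop=True)
        )
    emission = LibraryEmission(
        library_id,
        timepoint,
        condition,
        per_tag,
        int(n_adapt),
        int(n_noise),
        int(n_host),
        int(n_path),
    )
    return reads, emission


@dataclass
class SimulatedExperiment:
    config: SyntheticConfig
    transcriptome: ReferenceTranscriptome
    truth: SimulationTruth
    libraries: dict[str, RawReadSet]
    emissions: dict[str, LibraryEmission]


def simulate_experiment(config: SyntheticConfig, outdir: str | Path | None = None) -> SimulatedExperiment:
    """Generate the full six-library experiment (and optionally write
    reference FASTA, per-library FASTQ, truth and emission TSVs, and the
    config YAML to ``outdir``)."""
    transcriptome = simulate_transcriptome(config)
    truth = simulate_truth(config, transcriptome)
    libraries: dict[str, RawReadSet] = {}
    emissions: dict[str, LibraryEmission] = {}
    for tp in TIMEPOINTS:
        for condition in ("control", "infected"):
            reads, emission = simulate_library(transcriptome, truth, config, tp, condition)
            libraries[reads.library_id] = reads
            emissions[reads.library_id] = emission
    exp = SimulatedExperiment(config, transcriptome, truth, libraries, emissions)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        transcriptome.to_fasta(outdir / "reference.fasta")
        truth.write_tsv(outdir / "truth.tsv")
        for lib_id, reads in libraries.items():
            reads.write_fastq(outdir / f"{lib_id}.fastq")
            emissions[lib_id].per_tag.to_csv(outdir / f"{lib_id}.emission.tsv", sep="\t", index=False)
    return exp


def simulate_qpcr(
    truth: SimulationTruth,
    genes: list[str],
    timepoint: int,
    seed: int,
    ct_noise_sd: float = 0.3,
    replicates: int = 3,
) -> pd.DataFrame:
    """Synthetic Ct table for selected genes at one timepoint.

    Target Ct tracks -log2(expression); the infected sample shifts by
    -log2(fold change); the reference (housekeeping) gene is flat.  Gaussian
    cycle noise of ``ct_noise_sd`` is added per replicate.  Columns:
    gene_id, timepoint, condition, replicate, ct_target, ct_reference.
    """
    rng = np.random.default_rng([seed, 404, int(timepoint)])
    tab = truth.table.set_index("gene_id")
    col = FC_COLUMNS[int(timepoint)]
    rows = []
    for gene in genes:
        abundance = float(tab.loc[gene, "abundance"])
        fc = float(tab.loc[gene, col])
        ct_ref = 16.0
        ct_ctrl = 24.0 - np.log2(max(abundance, 1e-9) * 1000.0)
        for condition, ct_t in (("control", ct_ctrl), ("infected", ct_ctrl - np.log2(fc))):
            for rep in range(replicates):
                rows.append(
                    {
                        "gene_id": gene,
                        "timepoint": int(timepoint),
                        "condition": condition,
                        "replicate": rep + 1,
                        "ct_target": ct_t + rng.normal(0.0, ct_noise_sd),
                        "ct_reference": ct_ref + rng.normal(0.0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_annotations(
    gene_ids: list[str],
    seed: int,
    n_pathways: int = 20,
    mean_terms_per_gene: float = 1.0,
    go_terms_per_namespace: int = 15,
    go_annotation_rate: float = 0.6,
    planted_term: str | None = None,
    planted_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Random gene->term annotation table (pathway + three GO namespaces).

    If ``planted_term``/``planted_genes`` are given, those genes are all
    annotated to the planted pathway (for enrichment-recovery studies).
    Columns: gene_id, term_id, namespace.
    """
    rng = np.random.default_rng([seed, 505])
    rows = []
    pathways = [f"ko{i:05d}" for i in range(1, n_pathways + 1)]
    for gene in gene_ids:
        k = rng.poisson(mean_terms_per_gene)
        for term in rng.choice(pathways, size=min(k, n_pathways), replace=False):
            rows.append({"gene_id": gene, "term_id": str(term), "namespace": "pathway"})
        for ns in ("component", "function", "process"):
            if rng.random() < go_annotation_rate:
                term_i = int(rng.integers(1, go_terms_per_namespace + 1))
                rows.append(
                    {"gene_id": gene, "term_id": f"GO:{ns[:4]}{term_i:04d}", "namespace": ns}
                )
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace"])
    if planted_term and planted_genes:
        extra = pd.DataFrame(
            {"gene_id": planted_genes, "term_id": planted_term, "namespace": "pathway"}
        )
        df = pd.concat([df, extra], ignore_index=True).drop_duplicates(ignore_index=True)
    return df
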