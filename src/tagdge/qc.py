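"""Quality control: sequencing saturation, repeatability, qPCR concordance.

Saturation subsamples the clean-tag stream without replacement (multivariate
hypergeometric) at a grid of depths and counts genes detected via at least
one unambiguous tag; when the curve plateaus, the achieved depth suffices
for transcript coverage.  Repeatability is the Pearson correlation of
log-scale TPM between two parallel libraries.  qPCR relative expression uses
the 2^-ddCt method (target Ct normalized to a reference gene and a
calibrator sample, replicates aggregated by mean Ct), and concordance
compares the sign of the sequencing log2 ratio with the sign of
log2(2^-ddCt) per gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .tag_library import VirtualTagLibrary
from .tag_mapping import ExpressionProfile, match_tag
from .tag_processing import CleanTagTable

logger = logging.getLogger(__name__)


@dataclass
class SaturationCurve:
    library_id: str
    table: pd.DataFrame  # depth, mean_detected (+ detected_rep{i})
    full_detection: int
    replicates: int
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _unambiguous_gene_map(table: CleanTagTable, lib: VirtualTagLibrary) -> dict[str, str]:
    """Distinct clean tag -> gene for tags mapping unambiguously (either strand)."""
    out = {}
    for tag in table.counts:
        hits = match_tag(tag, lib)
        genes = {g for g, _, _ in hits}
        if len(genes) == 1:
            out[tag] = next(iter(genes))
    return out


def saturation_curve(
    table: CleanTagTable,
    lib: VirtualTagLibrary,
    grid,
    replicates: int = 3,
    seed: int = 0,
) -> SaturationCurve:
    """Detected-gene counts at subsampled sequencing depths.

    ``grid`` must be ascending; points beyond the library total are
    truncated to it (logged).  Each point is averaged over ``replicates``
    seeded draws without replacement.
    """
    grid = [int(g) for g in grid]
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be ascending")
    total = table.total_clean
    trunc = [min(g, total) for g in grid]
    if trunc != grid:
        logger.warning("grid points beyond library size truncated to %d", total)

    tag_gene = _unambiguous_gene_map(table, lib)
    tags = sorted(table.counts)
    counts = np.array([table.counts[t] for t in tags], dtype=np.int64)
    genes = [tag_gene.get(t) for t in tags]
    gene_ids = sorted({g for g in genes if g is not None})
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    tag_gene_idx = np.array([gene_index.get(g, -1) if g else -1 for g in genes], dtype=np.int64)
    full_detection = len(gene_ids)

    rng = np.random.default_rng(seed)
    rows = []
    for depth in trunc:
        reps = []
        for _ in range(replicates):
            if depth == 0:
                reps.append(0)
                continue
            if depth == total:
                sub = counts
            else:
                sub = rng.multivariate_hypergeometric(counts, depth, method="marginals")
            present = tag_gene_idx[(sub > 0) & (tag_gene_idx >= 0)]
            reps.append(len(np.unique(present)))
        rows.append([depth, float(np.mean(reps))] + reps)
    cols = ["depth", "mean_detected"] + [f"detected_rep{i + 1}" for i in range(replicates)]
    return SaturationCurve(table.library_id, pd.DataFrame(rows, columns=cols), full_detection, replicates, seed)


def repeatability(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    pseudo: float | None = None,
) -> float:
    """Pearson correlation of log2 TPM over genes detected in either profile
    (undetected side filled with zero counts; same pseudocount rule as the
    DE log2 ratio)."""
    a = profile_a.table[["gene_id", "tpm"]].rename(columns={"tpm": "tpm_a"})
    b = profile_b.table[["gene_id", "tpm"]].rename(columns={"tpm": "tpm_b"})
    df = a.merge(b, on="gene_id", how="outer").fillna(0.0)
    if len(df) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    if pseudo is None:
        pseudo = 1e6 / max(profile_a.total_clean, profile_b.total_clean)
    la = np.log2(df.tpm_a.to_numpy() + pseudo)
    lb = np.log2(df.tpm_b.to_numpy() + pseudo)
    return float(pearsonr(la, lb).statistic)


@dataclass
class QpcrRecord:
    """Ct replicates for one gene in one sample (target + reference gene)."""

    gene_id: str
    timepoint: int
    condition: str
    ct_target: list[float]
    ct_reference: list[float]


@dataclass
class DdctResult:
    gene_id: str
    timepoint: int
    relative_expression: float  # 2^-ddCt
    ddct: float
    sd_ddct: float  # replicate SD of dCt, sample and calibrator combined
    sd_expression: float  # delta-method SD of 2^-ddCt


def qpcr_records_from_table(df: pd.DataFrame) -> list[QpcrRecord]:
    """Group a long-format Ct table (gene_id, timepoint, condition,
    replicate, ct_target, ct_reference) into QpcrRecords."""
    records = []
    for (gene, tp, cond), grp in df.groupby(["gene_id", "timepoint", "condition"]):
        records.append(
            QpcrRecord(gene, int(tp), cond, list(grp.ct_target), list(grp.ct_reference))
        )
    return records


def ddct(record: QpcrRecord, calibrator: QpcrRecord) -> DdctResult:
    """Relative expression 2^-ddCt of a sample against a calibrator.

    dCt = mean(target Ct) - mean(reference Ct) per sample;
    ddCt = dCt_sample - dCt_calibrator.  Replicate SDs of both dCts are
    combined in quadrature and propagated to the expression scale.
    """
    for rec in (record, calibrator):
        if not rec.ct_target or not rec.ct_reference:
            raise ValueError(f"missing Ct replicates for {rec.gene_id} ({rec.condition})")
    dct_s = float(np.mean(record.ct_target) - np.mean(record.ct_reference))
    dct_c = float(np.mean(calibrator.ct_target) - np.mean(calibrator.ct_reference))
    dd = dct_s - dct_c

    def _var(rec: QpcrRecord) -> float:
        vt = float(np.var(rec.ct_target, ddof=1)) if len(rec.ct_target) > 1 else 0.0
        vr = float(np.var(rec.ct_reference, ddof=1)) if len(rec.ct_reference) > 1 else 0.0
        return vt + vr

    sd = math.sqrt(_var(record) + _var(calibrator))
    rel = 2.0 ** (-dd)
    return DdctResult(record.gene_id, record.timepoint, rel, dd, sd, math.log(2) * rel * sd)


def relative_expression_table(qpcr: pd.DataFrame, calibrator_condition: str = "control") -> pd.DataFrame:
    """2^-ddCt per gene x timepoint from a long-format Ct table, using the
    matching calibrator-condition sample (default: the control at the same
    timepoint)."""
    records = qpcr_records_from_table(qpcr)
    by_key = {(r.gene_id, r.timepoint, r.condition): r for r in records}
    rows = []
    for r in records:
        if r.condition == calibrator_condition:
            continue
        cal = by_key.get((r.gene_id, r.timepoint, calibrator_condition))
        if cal is None:
            raise ValueError(f"no {calibrator_condition} calibrator for {r.gene_id} at {r.timepoint}")
        res = ddct(r, cal)
        rows.append(
            {
                "gene_id": r.gene_id,
                "timepoint": r.timepoint,
                "relative_expression": res.relative_expression,
                "sd_expression": res.sd_expression,
            }
        )
    return pd.DataFrame(rows)


def concordance(de_results: pd.DataFrame, qpcr_expression: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Sign agreement between sequencing log2 ratios and qPCR log2(2^-ddCt).

    ``qpcr_expression`` needs columns gene_id and relative_expression (one
    timepoint).  Returns (agreement fraction, paired table for plotting).
    Symmetric under jointly flipping all signs.
    """
    pair = de_results[["gene_id", "log2_ratio"]].merge(
        qpcr_expression[["gene_id", "relative_expression"]], on="gene_id", how="inner"
    )
    if len(pair) == 0:
        raise ValueError("no genes shared between DE results and qPCR table")
    pair["qpcr_log2"] = np.log2(pair.relative_expression)
    pair["agree"] = np.sign(pair.log2_ratio) == np.sign(pair.qpcr_log2)
    return float(pair.agree.mean()), pair
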