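"""Differential expression between two tag libraries (Audic-Claverie test).

For a gene observed ``x`` times among ``N1`` clean tags in one library, the
probability of observing ``y`` copies among ``N2`` tags in a second library,
under equal underlying expression, follows the posterior predictive

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is a negative binomial in y with x+1 successes and success
probability N1/(N1+N2).  The two-sided p-value doubles the smaller tail
(both tails include the observed count) and is capped at 1; it is symmetric
under swapping (x, N1) with (y, N2).

Tails are accumulated by direct summation of the density evaluated in log
space with log-gamma (direct factorials overflow near x+y ~ 170); the grid
is extended ~20 standard deviations past the predictive mean so the
truncated remainder is far below double precision.

A gene is called differentially expressed when BH-adjusted FDR <= 0.001 and
|log2 ratio of TPM| >= 1 (pseudocount: the TPM equivalent of one tag copy in
the larger library, so presence/absence genes get finite ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .tag_mapping import ExpressionProfile

DEFAULT_FDR_THRESHOLD = 1e-3
DEFAULT_MIN_ABS_LOG2_RATIO = 1.0

DE_COLUMNS = ["gene_id", "x", "y", "N1", "N2", "tpm1", "tpm2", "log2_ratio", "p_value", "fdr", "call"]


def _check_counts(x) -> np.ndarray:
    arr = np.asarray(x)
    if not np.all(np.equal(np.mod(arr, 1), 0)) or np.any(arr < 0):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def audic_claverie_p(x: int, y, N1: float, N2: float):
    """Two-sided Audic-Claverie p-value(s) for count y given count x.

    ``y`` may be a scalar or an array (the tag-count grid is computed once
    and both tails are read off cumulative sums).  Returns a float for
    scalar ``y``, else an ndarray.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    x = int(_check_counts(x))
    y_arr = _check_counts(y)
    scalar = y_arr.ndim == 0
    y_arr = np.atleast_1d(y_arr)

    q = N2 / (N1 + N2)
    log_q = np.log(q)
    log_1mq = np.log(N1 / (N1 + N2))
    mean = (x + 1) * N2 / N1
    sd = np.sqrt((x + 1) * q) / (1.0 - q)
    # grid pad: 20 predictive SDs plus the geometric decay scale of the far
    # tail (ratio -> q), so the truncated upper-tail remainder is < 1e-17
    ymax = int(max(int(y_arr.max()), mean) + 20.0 * sd + 40.0 * (1.0 + N2 / N1) + 60.0)

    ygrid = np.arange(ymax + 1)
    logpmf = (
        gammaln(x + ygrid + 1)
        - gammaln(x + 1)
        - gammaln(ygrid + 1)
        + ygrid * log_q
        + (x + 1) * log_1mq
    )
    pmf = np.exp(logpmf)
    lower = np.cumsum(pmf)  # P(Y <= y)
    upper = np.cumsum(pmf[::-1])[::-1]  # P(Y >= y), truncated tail < 1e-16
    p = 2.0 * np.minimum(lower[y_arr], upper[y_arr])
    p = np.minimum(p, 1.0)
    return float(p[0]) if scalar else p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(tpm1, tpm2, pseudo: float):
    """log2((tpm2 + pseudo) / (tpm1 + pseudo)); antisymmetric in its arguments."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return np.log2((np.asarray(tpm2, dtype=float) + pseudo) / (np.asarray(tpm1, dtype=float) + pseudo))


def call_degs(
    profile_control: ExpressionProfile,
    profile_infected: ExpressionProfile,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_abs_log2_ratio: float = DEFAULT_MIN_ABS_LOG2_RATIO,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """DE table over all genes detected (sense count > 0) in either library.

    x is the control count, y the infected count; the multiplicity family is
    exactly the detected genes (undetectable genes would only dilute the
    adjustment).  Call: 'up' / 'down' when fdr <= threshold and the TPM
    log2 ratio clears the threshold in that direction, else 'ns'.
    """
    a = profile_control.table[["gene_id", "sense_count"]].rename(columns={"sense_count": "x"})
    b = profile_infected.table[["gene_id", "sense_count"]].rename(columns={"sense_count": "y"})
    if len(a) and len(b) and not (set(a.gene_id) & set(b.gene_id)):
        raise ValueError("gene universes are disjoint; profiles are not comparable")
    df = a.merge(b, on="gene_id", how="outer").fillna(0)
    df["x"] = df.x.astype(np.int64)
    df["y"] = df.y.astype(np.int64)
    df = df[(df.x > 0) | (df.y > 0)].sort_values("gene_id", ignore_index=True)

    N1 = profile_control.total_clean
    N2 = profile_infected.total_clean
    if pseudo is None:
        pseudo = 1e6 / max(N1, N2)
    df["N1"] = N1
    df["N2"] = N2
    df["tpm1"] = df.x * 1e6 / N1
    df["tpm2"] = df.y * 1e6 / N2
    df["log2_ratio"] = log2_ratio(df.tpm1.to_numpy(), df.tpm2.to_numpy(), pseudo)
    df["p_value"] = [audic_claverie_p(x, y, N1, N2) for x, y in zip(df.x, df.y)]
    df["fdr"] = bh_fdr(df.p_value.to_numpy())
    sig = df.fdr <= fdr_threshold
    df["call"] = np.select(
        [sig & (df.log2_ratio >= min_abs_log2_ratio), sig & (df.log2_ratio <= -min_abs_log2_ratio)],
        ["up", "down"],
        default="ns",
    )
    return df[DE_COLUMNS]


def deg_set(de_table: pd.DataFrame) -> dict[str, str]:
    """Called DE genes -> direction, from a call_degs table."""
    sub = de_table[de_table.call != "ns"]
    return dict(zip(sub.gene_id, sub.call))


@dataclass
class TimepointComparison:
    """DEG sets per timepoint and their intersections.

    ``intersections`` maps a tuple of timepoint labels to a dict with the
    common genes and direction-pattern counts (consistent_up = up at every
    timepoint of the subset, consistent_down analogously, discordant =
    direction differs between timepoints).
    """

    deg_sets: dict[object, dict[str, str]]
    intersections: dict[tuple, dict]


def compare_timepoints(deg_by_timepoint: Mapping[object, Mapping[str, str]]) -> TimepointComparison:
    """Pairwise and full intersections of per-timepoint DEG sets with
    direction-pattern decomposition."""
    labels = list(deg_by_timepoint)
    if len(labels) < 2:
        raise ValueError("need at least two timepoints")
    sets = {t: dict(d) for t, d in deg_by_timepoint.items()}

    subsets: list[tuple] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            subsets.append((labels[i], labels[j]))
    if len(labels) > 2:
        subsets.append(tuple(labels))

    inter: dict[tuple, dict] = {}
    for subset in subsets:
        common = set(sets[subset[0]])
        for t in subset[1:]:
            common &= set(sets[t])
        up = down = disc = 0
        for g in common:
            dirs = {sets[t][g] for t in subset}
            if dirs == {"up"}:
                up += 1
            elif dirs == {"down"}:
                down += 1
            else:
                disc += 1
        inter[subset] = {
            "genes": common,
            "consistent_up": up,
            "consistent_down": down,
            "discordant": disc,
        }
    return TimepointComparison(sets, inter)
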