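"""GO tallies and pathway over-representation for DE gene sets.

For each term with m background genes, of which k are among the K DE genes
drawn from an N-gene background, the raw p is the hypergeometric upper tail
P(X >= k).  Two multiplicity treatments are emitted side by side, mirroring
the two thresholds used in tag-DGE pathway reports: Bonferroni-corrected P
(reported set, p_raw <= 0.05) and a BH Q-value (significant set, Q <= 0.05).

The background universe should be the genes detected in the compared library
pair — undetectable genes cannot be called DE and would distort m and N.
GO terms are treated as flat sets (no ancestor propagation); a gene may
count in several namespaces.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_fdr

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("component", "function", "process")
ANNOTATION_COLUMNS = ["gene_id", "term_id", "namespace"]

RESULT_COLUMNS = [
    "term_id",
    "namespace",
    "k",
    "m",
    "K",
    "N",
    "p_raw",
    "p_bonferroni",
    "q_value",
    "reported",
    "significant",
]


def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV with columns gene_id, term_id, namespace."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df[ANNOTATION_COLUMNS]


def hypergeom_enrich(
    de_genes,
    background,
    annotations: pd.DataFrame,
    namespace: str = "pathway",
    q_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of ``de_genes`` within ``background``.

    Terms with no background genes are skipped (logged).  The result is
    sorted by raw p ascending; ``reported`` flags p_raw <= 0.05 and
    ``significant`` flags q_value <= 0.05.
    """
    de = set(de_genes)
    bg = set(background)
    if not de <= bg:
        raise ValueError("de_genes must be a subset of background")
    N = len(bg)
    K = len(de)
    ann = annotations[annotations.namespace == namespace]
    rows = []
    for term, genes in ann.groupby("term_id").gene_id:
        term_bg = set(genes) & bg
        m = len(term_bg)
        if m == 0:
            logger.info("term %s has no background genes; skipped", term)
            continue
        k = len(term_bg & de)
        p_raw = float(hypergeom.sf(k - 1, N, m, K))
        rows.append((term, namespace, k, m, K, N, p_raw))
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows, columns=["term_id", "namespace", "k", "m", "K", "N", "p_raw"])
    n_terms = len(df)
    df["p_bonferroni"] = (df.p_raw * n_terms).clip(upper=1.0)
    df["q_value"] = bh_fdr(df.p_raw.to_numpy())
    df["reported"] = df.p_raw <= p_threshold
    df["significant"] = df.q_value <= q_threshold
    return df.sort_values(["p_raw", "term_id"], ignore_index=True)[RESULT_COLUMNS]


def go_tally(de_genes, annotations: pd.DataFrame) -> dict[str, int]:
    """Per GO namespace, the number of DE genes with at least one term.

    A gene annotated in several namespaces contributes to each tally.
    """
    de = set(de_genes)
    out: dict[str, int] = {}
    for ns in GO_NAMESPACES:
        genes = set(annotations.gene_id[annotations.namespace == ns])
        out[ns] = len(genes & de)
    return out
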