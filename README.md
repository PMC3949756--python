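# tagdge

Tag-based digital gene expression (DGE) profiling pipeline for
host–pathogen transcriptomics, with a synthetic dual-organism data
generator for end-to-end validation.

## The problem

DGE (a SAGE descendant on Illumina sequencing) quantifies a transcriptome
by counting one short cDNA tag per transcript molecule: NlaIII cuts the
cDNA at its CATG sites, MmeI releases the 17 nt downstream, and the
resulting 21 nt tag (CATG + 17 nt) is sequenced as the 5' end of a 49 nt
read. This package implements the full analysis chain used to profile an
insect host responding to a fungal pathogen across an infection time
course (infected/control libraries at 8, 15 and 24 hours
post-inoculation): read cleaning, virtual tag-library mapping with
sense/antisense classification, host/pathogen tag partitioning, TPM
normalization, exact differential-expression testing, pathway
over-representation and sequencing QC.

It is written for researchers who need a tested, reusable implementation
of this tag-counting statistics stack — in particular the
Audic–Claverie test — and for anyone who wants to study its operating
characteristics on data with known ground truth.

## The statistics at the core

For a gene with `x` tags among `N1` clean tags in one library, the
probability of seeing `y` tags among `N2` in a second library under equal
expression follows the posterior predictive

```
p(y | x) = (N2/N1)^y · (x+y)! / ( x!·y!·(1 + N2/N1)^(x+y+1) )
```

(a negative binomial in `y` with `x+1` successes and success probability
`N1/(N1+N2)`). The two-sided p-value doubles the smaller tail, both tails
including the observed count, capped at 1; tails are accumulated in log
space with log-gamma. A gene is called differentially expressed when the
Benjamini–Hochberg FDR is ≤ 0.001 **and** |log2 ratio of TPM| ≥ 1, where
TPM = count × 10⁶ / total clean tags and the log2 ratio uses a
pseudocount equal to one tag copy in the larger library.

Pathway over-representation uses the hypergeometric upper tail with both
Bonferroni-corrected P and BH Q-values; qPCR concordance uses the
2^−ΔΔCt method against the control sample as calibrator.

## Worked example

Simulate a small two-condition experiment, map it, and call DEGs:

```python
import tagdge as T

cfg = T.SyntheticConfig(n_host_genes=200, n_pathogen_genes=40,
                        depth_per_library=200_000, seed=42)
tx = T.simulate_transcriptome(cfg)
truth = T.simulate_truth(cfg, tx)
host_lib = T.build_virtual_tag_library(tx.subset("host"))
path_lib = T.build_virtual_tag_library(tx.subset("pathogen"))

profiles = {}
for cond in ("control", "infected"):
    reads, _ = T.simulate_library(tx, truth, cfg, 15, cond)
    table = T.clean_reads(reads, T.DEFAULT_ADAPTOR3)
    asn = T.assign_tags(table, host_lib, path_lib)
    prof = T.gene_counts(asn, table)
    host = prof.table[prof.table.gene_id.str.startswith("bm_")]
    profiles[cond] = T.ExpressionProfile(prof.library_id, prof.total_clean,
                                         host.reset_index(drop=True))

de = T.call_degs(profiles["control"], profiles["infected"])
```

This prints (via the summaries in the example script):

```
host library: {'all_tags': 674, 'unambiguous_tags': 674, 'genes_with_site': 200}
clean summary: {'library_id': 'ZC2', 'raw_reads': 200000, 'total_clean': 188110,
                'distinct_clean': 1153, 'dropped': {'adaptor_only': 1992,
                'contains_N': 2440, 'bad_length': 4120, 'singleton': 3338}}
5 DEGs of 195 genes (up=4, down=1); true DE at 15 hpi: 10
 gene_id   x    y        tpm1         tpm2  log2_ratio       p_value           fdr call
bm_g0033 563 2779 2992.929669 14770.051714    2.301004  0.000000e+00  0.000000e+00   up
bm_g0069 124   19  659.188773   100.982721   -2.644168  2.525279e-20  6.155369e-19 down
bm_g0147 157  795  834.618043  4225.329655    2.332531 3.177022e-103 2.065064e-101   up
bm_g0156 959 4494 5098.080910 23885.071033    2.226901  0.000000e+00  0.000000e+00   up
bm_g0195 353  863 1876.561586  4586.741500    1.286968  1.093547e-49  5.331039e-48   up
```

The virtual library indexes every CATG+17 nt window of the 200 host
transcripts (674 reference tags, all gene-unique here). Of 200,000 raw
reads, 188,110 survive the filter cascade; the columns `x, y` are clean
tag counts in control and infected libraries, `tpm1, tpm2` the normalized
abundances, and the joint threshold (FDR ≤ 0.001, |log2 ratio| ≥ 1) calls
5 of the 10 planted fold changes at this shallow depth — the remainder
are low-abundance or sub-2-fold genes, which is the expected operating
behaviour (sensitivity exceeds 0.9 at the default 2 M-tag depth and
8-fold changes).

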