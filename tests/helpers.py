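"""Shared helpers for the test suite."""

import zlib

import numpy as np

import tagdge as T


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test RNG, independent of the library's seeds."""
    return np.random.default_rng(zlib.crc32(name.encode()) % 2**31)


def host_profile(profile: T.ExpressionProfile) -> T.ExpressionProfile:
    """Restrict an expression profile to host genes (bm_ namespace)."""
    table = profile.table[profile.table.gene_id.str.startswith("bm_")].reset_index(drop=True)
    return T.ExpressionProfile(profile.library_id, profile.total_clean, table)


def run_pair(cfg: T.SyntheticConfig, timepoint: int, host_lib=None, tx=None, truth=None,
             conditions=("control", "infected"), replicates=(0, 0)):
    """Simulate, clean, map and count a pair of libraries; returns host-only
    expression profiles in the order of ``conditions``."""
    if tx is None:
        tx = T.simulate_transcriptome(cfg)
    if truth is None:
        truth = T.simulate_truth(cfg, tx)
    if host_lib is None:
        host_lib = T.build_virtual_tag_library(tx.subset("host"))
    profiles = []
    for cond, rep in zip(conditions, replicates):
        reads, _ = T.simulate_library(tx, truth, cfg, timepoint, cond, replicate=rep)
        table = T.clean_reads(reads, T.DEFAULT_ADAPTOR3)
        assignments = T.assign_tags(table, host_lib)
        profiles.append(host_profile(T.gene_counts(assignments, table)))
    return tx, truth, profiles
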