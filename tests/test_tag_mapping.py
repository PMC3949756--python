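"""Tag-to-gene assignment: matching, precedence, counting, strandedness."""

import math

import numpy as np
import pandas as pd
import pytest

import tagdge as T
from tagdge.tag_library import GeneRecord, ReferenceTranscriptome
from helpers import rng_for

TAG1 = "CATG" + "ACGTACGTACGTACGTA"
TAG2 = "CATG" + "GGGGCCCCAAAATTTTG"


def lib_of(**genes):
    recs = [GeneRecord(g, "host", s) for g, s in genes.items()]
    return T.build_virtual_tag_library(ReferenceTranscriptome(recs))


def mutate(tag, pos, base):
    return tag[:pos] + base + tag[pos + 1 :]


class TestMatchTag:
    def test_exact_sense(self):
        lib = lib_of(A="CC" + TAG1)
        assert T.match_tag(TAG1, lib) == [("A", "sense", 0)]

    def test_exact_antisense(self):
        lib = lib_of(A="CC" + TAG1)
        assert T.match_tag(T.revcomp(TAG1), lib) == [("A", "antisense", 0)]

    def test_one_mismatch_in_variable_region(self):
        lib = lib_of(A="CC" + TAG1)
        variant = mutate(TAG1, 10, "A" if TAG1[10] != "A" else "C")
        assert T.match_tag(variant, lib) == [("A", "sense", 1)]

    def test_anchor_mismatch_not_allowed(self):
        lib = lib_of(A="CC" + TAG1)
        variant = mutate(TAG1, 2, "A")  # breaks the CATG anchor
        assert T.match_tag(variant, lib) == []

    def test_exact_hit_suppresses_mismatch_hits(self):
        # TAG1 exact in A; 1-mismatch from a tag of B
        near = mutate(TAG1, 8, "A" if TAG1[8] != "A" else "C")
        lib = lib_of(A="CC" + TAG1, B="GG" + near)
        assert T.match_tag(TAG1, lib) == [("A", "sense", 0)]

    def test_malformed_tag_rejected(self):
        lib = lib_of(A="CC" + TAG1)
        with pytest.raises(ValueError):
            T.match_tag("CATGNNN", lib)
        with pytest.raises(ValueError):
            T.match_tag("N" * 21, lib)

    def test_agrees_with_brute_force_oracle(self, small_world):
        *_, host_lib, _ = small_world
        ref_tags = list(host_lib.tags)
        rng = rng_for("match-oracle")

        def oracle(tag):
            hits = set()
            for strand, query in (("sense", tag), ("antisense", T.revcomp(tag))):
                for ref in ref_tags:
                    d = sum(a != b for a, b in zip(query, ref))
                    if d == 0:
                        hits.add((ref, strand, 0))
                    elif d == 1 and query[:4] == "CATG":
                        hits.add((ref, strand, 1))
            out = set()
            exact = {h for h in hits if h[2] == 0}
            for ref, strand, mm in exact or hits:
                for gene in (g for g, _ in host_lib.get(ref)):
                    out.add((gene, strand, mm))
            return out

        queries = []
        for _ in range(120):
            base = ref_tags[rng.integers(len(ref_tags))]
            if rng.random() < 0.4:
                base = T.revcomp(base)
            k = rng.integers(0, 3)
            for _ in range(k):
                pos = int(rng.integers(0, 21))
                base = mutate(base, pos, "ACGT"[rng.integers(4)])
            queries.append(base)
        for _ in range(30):
            queries.append("".join("ACGT"[i] for i in rng.integers(0, 4, 21)))
        for q in queries:
            got = {(g, s, m) for g, s, m in T.match_tag(q, host_lib)}
            # suppressing mismatch hits only when an exact hit exists
            expected = oracle(q)
            exact = {h for h in expected if h[2] == 0}
            assert got == (exact or expected)


class TestAssignTags:
    def make_table(self, counts):
        return T.CleanTagTable("x", counts)

    def test_multi_gene_tag_is_ambiguous(self):
        lib = lib_of(A="CC" + TAG1, B="TT" + TAG1)
        asn = T.assign_tags(self.make_table({TAG1: 5}), lib)
        assert list(asn.category) == ["gene_ambiguous"]
        assert asn.gene_id.isna().all()

    def test_pathogen_precedence_after_host(self):
        host = lib_of(A="CC" + TAG1)
        path = lib_of(P="GG" + TAG2)
        asn = T.assign_tags(self.make_table({TAG2: 4}), host, path)
        row = asn.iloc[0]
        assert row.category == "pathogen_gene" and row.gene_id == "P" and row.mismatches == 0

    def test_host_hit_wins_over_pathogen(self):
        host = lib_of(A="CC" + TAG1)
        path = lib_of(P="GG" + TAG1)
        asn = T.assign_tags(self.make_table({TAG1: 4}), host, path)
        assert asn.iloc[0].category == "gene_unambiguous"
        assert asn.iloc[0].gene_id == "A"

    def test_genome_only_and_unknown(self):
        host = lib_of(A="CC" + TAG1)
        genome = T.GenomeIndex("TTTT" + TAG2 + "GGGG")
        table = self.make_table({TAG2: 3, "A" * 21: 2})
        asn = T.assign_tags(table, host, genome=genome).set_index("tag")
        assert asn.loc[TAG2].category == "genome_only"
        assert asn.loc["A" * 21].category == "unknown"

    def test_genome_matches_either_strand(self):
        host = lib_of(A="CC" + TAG1)
        genome = T.GenomeIndex("TTTT" + T.revcomp(TAG2) + "GGGG")
        asn = T.assign_tags(self.make_table({TAG2: 3}), host, genome=genome)
        assert asn.iloc[0].category == "genome_only"

    def test_every_tag_gets_exactly_one_category(self, small_pipeline):
        asn = small_pipeline["infected"]["assignments"]
        table = small_pipeline["infected"]["table"]
        assert len(asn) == table.distinct_clean
        assert set(asn.category) <= set(
            ["gene_unambiguous", "gene_ambiguous", "genome_only", "pathogen_gene", "unknown"]
        )
        assert asn.copies.sum() == table.total_clean

    def test_record_permutation_invariance(self, small_world):
        cfg, tx, truth, host_lib, _ = small_world
        table = T.CleanTagTable("x", {t: 3 for t in list(host_lib.tags)[:50]})
        shuffled = ReferenceTranscriptome(list(tx.subset("host").records[::-1]))
        lib2 = T.build_virtual_tag_library(shuffled)
        a = T.assign_tags(table, host_lib)
        b = T.assign_tags(table, lib2)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_tags_land_in_unknown_without_singleton_filter(self):
        # exposes the mapper to raw noise tags by tallying reads directly
        # (the cleaning cascade would have removed them as singletons)
        cfg = T.SyntheticConfig(
            n_host_genes=30, n_pathogen_genes=0, depth_per_library=50_000,
            per_base_error_rate=0.0, singleton_noise_fraction=0.02,
            adaptor_only_fraction=0.0, seed=23,
        )
        tx = T.simulate_transcriptome(cfg)
        truth = T.simulate_truth(cfg, tx)
        lib = T.build_virtual_tag_library(tx)
        reads, emission = T.simulate_library(tx, truth, cfg, 8, "control")
        from collections import Counter

        tally = Counter(s[:21] for s, _ in reads.iter_reads())
        table = T.CleanTagTable("raw", dict(tally))
        asn = T.assign_tags(table, lib)
        unknown_copies = asn.copies[asn.category == "unknown"].sum()
        f, n = 0.02, cfg.depth_per_library
        assert abs(unknown_copies - emission.n_noise) <= 5  # rare random collisions
        assert abs(unknown_copies - f * n) <= 3 * np.sqrt(f * (1 - f) * n) + 5


class TestGeneCounts:
    def test_copies_summed_per_gene(self):
        lib = lib_of(A="CC" + TAG1 + "GGA" + TAG2)
        table = T.CleanTagTable("x", {TAG1: 10, TAG2: 5})
        prof = T.gene_counts(T.assign_tags(table, lib), table)
        assert prof.table.set_index("gene_id").loc["A", "sense_count"] == 15

    def test_tpm_definition(self):
        lib = lib_of(A="CC" + TAG1)
        filler = "CATG" + "T" * 17  # unmapped filler to pad the library total
        table = T.CleanTagTable("x", {TAG1: 5, filler: 10**6 - 5})
        prof = T.gene_counts(T.assign_tags(table, lib), table)
        assert prof.table.set_index("gene_id").loc["A", "tpm"] == pytest.approx(5.0)

    def test_tpm_sum_identity(self, small_pipeline):
        prof = small_pipeline["control"]["profile"]
        expected = 1e6 * prof.table.sense_count.sum() / prof.total_clean
        assert prof.table.tpm.sum() == pytest.approx(expected)

    def test_zero_total_rejected(self):
        lib = lib_of(A="CC" + TAG1)
        table = T.CleanTagTable("x", {})
        with pytest.raises(ValueError, match="TPM"):
            T.gene_counts(T.assign_tags(table, lib), table)

    def test_antisense_excluded_from_tpm(self):
        lib = lib_of(A="CC" + TAG1)
        table = T.CleanTagTable("x", {TAG1: 8, T.revcomp(TAG1): 4})
        prof = T.gene_counts(T.assign_tags(table, lib), table)
        row = prof.table.set_index("gene_id").loc["A"]
        assert row.sense_count == 8 and row.antisense_count == 4
        assert row.tpm == pytest.approx(8e6 / 12)


class TestStrandSummary:
    def test_basic_counts(self):
        lib = lib_of(A="CC" + TAG1, B="GG" + TAG2)
        table = T.CleanTagTable("x", {TAG1: 5, TAG2: 5, T.revcomp(TAG2): 2})
        ss = T.strand_summary(T.assign_tags(table, lib))
        assert ss.genes_with_sense == 2
        assert ss.genes_with_antisense == 1
        assert ss.genes_bidirectional == 1
        assert ss.sense_to_antisense_transcript_ratio == pytest.approx(10 / 2)

    def test_no_antisense_gives_infinite_ratio(self):
        lib = lib_of(A="CC" + TAG1)
        table = T.CleanTagTable("x", {TAG1: 5})
        ss = T.strand_summary(T.assign_tags(table, lib))
        assert ss.genes_with_antisense == 0
        assert math.isinf(ss.sense_to_antisense_transcript_ratio)

    def test_zero_antisense_config_recovers_zero(self):
        cfg = T.SyntheticConfig(
            n_host_genes=40, n_pathogen_genes=0, depth_per_library=50_000,
            antisense_gene_fraction=0.0, per_base_error_rate=0.0, seed=29,
        )
        tx = T.simulate_transcriptome(cfg)
        truth = T.simulate_truth(cfg, tx)
        lib = T.build_virtual_tag_library(tx)
        reads, _ = T.simulate_library(tx, truth, cfg, 8, "control")
        table = T.clean_reads(reads, T.DEFAULT_ADAPTOR3)
        ss = T.strand_summary(T.assign_tags(table, lib))
        assert ss.genes_with_antisense == 0
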