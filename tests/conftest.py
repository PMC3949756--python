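import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tagdge as T

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return T.SyntheticConfig(
        n_host_genes=60,
        n_pathogen_genes=12,
        transcript_length_range=(100, 400),
        depth_per_library=60_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Transcriptome, truth and tag libraries for the small test config."""
    tx = T.simulate_transcriptome(small_config)
    truth = T.simulate_truth(small_config, tx)
    host_lib = T.build_virtual_tag_library(tx.subset("host"))
    path_lib = T.build_virtual_tag_library(tx.subset("pathogen"))
    return small_config, tx, truth, host_lib, path_lib


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    """Cleaned, mapped and counted control/infected pair at 15 hpi."""
    cfg, tx, truth, host_lib, path_lib = small_world
    out = {}
    for cond in ("control", "infected"):
        reads, emission = T.simulate_library(tx, truth, cfg, 15, cond)
        table = T.clean_reads(reads, T.DEFAULT_ADAPTOR3)
        assignments = T.assign_tags(table, host_lib, path_lib)
        out[cond] = {
            "reads": reads,
            "emission": emission,
            "table": table,
            "assignments": assignments,
            "profile": T.gene_counts(assignments, table),
        }
    return out
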