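"""Shared fixtures: simulated datasets are generated once per session."""

from __future__ import annotations

import pytest

from mitolineage.experiments import default_config, precursor_recovery, trace_once
from mitolineage.simulate import CloneSimConfig


@pytest.fixture(scope="session")
def default_run():
    """One end-to-end run of the default 3-donor scenario."""
    return trace_once(default_config(seed=11))


@pytest.fixture(scope="session")
def recovery_stats():
    """Replicated precursor-recovery statistics at the study conditions.

    Shared between the recovery, power and mode-sensitivity tests so the 200
    replicates are simulated only once.
    """
    return precursor_recovery(n_replicates=200, seed=1)


@pytest.fixture()
def tiny_clone_config():
    """Small, fast clonal scenario for unit tests."""
    clusters = {
        "skin": (("pre", "myeloid", 30), ("skin T", "T", 20)),
        "synovium": (("pre", "myeloid", 24), ("mac", "myeloid", 24), ("syn T", "T", 20)),
    }
    return CloneSimConfig(
        n_donors=1,
        n_germline_variants_per_donor=4,
        n_clones=4,
        clone_tree_depth=2,
        somatic_variants_per_clone=2,
        clusters_per_tissue=clusters,
        precursor_cluster="pre",
        downstream_clusters=("pre", "mac"),
        independent_clusters=(),
        coverage_model=(40.0, 10.0),
        base_error_rate=0.0,
        seed=3,
    )
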