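"""Shared fixtures: one moderately sized synthetic dataset reused across
module tests (session-scoped; everything is seed-reproducible)."""

import numpy as np
import pytest

import epistate as es


@pytest.fixture(scope="session")
def spec():
    return es.SimulationSpec(n_bins=4000, seed=11)


@pytest.fixture(scope="session")
def state_track(spec):
    return es.simulate_state_track(spec)


@pytest.fixture(scope="session")
def tracks(state_track, spec):
    track, cpg = es.simulate_tracks(state_track, spec)
    return track, cpg


@pytest.fixture(scope="session")
def genes_truth(state_track):
    return es.simulate_gene_models(state_track, 300, seed=11)


@pytest.fixture(scope="session")
def truth_table(genes_truth):
    """Gene-state table built from simulation truth (no decoding noise)."""
    _, truth = genes_truth
    return truth.rename(columns={"true_genebody_state": "genebody_state",
                                 "true_tss_state": "tss_state"})


@pytest.fixture(scope="session")
def cells(truth_table, spec):
    return es.simulate_cells(truth_table, spec)


@pytest.fixture(scope="session")
def norm_cells(cells):
    return es.downsample_cells(cells, target=5000, seed=1)


@pytest.fixture(scope="session")
def cell_distance(norm_cells):
    return es.spearman_distance(norm_cells)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
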