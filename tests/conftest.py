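"""Shared fixtures: scaled-down simulated datasets reused across tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sigtrace import SimConfig, simulate_single_cell, simulate_trial
from sigtrace.markers import build_all_signatures, marker_table
from sigtrace.scqc import (
    cluster_cells,
    merge_small_clusters,
    normalize_cells,
    qc_filter_barcodes,
)


def small_sim_config(**overrides) -> SimConfig:
    """A fast, reduced-size study configuration for unit tests."""
    defaults = dict(
        n_cell_types=3,
        n_genes=400,
        n_markers_per_type=12,
        marker_fold_change=8.0,
        cells_per_type=60,
        mito_gene_count=10,
        n_patients=20,
        n_activity_genes=30,
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_single_cell():
    """Default-condition single-cell dataset (5 planted types, fold 8)."""
    return simulate_single_cell(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clustered_single_cell(default_single_cell):
    """QC-filtered, normalized, clustered and merged default dataset."""
    cells, truth = default_single_cell
    filtered, report = qc_filter_barcodes(cells)
    norm = normalize_cells(filtered)
    labels = cluster_cells(norm, seed=1, donors=filtered.donor)
    labels = merge_small_clusters(norm, labels)
    return filtered, norm, labels, truth, report


@pytest.fixture(scope="session")
def default_signatures(clustered_single_cell):
    filtered, norm, labels, truth, _ = clustered_single_cell
    table = marker_table(norm, labels, filtered.gene_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sigs = build_all_signatures(table)
    return table, sigs


@pytest.fixture(scope="session")
def default_trial():
    """Default-condition trial (100 patients 1:4, effect_size 0.5)."""
    return simulate_trial(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
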