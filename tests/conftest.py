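"""Shared fixtures: synthetic landscapes, fitted trees, small partitions.

Everything is generated programmatically and seeded; heavyweight objects
(the default landscape, its pruned tree, the full Hamming graph) are
session-scoped so the suite fits a single-CPU budget.
"""

from __future__ import annotations

import numpy as np
import pytest

import sdclouds as sc
from sdclouds.etr_data import all_cores


@pytest.fixture(scope="session")
def landscape() -> sc.EtrMap:
    """Default synthetic landscape (seed 42): additive G-centric effects
    plus mild noise, emulating an SD-core expression map."""
    return sc.generate_synthetic_landscape()


@pytest.fixture(scope="session")
def noise_free_landscape() -> sc.EtrMap:
    return sc.generate_synthetic_landscape(
        sc.SyntheticLandscapeConfig(noise_sd=0.0)
    )


@pytest.fixture(scope="session")
def constant_landscape() -> sc.EtrMap:
    return sc.EtrMap(
        {c: 0.5 for c in all_cores()}, {c: "synthetic" for c in all_cores()}
    )


@pytest.fixture(scope="session")
def tree(landscape) -> sc.PrunedLatticeTree:
    return sc.PrunedLatticeTree().fit(landscape)


@pytest.fixture(scope="session")
def constant_tree(constant_landscape) -> sc.PrunedLatticeTree:
    return sc.PrunedLatticeTree().fit(constant_landscape)


@pytest.fixture(scope="session")
def hamming_graph(landscape) -> "sc.mutgraph.nx.Graph":
    return sc.build_hamming_graph(landscape)


def quantile_bin_partition(etr_map: sc.EtrMap, n_bins: int = 100) -> sc.CloudTable:
    """Synthetic cloud partition: cores binned by ETR quantile.

    Stands in for a fine-grained activity-cloud partition when a check
    needs many clouds with distinct mean ETRs (e.g. correlation
    parameter-recovery); it is not produced by the clustering machinery.
    """
    cores = etr_map.cores
    etrs = etr_map.etr_array(cores)
    edges = np.quantile(etrs, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, etrs, side="right") - 1, 0, n_bins - 1)
    members: dict[int, list[str]] = {}
    for core, b in zip(cores, bins):
        members.setdefault(int(b), []).append(core)
    # relabel densely in bin order
    dense = {
        i: cores_
        for i, (_, cores_) in enumerate(sorted(members.items()))
    }
    return sc.CloudTable(dense, etr_map)


@pytest.fixture(scope="session")
def binned_clouds(landscape) -> sc.CloudTable:
    return quantile_bin_partition(landscape, n_bins=100)
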