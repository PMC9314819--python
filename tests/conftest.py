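"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

import leafgas as lg


def dijkstra_geodesic(ias: np.ndarray, seeds: np.ndarray, voxel_size: float) -> np.ndarray:
    """Exact shortest-path distance on the 26-neighbour voxel graph.

    Independent oracle for the production geodesic propagation: builds
    the sparse IAS adjacency graph with edge weights equal to the
    Euclidean offset length times the voxel pitch and runs multi-source
    Dijkstra.  Returns a dense field (inf where unreachable or solid).
    """
    shape = ias.shape
    idx = -np.ones(shape, dtype=np.int64)
    nodes = np.argwhere(ias)
    idx[ias] = np.arange(len(nodes))
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    rows, cols, weights = [], [], []
    for off in offsets:
        sl_a = tuple(slice(max(0, -o), shape[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), shape[i] + min(0, o)) for i, o in enumerate(off))
        m = ias[sl_a] & ias[sl_b]
        a, b = idx[sl_a][m], idx[sl_b][m]
        rows.append(a)
        cols.append(b)
        weights.append(np.full(len(a), np.linalg.norm(off) * voxel_size))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    graph = sparse.coo_matrix(
        (
            np.concatenate([weights, weights]),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(len(nodes), len(nodes)),
    ).tocsr()
    seed_ids = [idx[tuple(s)] for s in np.atleast_2d(seeds)]
    dist = dijkstra(graph, indices=seed_ids, min_only=True)
    out = np.full(shape, np.inf)
    out[ias] = dist
    return out


def small_phantom_params(seed: int = 0, **overrides) -> lg.LeafPhantomParams:
    """A quick 64^3-scale leaf phantom with stomatal density boosted so a
    few stomata fall inside the small lateral field."""
    kwargs = dict(
        shape=(64, 64, 64),
        voxel_size_um=2.0,
        thickness_epidermis_adaxial=8.0,
        thickness_palisade=50.0,
        thickness_spongy=40.0,
        thickness_epidermis_abaxial=8.0,
        porosity_palisade=0.25,
        porosity_spongy=0.4,
        palisade_diameter_um=24.0,
        stomatal_density_mm2=150.0,
        bse_spacing_um=None,
        seed=seed,
    )
    kwargs.update(overrides)
    return lg.LeafPhantomParams(**kwargs)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default phantom, generated once per session."""
    params = lg.LeafPhantomParams(seed=11)
    volume, truth = lg.generate_leaf_volume(params)
    return params, volume, truth


@pytest.fixture(scope="session")
def small_phantom():
    params = small_phantom_params(seed=4)
    volume, truth = lg.generate_leaf_volume(params)
    return params, volume, truth
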