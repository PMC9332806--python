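"""Shared fixtures and the brute-force graph oracle.

The oracle enumerates all pixel pairs and applies the distance and gradient
thresholds directly; it is deliberately independent of the windowed
construction it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungnet.hu_layers import LayerMask
from lungnet.pixel_graph import GraphParams


def brute_force_edges(layer: LayerMask, params: GraphParams) -> set[tuple[int, int]]:
    """All-pairs reference edge set, ids in row-major crop order."""
    n_rows, n_cols = layer.mask.shape
    rows, cols = np.nonzero(layer.mask)
    ids = rows * n_cols + cols
    vals = layer.hu[layer.mask]
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d2 = (rows[i] - rows[j]) ** 2 + (cols[i] - cols[j]) ** 2
            if d2 <= params.rd_max**2 and abs(vals[i] - vals[j]) <= params.delta_max:
                edges.add((int(min(ids[i], ids[j])), int(max(ids[i], ids[j]))))
    return edges


def random_layer(rng: np.random.Generator, size: int = 20,
                 density: float = 0.5, value_span: float = 200.0) -> LayerMask:
    """Random mask with random HU-like values, for oracle comparisons."""
    mask = rng.random((size, size)) < density
    hu = -600.0 + rng.uniform(0, value_span, size=(size, size))
    return LayerMask("test", mask, hu)


@pytest.fixture
def rng():
    return np.random.default_rng(20220727)


@pytest.fixture
def uniform_layer():
    """All 65x65 pixels in band, identical value: the densest possible layer."""
    return LayerMask(
        "emphysema", np.ones((65, 65), bool), np.full((65, 65), -1000.0)
    )
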