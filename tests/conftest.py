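import numpy as np
import pytest

import fogbank as fb


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sheet5():
    """Noise-free 5-cell confluent sheet with ground truth."""
    spec = fb.SheetSpec(n_cells=5, rng_seed=1, shape=(128, 128))
    img, truth, centers = fb.make_confluent_sheet(spec)
    return img, truth, centers


def random_label_pair(rng, shape=(12, 12), max_labels=4):
    """Random pair of small label images with background."""
    ref = rng.integers(0, max_labels + 1, size=shape)
    seg = rng.integers(0, max_labels + 1, size=shape)
    return ref, seg


def bfs_oracle_distances(traversable, sources, connectivity=8):
    """Textbook BFS over the explicit pixel adjacency graph (networkx)."""
    import networkx as nx

    h, w = traversable.shape
    g = nx.Graph()
    offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for r in range(h):
        for c in range(w):
            if not traversable[r, c]:
                continue
            g.add_node((r, c))
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and traversable[nr, nc]:
                    g.add_edge((r, c), (nr, nc))
    import networkx as nx

    lengths = nx.multi_source_dijkstra_path_length(g, set(map(tuple, sources)))
    dist = np.full((h, w), np.inf)
    for (r, c), d in lengths.items():
        dist[r, c] = d
    return dist
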