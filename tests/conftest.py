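import numpy as np
import pytest

from transintro.io import (
    LocusAlignment,
    SampleRecord,
    SampleSheet,
    coding_mask_from_ranges,
    partition_by_species,
)


def make_alignment(pairs, name="toy", coding_ranges=None, frame_offset=0):
    L = len(pairs[0][1])
    return LocusAlignment(
        locus_name=name,
        sequences=tuple(pairs),
        coding_mask=coding_mask_from_ranges(L, coding_ranges),
        frame_offset=frame_offset,
    )


@pytest.fixture
def sheet5():
    return SampleSheet(tuple(
        SampleRecord(i, sp, "pop", f"ind_{i}") for i, sp in [
            ("L1", "lyrata"), ("L2", "lyrata"),
            ("H1", "halleri"), ("H2", "halleri"),
            ("OUT", "thaliana"),
        ]
    ))


@pytest.fixture
def five_taxon_alignment(sheet5):
    base = "AAAAAAAAAACCCCCGGGGG"

    def mut(s, pos, b):
        s = list(s)
        for p in pos:
            s[p] = b
        return "".join(s)

    return make_alignment([
        ("L1", base),
        ("L2", mut(base, [19], "T")),
        ("H1", mut(base, [0, 1, 2], "T")),
        ("H2", mut(base, [0, 1, 2, 18], "T")),
        ("OUT", mut(base, [5, 6, 7, 10, 11], "T")),
    ], coding_ranges=[[1, 18]])


@pytest.fixture
def five_taxon_partition(five_taxon_alignment, sheet5):
    return partition_by_species(five_taxon_alignment, sheet5)


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree topology with positive branch lengths,
    returned as (leaf-pair path-distance matrix, set of non-trivial splits)."""
    import itertools

    import networkx as nx

    G = nx.Graph()
    nodes = [f"t{i}" for i in range(n_taxa)]
    # random sequential attachment: start from a 3-star
    G.add_node("i0")
    for leaf in nodes[:3]:
        G.add_edge("i0", leaf, weight=float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for leaf in nodes[3:]:
        edges = list(G.edges(data=True))
        u, v, d = edges[int(rng.integers(len(edges)))]
        G.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        w = d["weight"]
        split = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, weight=w * split)
        G.add_edge(mid, v, weight=w * (1 - split))
        G.add_edge(mid, leaf, weight=float(rng.uniform(0.05, 1.0)))
    D = np.zeros((n_taxa, n_taxa))
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = dist[nodes[i]][nodes[j]]
    # non-trivial splits, canonicalised as the side not containing nodes[0]
    canon = set()
    for u, v in list(G.edges()):
        H = G.copy()
        H.remove_edge(u, v)
        side = {x for x in nx.node_connected_component(H, u) if x in nodes}
        if 1 < len(side) < n_taxa - 1:
            canon.add(frozenset(side if nodes[0] not in side else set(nodes) - side))
    return D, nodes, canon
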