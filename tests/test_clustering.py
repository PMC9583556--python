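"""PWM similarity, graph clustering, and unique-motif derivation."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from conftest import sharp_pwm
from crmkit.clustering import (
    MotifGraph,
    build_motif_graph,
    cluster_graph,
    derive_um,
    motif_similarity,
)
from crmkit.motifs import Motif, MotifSite, PWMModel, encode


def test_self_similarity_is_one():
    m = sharp_pwm("ACGTACGTAC", 0.8)
    assert motif_similarity(m, m) == pytest.approx(1.0)


def test_reverse_complement_similarity_is_one():
    m = sharp_pwm("ACGTTGCATC", 0.8)
    assert motif_similarity(m, m.reverse_complement()) == pytest.approx(1.0)


def test_orthogonal_columns_score_zero():
    # column (1,0,0,0) vs (0,1,0,0): TV similarity 0 per column
    a = PWMModel(np.array([[0.97, 0.97, 0.97, 0.97, 0.97, 0.97],
                           [0.01] * 6, [0.01] * 6, [0.01] * 6]),
                 background=np.full(4, 0.25))
    b = PWMModel(np.array([[0.01] * 6,
                           [0.97, 0.97, 0.97, 0.97, 0.97, 0.97],
                           [0.01] * 6, [0.01] * 6]),
                 background=np.full(4, 0.25))
    # with pure one-hot columns the score would be exactly 0; with the tiny
    # pseudocount mass it stays near 0 and far below any edge cutoff
    assert motif_similarity(a, b) < 0.1


def test_minimum_overlap_enforced():
    a = sharp_pwm("ACGTA")  # width 5 < minimum overlap 6
    b = sharp_pwm("ACGTA")
    assert motif_similarity(a, b) == 0.0


def test_edge_cutoff_is_strict():
    models = {"a": sharp_pwm("ACGTACGTAC", 0.9), "b": sharp_pwm("ACGTACGTAC", 0.9)}
    g1 = build_motif_graph(models, edge_cutoff=0.8)
    assert g1.graph.number_of_edges() == 1

    # a pair whose similarity is exactly the cutoff gets no edge
    g2 = build_motif_graph(models, edge_cutoff=1.0,
                           similarity=lambda x, y: 1.0)
    assert g2.graph.number_of_edges() == 0


def test_dissimilar_set_gives_edgeless_graph():
    models = {"a": sharp_pwm("AAAAAAAAAA", 0.9), "b": sharp_pwm("CGCGCGCGCG", 0.9)}
    g = build_motif_graph(models, edge_cutoff=0.8)
    assert g.graph.number_of_edges() == 0


def _density_partition_oracle(g):
    """Exhaustive best bipartition of a small graph by (intra-density,
    -cut-edges); used to validate the clustering on two bridged cliques."""
    nodes = sorted(g.nodes)
    best, best_key = None, None
    for mask in range(1, 2 ** (len(nodes) - 1)):
        part_a = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        part_b = set(nodes) - part_a
        if not part_a or not part_b:
            continue
        dens = []
        for part in (part_a, part_b):
            n = len(part)
            dens.append(
                1.0 if n == 1
                else 2 * g.subgraph(part).number_of_edges() / (n * (n - 1))
            )
        cut = sum(1 for u, v in g.edges if (u in part_a) != (v in part_a))
        key = (np.mean(dens), -cut)
        if best_key is None or key > best_key:
            best, best_key = (part_a, part_b), key
    return best


def test_two_bridged_cliques_split_into_two_clusters():
    g = nx.Graph()
    for base in (0, 5):
        for a, b in combinations(range(base, base + 5), 2):
            g.add_edge(a, b, similarity=1.0)
    g.add_edge(0, 5, similarity=1.0)  # the bridge
    clusters = cluster_graph(MotifGraph(g), seed=0)
    assert sorted(sorted(c) for c in clusters) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
    # agrees with the exhaustive density-optimal bipartition
    oracle = _density_partition_oracle(g)
    assert {frozenset(c) for c in clusters} == {frozenset(p) for p in oracle}


def test_single_clique_is_one_cluster():
    g = nx.Graph()
    for a, b in combinations(range(5), 2):
        g.add_edge(a, b, similarity=1.0)
    assert cluster_graph(MotifGraph(g), seed=0) == [set(range(5))]


def test_isolated_node_is_singleton():
    g = nx.Graph()
    g.add_node("solo")
    g.add_edge("a", "b", similarity=0.9)
    clusters = cluster_graph(MotifGraph(g), seed=0)
    assert {"solo"} in clusters


def test_cluster_output_is_partition(tiny_fixture):
    rng = np.random.default_rng(2)
    g = nx.Graph()
    g.add_nodes_from(range(30))
    for a, b in combinations(range(30), 2):
        if rng.random() < 0.15:
            g.add_edge(a, b, similarity=float(rng.uniform(0.8, 1.0)))
    clusters = cluster_graph(MotifGraph(g), seed=1)
    flat = [n for c in clusters for n in c]
    assert sorted(flat) == sorted(g.nodes)
    assert len(flat) == len(set(flat))


def _motif_with_sites(mid, dataset, consensus, peak_positions, p=0.9):
    """Motif whose counts match `p`-sharp draws and whose sites live on the
    peaks given as {peak_id: window_start}."""
    w = len(consensus)
    counts = sharp_pwm(consensus, p).probabilities * len(peak_positions) * 10
    sites = [MotifSite(pid, 25, "+", consensus) for pid in peak_positions]
    return Motif(mid, dataset, counts, sites)


def test_derive_um_from_copies_preserves_pwm():
    locator = {("d1", f"p{i}"): ("chr1", 1000 * i) for i in range(8)}
    peaks = [f"p{i}" for i in range(8)]
    m1 = _motif_with_sites("m1", "d1", "ACGTTGCATC", peaks)
    m2 = _motif_with_sites("m2", "d1", "ACGTTGCATC", peaks)
    um = derive_um({"m1", "m2"}, {"m1": m1, "m2": m2}, locator, min_sites=2)
    assert um.viable
    np.testing.assert_allclose(
        um.model.probabilities, m1.model().probabilities, atol=0.02
    )
    # identical genomic coordinates deduplicate: 8 distinct sites, not 16
    assert um.n_sites == 8


def test_derive_um_flags_insufficient_sites():
    locator = {("d1", "p0"): ("chr1", 0)}
    m = _motif_with_sites("m1", "d1", "ACGTTGCATC", ["p0"])
    um = derive_um({"m1"}, {"m1": m}, locator, min_sites=5)
    assert not um.viable
    assert "min_sites" in um.drop_reason


def test_derive_um_recovers_planted_family():
    """Three jittered dataset motifs of one planted consensus collapse to a
    UM with that consensus."""
    rng = np.random.default_rng(4)
    consensus = "GATTACAGTC"
    motifs = {}
    locator = {}
    for d in range(3):
        peaks = {}
        counts = np.zeros((4, 10))
        sites = []
        mat = sharp_pwm(consensus, 0.85).probabilities
        for i in range(20):
            pid = f"d{d}p{i}"
            locator[(f"d{d}", pid)] = ("chr1", 10_000 * (20 * d + i))
            draw = [int(rng.choice(4, p=mat[:, j])) for j in range(10)]
            for j, c in enumerate(draw):
                counts[c, j] += 1
            sites.append(MotifSite(pid, 25, "+", "".join("ACGT"[c] for c in draw)))
        motifs[f"m{d}"] = Motif(f"m{d}", f"d{d}", counts, sites)
    um = derive_um(set(motifs), motifs, locator, min_sites=5)
    assert um.viable
    assert um.model.consensus == consensus
    assert um.n_sites == 60
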