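"""Cross-dataset motif clustering and unique-motif (UM) derivation.

Motifs surviving CP selection across all datasets are clustered by PWM
similarity: a graph is built with an edge wherever similarity strictly
exceeds a cutoff (default 0.8), the graph is cut into dense subgraphs, and
each cluster is collapsed to one representative unique motif whose site
list pools the (deduplicated) genomic sites of all members.

The column similarity is the total-variation complement
``1 - 1/2 * sum_b |p_a(b) - p_b(b)|``, maximized over all ungapped offsets
and over reverse-complement orientation, averaged over aligned columns
(minimum overlap 6 columns). An externally computed similarity matrix can
be substituted via :func:`build_motif_graph`'s ``similarity`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, NamedTuple

import networkx as nx
import numpy as np

from .motifs import Motif, PWMModel

logger = logging.getLogger(__name__)

MIN_OVERLAP = 6


def _tv_column_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column 1 - TV distance for two aligned (4, k) probability blocks."""
    return 1.0 - 0.5 * np.abs(a - b).sum(axis=0)


def _best_alignment(pa: np.ndarray, pb: np.ndarray):
    """Best (score, offset, flipped) of pb against pa over ungapped offsets.

    Offset t aligns pb column j with pa column j + t. Overhanging columns
    are excluded; alignments with fewer than MIN_OVERLAP columns score 0.
    """
    wa, wb = pa.shape[1], pb.shape[1]
    best = (0.0, 0, False)
    for flipped in (False, True):
        q = pb[::-1, ::-1] if flipped else pb
        for t in range(-(wb - 1), wa):
            lo, hi = max(0, t), min(wa, wb + t)
            if hi - lo < MIN_OVERLAP:
                continue
            sim = _tv_column_similarity(pa[:, lo:hi], q[:, lo - t:hi - t]).mean()
            if sim > best[0]:
                best = (float(sim), t, flipped)
    return best


def motif_similarity(ma: PWMModel, mb: PWMModel) -> float:
    """Maximum mean aligned-column similarity over offsets and orientation."""
    return _best_alignment(ma.probabilities, mb.probabilities)[0]


@dataclass
class MotifGraph:
    graph: nx.Graph

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [(u, v, d["similarity"]) for u, v, d in self.graph.edges(data=True)]


def build_motif_graph(
    models: dict[str, PWMModel],
    edge_cutoff: float = 0.8,
    similarity: Callable[[PWMModel, PWMModel], float] = motif_similarity,
) -> MotifGraph:
    """Undirected graph over motif ids; edge iff similarity strictly > cutoff."""
    g = nx.Graph()
    g.add_nodes_from(models)
    for a, b in combinations(models, 2):
        s = similarity(models[a], models[b])
        if s > edge_cutoff:
            g.add_edge(a, b, similarity=s)
    return MotifGraph(g)


def _partition_density_ok(g: nx.Graph, clusters: list[set]) -> bool:
    """Mean intra-cluster edge density >= density of the cut edge set."""
    intra = []
    label = {}
    for ci, cl in enumerate(clusters):
        for n in cl:
            label[n] = ci
        n_c = len(cl)
        if n_c == 1:
            intra.append(1.0)
            continue
        m_c = g.subgraph(cl).number_of_edges()
        intra.append(2.0 * m_c / (n_c * (n_c - 1)))
    cut = sum(1 for u, v in g.edges if label[u] != label[v])
    n = g.number_of_nodes()
    inter_pairs = n * (n - 1) // 2 - sum(len(c) * (len(c) - 1) // 2 for c in clusters)
    cut_density = cut / inter_pairs if inter_pairs else 0.0
    return float(np.mean(intra)) >= cut_density if intra else True


def cluster_graph(mg: MotifGraph, seed: int = 0) -> list[set]:
    """Partition the motif graph into dense connected subgraphs.

    Greedy modularity communities are computed per connected component and
    split into connected parts; if the resulting partition fails the density
    acceptance test (mean intra-cluster density >= cut-edge density), the
    plain connected components are used instead (zero cut edges). The
    ``seed`` is part of the determinism contract; the procedure itself is
    deterministic. Clusters are returned in a stable sorted order.
    """
    g = mg.graph
    clusters: list[set] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() <= 2 or sub.number_of_edges() == 0:
            clusters.append(set(comp))
            continue
        comms = nx.community.greedy_modularity_communities(sub, weight="similarity")
        parts = []
        for comm in comms:
            for piece in nx.connected_components(g.subgraph(comm)):
                parts.append(set(piece))
        if _partition_density_ok(sub, parts):
            clusters.extend(parts)
        else:
            clusters.append(set(comp))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


class GenomicMotifSite(NamedTuple):
    dataset_id: str
    peak_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class UniqueMotif:
    """Representative motif of one cluster with pooled genomic sites."""

    um_id: str
    member_motifs: list[str]
    model: PWMModel
    sites: list[GenomicMotifSite] = field(default_factory=list)
    drop_reason: str | None = None  # set instead of silently dropping the UM

    @property
    def viable(self) -> bool:
        return self.drop_reason is None

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def derive_um(
    cluster: set[str],
    motifs_by_id: dict[str, Motif],
    peak_locator: dict[tuple[str, str], tuple[str, int]],
    um_id: str = "UM0",
    min_sites: int = 2,
    pseudocount: float = 0.5,
    background=None,
) -> UniqueMotif:
    """Collapse one cluster to a unique motif.

    The representative frame is the member with the modal width and the most
    sites; every other member is aligned to it at its similarity-maximizing
    offset/orientation and its count matrix and genomic sites are mapped
    into that frame. Sites are deduplicated on (chrom, start, end, strand).
    ``peak_locator`` maps (dataset_id, peak_id) to the (chrom, window_start)
    of the sequence the member sites were found in.
    """
    members = sorted(cluster)
    widths = [motifs_by_id[m].width for m in members]
    modal_w = max(set(widths), key=lambda w: (widths.count(w), w))
    rep_id = max(
        (m for m in members if motifs_by_id[m].width == modal_w),
        key=lambda m: (motifs_by_id[m].n_sites, m),
    )
    rep = motifs_by_id[rep_id]
    rep_model = rep.model(pseudocount=pseudocount, background=background)
    wa = rep.width

    counts = np.zeros((4, wa))
    seen: set[tuple[str, int, int, str]] = set()
    sites: list[GenomicMotifSite] = []
    for mid in members:
        m = motifs_by_id[mid]
        wb = m.width
        if mid == rep_id:
            t, flipped = 0, False
        else:
            _, t, flipped = _best_alignment(
                rep_model.probabilities,
                m.model(pseudocount=pseudocount, background=background).probabilities,
            )
        block = m.counts[::-1, ::-1] if flipped else m.counts
        lo, hi = max(0, t), min(wa, wb + t)
        if hi > lo:
            counts[:, lo:hi] += block[:, lo - t:hi - t]
        for s in m.sites:
            key = (m.dataset_id, s.peak_id)
            if key not in peak_locator:
                continue
            chrom, win_start = peak_locator[key]
            gstart = win_start + s.offset
            strand = s.strand
            if flipped:
                strand = "-" if strand == "+" else "+"
            if strand == "+":
                a, b = gstart - t, gstart - t + wa
            else:
                a, b = gstart + wb + t - wa, gstart + wb + t
            if a < 0:
                continue
            dkey = (chrom, a, b, strand)
            if dkey in seen:
                continue
            seen.add(dkey)
            sites.append(GenomicMotifSite(m.dataset_id, s.peak_id, chrom, a, b, strand))

    model = PWMModel.from_counts(counts, pseudocount=pseudocount, background=background)
    drop = None
    if len(sites) < min_sites:
        drop = f"pooled sites {len(sites)} < min_sites {min_sites}"
        logger.info("cluster %s yields no UM: %s", um_id, drop)
    return UniqueMotif(um_id=um_id, member_motifs=members, model=model,
                       sites=sites, drop_reason=drop)
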