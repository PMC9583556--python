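"""Fully connected UM interaction network and its weight-shuffled null.

The edge weight between unique motifs U_i and U_j averages, over the
datasets D(U_i, U_j) containing sites of both, a term that rewards pairs
sharing many peaks and sitting close together:

    S_INTER(U_i, U_j) = 1/|D| * sum_d (1/|d(U_i)| + 1/|d(U_j)|)
                                * sum_{s in S} 150 / r(s)

with |d(U_k)| the number of peaks of dataset d containing a U_k site, S the
peaks of d containing sites of both, and r(s) the shortest edge-to-edge
distance in bp between any U_i site and any U_j site in peak s. The 150 bp
constant is roughly a nucleosome length, so 150/r rewards nucleosome-scale
spacing. r is floored at 1 bp (overlapping or abutting sites), bounding
each peak's contribution at 150.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import UniqueMotif

DISTANCE_SCALE = 150.0


@dataclass
class InteractionNetwork:
    um_ids: list[str]
    weights: np.ndarray  # symmetric, diagonal 0, all >= 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self._index = {u: i for i, u in enumerate(self.um_ids)}

    def weight(self, ui: str, uj: str) -> float:
        return float(self.weights[self._index[ui], self._index[uj]])

    def index_of(self, um_id: str) -> int:
        return self._index[um_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.um_ids, columns=self.um_ids)

    def to_edge_tsv(self, path) -> None:
        rows = []
        n = len(self.um_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.um_ids[i], self.um_ids[j], self.weights[i, j]))
        pd.DataFrame(rows, columns=["um_i", "um_j", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_edge_tsv(cls, path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df.um_i) | set(df.um_j))
        idx = {u: i for i, u in enumerate(ids)}
        w = np.zeros((len(ids), len(ids)))
        for r in df.itertuples():
            w[idx[r.um_i], idx[r.um_j]] = w[idx[r.um_j], idx[r.um_i]] = r.weight
        return cls(ids, w)


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge distance between two half-open intervals (0 if touching)."""
    if a[0] < b[0]:
        return max(b[0] - a[1], 0)
    return max(a[0] - b[1], 0)


def interaction_score(ui: UniqueMotif, uj: UniqueMotif) -> float:
    """S_INTER between two UMs from their annotated site lists.

    Returns 0 (not an error) when no dataset contains sites of both.
    """
    by_ds_i: dict[str, dict[str, list[tuple[int, int]]]] = {}
    by_ds_j: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for um, acc in ((ui, by_ds_i), (uj, by_ds_j)):
        for s in um.sites:
            acc.setdefault(s.dataset_id, {}).setdefault(s.peak_id, []).append(
                (s.start, s.end)
            )
    shared_ds = set(by_ds_i) & set(by_ds_j)
    if not shared_ds:
        return 0.0
    total = 0.0
    for d in shared_ds:
        peaks_i, peaks_j = by_ds_i[d], by_ds_j[d]
        inner = 0.0
        for s in set(peaks_i) & set(peaks_j):
            r = min(_gap(a, b) for a in peaks_i[s] for b in peaks_j[s])
            inner += DISTANCE_SCALE / max(r, 1)
        total += (1.0 / len(peaks_i) + 1.0 / len(peaks_j)) * inner
    # |D| counts every dataset containing sites of both UMs, even when the
    # two never share a peak there (that dataset contributes 0).
    return total / len(shared_ds)


def build_network(ums: list[UniqueMotif]) -> InteractionNetwork:
    ums = [u for u in ums if u.viable]
    n = len(ums)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = interaction_score(ums[i], ums[j])
    return InteractionNetwork([u.um_id for u in ums], w)


def shuffle_weights(net: InteractionNetwork, seed: int) -> InteractionNetwork:
    """Random permutation of the off-diagonal upper-triangle weight multiset."""
    rng = np.random.default_rng(seed)
    n = len(net.um_ids)
    iu = np.triu_indices(n, k=1)
    vals = net.weights[iu].copy()
    rng.shuffle(vals)
    w = np.zeros((n, n))
    w[iu] = vals
    w = w + w.T
    return InteractionNetwork(list(net.um_ids), w)
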