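"""Pairwise overlap of extended peak sets between datasets.

Cooperative TFs that are reused across cell types produce ChIP-seq datasets
whose 1,000-bp peak windows overlap heavily. The symmetric overlap score

    S_o(d_i, d_j) = 1/2 * ( o / |d_i| + o / |d_j| )

with ``o`` the overlap count between the two window sets and ``|d|`` the
window count, quantifies this and is used as a QC view of the
cooperative-TF structure of a collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals

__all__ = ["overlap_score", "overlap_matrix", "OverlapMatrix"]


def _overlap_count(wa, wb, mode: str) -> float:
    """Overlap numerator o(d_i + d_j) between two per-chrom window dicts.

    mode="pairs": number of intersecting window pairs (capped by the caller).
    mode="bp": total intersecting base pairs (callers divide by bp sizes).
    """
    total = 0
    for chrom in set(wa) & set(wb):
        if mode == "pairs":
            total += intervals.count_overlapping_pairs(wa[chrom], wb[chrom])
        else:
            total += intervals.intersection_length(wa[chrom], wb[chrom])
    return total


def overlap_score(wa: dict, wb: dict, mode: str = "pairs") -> float:
    """S_o between two extended-window dicts (chrom -> (n,2) intervals).

    With ``mode="pairs"`` (default) ``o`` is the count of intersecting
    window pairs capped at min(|d_i|, |d_j|) so the score stays in [0, 1];
    with ``mode="bp"`` the numerator and sizes are base-pair counts
    (union bp of each set, shared bp as numerator).
    """
    na = sum(len(v) for v in wa.values())
    nb = sum(len(v) for v in wb.values())
    if na == 0 or nb == 0:
        raise ValueError("overlap_score undefined for an empty dataset")
    if mode == "pairs":
        o = min(_overlap_count(wa, wb, "pairs"), min(na, nb))
        return 0.5 * (o / na + o / nb)
    if mode == "bp":
        o = _overlap_count(wa, wb, "bp")
        la = sum(intervals.union_length(v) for v in wa.values())
        lb = sum(intervals.union_length(v) for v in wb.values())
        return 0.5 * (o / la + o / lb)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class OverlapMatrix:
    dataset_ids: list[str]
    values: np.ndarray  # symmetric, [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dataset_ids, columns=self.dataset_ids)

    def to_tsv(self, path, *, cluster: bool = False) -> None:
        """Write the matrix; optionally order rows by average-linkage
        hierarchical clustering on 1 - S_o (QC convenience only)."""
        frame = self.to_frame()
        if cluster and len(self.dataset_ids) > 2:
            from scipy.cluster.hierarchy import average, leaves_list
            from scipy.spatial.distance import squareform

            d = 1.0 - self.values
            np.fill_diagonal(d, 0.0)
            order = leaves_list(average(squareform(d, checks=False)))
            frame = frame.iloc[order, order]
        frame.to_csv(path, sep="\t")


def overlap_matrix(window_sets: dict[str, dict], mode: str = "pairs") -> OverlapMatrix:
    """All pairwise S_o scores over a {dataset_id: windows} mapping."""
    ids = list(window_sets)
    if len(ids) < 2:
        raise ValueError("need at least two datasets")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        m[i, i] = 1.0
        for j in range(i + 1, n):
            s = overlap_score(window_sets[ids[i]], window_sets[ids[j]], mode=mode)
            m[i, j] = m[j, i] = s
    return OverlapMatrix(dataset_ids=ids, values=m)
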