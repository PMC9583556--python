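"""Within-dataset motif co-occurrence and selection of co-occurring pairs.

Motifs of cooperative TFs tend to appear in the same binding peaks. The
co-occurrence score of two motifs found in the same dataset is

    Sc(M_i, M_j) = o(M_i, M_j) / max(|M_i|, |M_j|)

where |M| is the number of distinct peaks containing at least one site of
the motif and o the number of distinct peaks containing sites of both.
Pairs with Sc strictly above the cutoff (0.7 by default, the high mode of
the empirically trimodal Sc distribution) are kept as co-occurring pairs
(CPs); motifs in no CP, and datasets retaining no CP, are discarded from
all downstream stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .motifs import Motif

logger = logging.getLogger(__name__)

__all__ = ["CooccurringPair", "cooccurrence_score", "select_cps", "sc_histogram"]


@dataclass(frozen=True)
class CooccurringPair:
    dataset_id: str
    motif_i: str
    motif_j: str
    sc: float

    def __post_init__(self):
        if self.motif_i == self.motif_j:
            raise ValueError("a motif cannot co-occur with itself")
        if not 0.0 <= self.sc <= 1.0:
            raise ValueError("Sc must lie in [0, 1]")


def cooccurrence_score(mi: Motif, mj: Motif) -> float:
    """Sc between two motifs of the same dataset (distinct-peak counting)."""
    pi, pj = mi.peak_ids, mj.peak_ids
    if not pi or not pj:
        raise ValueError("co-occurrence undefined for a motif with zero peaks")
    o = len(pi & pj)
    return o / max(len(pi), len(pj))


def select_cps(motifs: list[Motif], cutoff: float = 0.7) -> list[CooccurringPair]:
    """All unordered motif pairs of one dataset with Sc strictly > cutoff.

    Returns an empty list when no pair passes — the caller then drops the
    dataset from downstream stages.
    """
    cps = []
    for mi, mj in combinations(motifs, 2):
        sc = cooccurrence_score(mi, mj)
        if sc > cutoff:
            a, b = sorted((mi.motif_id, mj.motif_id))
            cps.append(CooccurringPair(mi.dataset_id, a, b, sc))
    if not cps and motifs:
        logger.info("dataset %s: no CP above Sc > %s, dataset dropped",
                    motifs[0].dataset_id, cutoff)
    return cps


def sc_histogram(motifs: list[Motif], bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all pairwise Sc values (inspection of the trimodal shape)."""
    scores = [cooccurrence_score(a, b) for a, b in combinations(motifs, 2)]
    return np.histogram(np.asarray(scores), bins=bins, range=(0.0, 1.0))
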