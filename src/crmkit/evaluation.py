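"""Validation machinery for predicted CRMs.

Covers the standard yardsticks used to judge CRM maps against reference
element sets (enhancer databases, promoter atlases, QTL catalogues):

* recall under the 50%-of-shorter rule (a reference element is recalled if
  a predicted element overlaps it by at least half the shorter length);
* matched random controls (same count and exact length multiset, placed
  uniformly in a universe) and the analytic chance expectation of their
  recall;
* proportion of selective neutrality of a position set: the fraction of
  positions whose conservation score lies in [-delta, +delta] (delta = 1);
* exact shared/specific base-pair decomposition of two element sets;
* length ratios of recalling vs recalled elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals

Interval = tuple[str, int, int]


@dataclass
class ElementSet:
    label: str
    intervals: dict[str, np.ndarray]  # chrom -> sorted (n, 2)

    def __post_init__(self):
        self.intervals = {c: intervals.as_array(v) for c, v in self.intervals.items()}

    @classmethod
    def from_tuples(cls, label: str, elements) -> "ElementSet":
        per: dict[str, list] = {}
        for chrom, s, e in elements:
            per.setdefault(chrom, []).append((s, e))
        return cls(label, {c: np.asarray(v) for c, v in per.items()})

    @classmethod
    def from_bed(cls, label: str, path) -> "ElementSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        per = {c: g[["start", "end"]].to_numpy() for c, g in df.groupby("chrom")}
        return cls(label, per)

    def elements(self) -> list[Interval]:
        return [(c, int(s), int(e))
                for c in sorted(self.intervals)
                for s, e in self.intervals[c]]

    def total_bp(self) -> int:
        return sum(intervals.union_length(v) for v in self.intervals.values())

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())


@dataclass
class RecallResult:
    sensitivity: float
    flags: dict[Interval, bool]
    #: recalled reference -> the recalling predicted element with the
    #: longest overlap (ties broken by coordinate)
    mapping: dict[Interval, Interval]


def recall(predicted: ElementSet, reference: ElementSet) -> RecallResult:
    """Recall of reference elements under the inclusive 50%-of-shorter rule."""
    flags: dict[Interval, bool] = {}
    mapping: dict[Interval, Interval] = {}
    for chrom in sorted(reference.intervals):
        refs = reference.intervals[chrom]
        preds = predicted.intervals.get(chrom, np.empty((0, 2), np.int64))
        pstarts = preds[:, 0] if len(preds) else np.empty(0, np.int64)
        pends = preds[:, 1] if len(preds) else np.empty(0, np.int64)
        for rs, re_ in refs:
            key = (chrom, int(rs), int(re_))
            best_ov, best_pred = 0, None
            if len(preds):
                # candidates: preds with start < re_ and end > rs
                cand = np.nonzero((pstarts < re_) & (pends > rs))[0]
                for i in cand:
                    ps, pe = int(pstarts[i]), int(pends[i])
                    ov = min(pe, re_) - max(ps, rs)
                    shorter = min(pe - ps, re_ - rs)
                    if 2 * ov >= shorter and (
                        ov > best_ov or (ov == best_ov and best_pred is None)
                    ):
                        best_ov, best_pred = ov, (chrom, ps, pe)
            flags[key] = best_pred is not None
            if best_pred is not None:
                mapping[key] = best_pred
    n = len(flags)
    sens = sum(flags.values()) / n if n else float("nan")
    return RecallResult(sensitivity=sens, flags=flags, mapping=mapping)


def matched_controls(
    predicted: ElementSet,
    universe: dict[str, np.ndarray],
    seed: int,
    max_tries: int = 1000,
) -> ElementSet:
    """Random elements with the exact length multiset of ``predicted``,
    placed uniformly within ``universe`` without self-overlap.

    Deterministic given seed. Raises if a length cannot be placed after
    ``max_tries`` attempts.
    """
    rng = np.random.default_rng(seed)
    segments = []  # (chrom, start, end)
    for chrom in sorted(universe):
        for s, e in intervals.merge(universe[chrom]):
            segments.append((chrom, int(s), int(e)))
    lengths = sorted(
        (int(e - s) for v in predicted.intervals.values() for s, e in v),
        reverse=True,
    )
    placed: dict[str, list[tuple[int, int]]] = {}
    for L in lengths:
        sizes = np.array([max(0, e - s - L + 1) for _, s, e in segments], float)
        if sizes.sum() == 0:
            raise ValueError(f"universe cannot host an element of length {L}")
        probs = sizes / sizes.sum()
        ok = False
        for _ in range(max_tries):
            si = rng.choice(len(segments), p=probs)
            chrom, s0, e0 = segments[si]
            x = int(rng.integers(s0, e0 - L + 1))
            clash = placed.get(chrom) and intervals.count_overlapping_pairs(
                [(x, x + L)], placed[chrom]
            )
            if not clash:
                placed.setdefault(chrom, []).append((x, x + L))
                ok = True
                break
        if not ok:
            raise ValueError(f"could not place control of length {L} "
                             f"after {max_tries} tries")
    return ElementSet(
        f"{predicted.label}_control",
        {c: np.asarray(v) for c, v in placed.items()},
    )


def chance_recall_expectation(
    predicted: ElementSet, reference: ElementSet, universe_bp: int
) -> float:
    """Analytic expected recall of uniformly placed length-matched controls.

    For a control of length L and a reference of length R, the number of
    start offsets satisfying the 50%-of-shorter rule is
    L + R - 2*ceil(min(L, R)/2) + 1; under uniform placement each control
    hits with probability that count over the universe size.
    """
    pred_lengths = [int(e - s) for v in predicted.intervals.values() for s, e in v]
    probs = []
    for _, rs, re_ in reference.elements():
        r = re_ - rs
        log_miss = 0.0
        for L in pred_lengths:
            m = -(-min(L, r) // 2)  # ceil
            a = max(0, L + r - 2 * m + 1)
            log_miss += np.log1p(-min(a / universe_bp, 1.0 - 1e-12))
        probs.append(1.0 - np.exp(log_miss))
    return float(np.mean(probs)) if probs else float("nan")


@dataclass
class NeutralityProfile:
    """Per-base conservation scores (bedGraph semantics) with neutral band
    half-width ``delta`` (default 1 score unit)."""

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # starts, ends, scores
    delta: float = 1.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @classmethod
    def from_bigwig(cls, path, delta: float = 1.0) -> "NeutralityProfile":
        """Adapter for bigWig score tracks (requires pyBigWig)."""
        import pyBigWig

        bw = pyBigWig.open(str(path))
        runs = {}
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom) or []
            if not ivs:
                continue
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            scores = np.array([i[2] for i in ivs], dtype=float)
            runs[chrom] = (starts, ends, scores)
        bw.close()
        return cls(runs, delta=delta)

    @classmethod
    def from_bedgraph(cls, path, delta: float = 1.0) -> "NeutralityProfile":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "score"])
        runs = {}
        for chrom, g in df.groupby("chrom"):
            order = np.argsort(g["start"].to_numpy())
            runs[str(chrom)] = (
                g["start"].to_numpy()[order],
                g["end"].to_numpy()[order],
                g["score"].to_numpy(float)[order],
            )
        return cls(runs, delta=delta)

    def scores_over(self, element_intervals: dict[str, np.ndarray]):
        """Per-position scores over an interval set.

        Returns (scores array over scored positions, missing position
        count). Missing positions are excluded, never imputed.
        """
        chunks = []
        missing = 0
        for chrom, ivs in element_intervals.items():
            merged = intervals.merge(ivs)
            if chrom not in self.runs:
                missing += int(np.sum(merged[:, 1] - merged[:, 0])) if len(merged) else 0
                continue
            starts, ends, scores = self.runs[chrom]
            track = np.column_stack([starts, ends])
            for s, e in merged:
                overlapped = 0
                i0 = np.searchsorted(ends, s, side="right")
                i1 = np.searchsorted(starts, e, side="left")
                for i in range(i0, i1):
                    lo, hi = max(int(starts[i]), int(s)), min(int(ends[i]), int(e))
                    if hi > lo:
                        chunks.append(np.full(hi - lo, scores[i]))
                        overlapped += hi - lo
                missing += (e - s) - overlapped
        out = np.concatenate(chunks) if chunks else np.empty(0)
        return out, int(missing)


def proportion_of_neutrality(
    element_intervals: dict[str, np.ndarray],
    profile: NeutralityProfile,
    min_scored: float = 0.99,
    method: str = "count",
) -> float:
    """Fraction of scored positions with score in [-delta, +delta].

    Requires scores for at least ``min_scored`` of the queried positions.
    ``method="count"`` counts positions directly; ``method="integrate"``
    integrates the empirical score density over the neutral band (the two
    agree exactly up to float representation of the band edges).
    """
    scores, missing = profile.scores_over(element_intervals)
    total = len(scores) + missing
    if len(scores) == 0:
        raise ValueError("no scored positions in the queried intervals")
    if total and len(scores) / total < min_scored:
        raise ValueError(
            f"only {len(scores)}/{total} positions have scores "
            f"(< {min_scored:.0%} required)"
        )
    d = profile.delta
    if method == "count":
        return float(np.mean((scores >= -d) & (scores <= d)))
    if method == "integrate":
        lo = min(scores.min(), -d) - 1.0
        hi = max(scores.max(), d) + 1.0
        edges = np.array([lo, -d, np.nextafter(d, np.inf), hi])
        density, _ = np.histogram(scores, bins=edges, density=True)
        widths = np.diff(edges)
        return float(density[1] * widths[1])
    raise ValueError(f"unknown method {method!r}")


def decompose_positions(set_a: ElementSet, set_b: ElementSet):
    """(shared bp, A-specific bp, B-specific bp) by exact interval arithmetic."""
    shared = a_spec = b_spec = 0
    for chrom in set(set_a.intervals) | set(set_b.intervals):
        a = set_a.intervals.get(chrom, np.empty((0, 2), np.int64))
        b = set_b.intervals.get(chrom, np.empty((0, 2), np.int64))
        s = intervals.intersection_length(a, b)
        shared += s
        a_spec += intervals.union_length(a) - s
        b_spec += intervals.union_length(b) - s
    return shared, a_spec, b_spec


def length_ratio_stats(mapping: dict[Interval, Interval]) -> pd.Series:
    """Length ratio recalling/recalled per pair; summary quantiles."""
    if not mapping:
        return pd.Series(dtype=float)
    ratios = np.array([
        (p[2] - p[1]) / (r[2] - r[1]) for r, p in mapping.items()
    ])
    return pd.Series({
        "n": len(ratios),
        "mean": ratios.mean(),
        "median": float(np.median(ratios)),
        "q25": float(np.quantile(ratios, 0.25)),
        "q75": float(np.quantile(ratios, 0.75)),
        "min": ratios.min(),
        "max": ratios.max(),
    })
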