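"""Null calibration of CRMC scores.

The empirical null is built by sampling, from a 3rd-order Markov chain
fitted to the CRMC sequences themselves, one random sequence per CRMC with
exactly the CRMC's length (matched lengths and nucleotide frequencies).
Each null sequence is re-scanned with the UM PWMs, positively scoring sites
are linked with the same 300-bp rule, and the best linked run is scored
with the CRM score under a weight-shuffled interaction network. The
empirical p-value of a CRMC scoring s is

    p = n(s) / M

with n(s) the number of null scores strictly above s and M the (matched)
number of CRMCs. Expected true/false positive counts per score bin follow
from the two score densities: FP(b) = null count in b,
TP(b) = max(0, CRMC count - null count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import PWMModel, encode, score_positions
from .network import InteractionNetwork

ORDER = 3


@dataclass
class MarkovModel:
    """Fixed-order Markov chain over ACGT (order 3 by default)."""

    order: int
    initial: np.ndarray  # distribution over 4^order context codes
    transitions: np.ndarray  # (4^order, 4) conditional distributions

    def __post_init__(self):
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each conditional distribution must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


def fit_markov(sequences: list[str], order: int = ORDER, pseudocount: float = 1.0) -> MarkovModel:
    """Add-pseudocount estimation of transition and initial distributions.

    Sequences shorter than order+1 are skipped. Requires enough training
    sequence for the context table (> 4^(order+1) bases in total).
    """
    n_ctx = 4 ** order
    trans = np.zeros((n_ctx, 4))
    init = np.zeros(n_ctx)
    total = 0
    for seq in sequences:
        codes = encode(seq)
        codes = codes[codes < 4]  # ambiguous bases break contexts; drop them
        if len(codes) < order + 1:
            continue
        total += len(codes)
        ctx = np.zeros(len(codes) - order, dtype=np.int64)
        for i in range(order):
            ctx = ctx * 4 + codes[i:len(codes) - order + i]
        init[ctx[0]] += 1
        np.add.at(trans, (ctx, codes[order:]), 1)
    if total <= 4 ** (order + 1):
        raise ValueError(
            f"need more than 4^{order + 1} training bases, got {total}"
        )
    trans += pseudocount
    init += pseudocount / n_ctx
    return MarkovModel(
        order=order,
        initial=init / init.sum(),
        transitions=trans / trans.sum(axis=1, keepdims=True),
    )


def sample_sequences(model: MarkovModel, lengths: list[int], seed: int) -> list[str]:
    """One random sequence per requested length, exactly those lengths.

    Deterministic given seed. Sampling is vectorized across sequences.
    """
    rng = np.random.default_rng(seed)
    lengths = [int(x) for x in lengths]
    n = len(lengths)
    if n == 0:
        return []
    max_len = max(lengths)
    order = model.order
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transitions, axis=1)
    state = np.searchsorted(cum_init, rng.random(n), side="right")
    out = np.full((n, max_len), 4, dtype=np.int8)
    # unpack the initial context codes into the first `order` bases
    for i in range(order - 1, -1, -1):
        out[:, i] = state % 4
        state //= 4
    # restore: state was consumed; recompute context codes
    ctx = np.zeros(n, dtype=np.int64)
    for i in range(order):
        ctx = ctx * 4 + out[:, i]
    for pos in range(order, max_len):
        r = rng.random(n)
        nxt = (cum_trans[ctx] < r[:, None]).sum(axis=1).astype(np.int64)
        nxt = np.minimum(nxt, 3)
        out[:, pos] = nxt
        ctx = (ctx * 4 + nxt) % (4 ** order)
    seqs = []
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, L in enumerate(lengths):
        if L < order:
            seqs.append("".join("ACGT"[c] for c in out[i, :L]))
        else:
            seqs.append(alphabet[out[i, :L]].tobytes().decode())
    return seqs


def _score_run(u_idx: np.ndarray, scores: np.ndarray, weights: np.ndarray) -> float:
    n = len(u_idx)
    if n < 2:
        return 0.0
    sub = weights[np.ix_(u_idx, u_idx)]
    row = sub.sum(axis=1) - np.diag(sub)
    return float(2.0 / (n - 1) * np.dot(scores, row))


def score_null_sequences(
    sequences: list[str],
    models: dict[str, PWMModel],
    net: InteractionNetwork,
    max_gap: int = 300,
    thresholds: dict[str, float] | None = None,
) -> np.ndarray:
    """Scan sequences with the UM PWMs and score the best linked site run.

    Sites are positions (both strands) whose log-odds exceeds the UM's
    entry in ``thresholds`` (0, i.e. any positive score, when absent) —
    pass the same per-PWM thresholds used for real site calls so null
    sequences are scanned by the same rule as the real ones. Runs are
    maximal site groups with inter-site gap <= max_gap; a sequence's null
    score is the S_CRM of its best run under ``net`` (0 for sequences with
    fewer than 2 linked sites).
    """
    out = np.zeros(len(sequences))
    order_ids = list(net.um_ids)
    pwms = [(net.index_of(u), u, models[u], models[u].reverse_complement())
            for u in order_ids if u in models]
    for i, seq in enumerate(sequences):
        codes = encode(seq)
        hits = []  # (start, end, um_index, score)
        for u_idx, u_id, m, rc in pwms:
            w = m.width
            thr = max(0.0, (thresholds or {}).get(u_id, 0.0))
            for mm in (m, rc):
                sc = score_positions(mm, codes)
                for pos in np.nonzero(sc > thr)[0]:
                    hits.append((int(pos), int(pos) + w, u_idx, float(sc[pos])))
        if len(hits) < 2:
            continue
        hits.sort()
        best = 0.0
        run: list[tuple] = []
        run_end = None
        for h in hits:
            if run and h[0] - run_end > max_gap:
                best = max(best, _score_run(
                    np.array([x[2] for x in run]),
                    np.array([x[3] for x in run]), net.weights))
                run = []
                run_end = None
            run.append(h)
            run_end = h[1] if run_end is None else max(run_end, h[1])
        best = max(best, _score_run(
            np.array([x[2] for x in run]),
            np.array([x[3] for x in run]), net.weights))
        out[i] = best
    return out


@dataclass
class ScoreDistributions:
    crmc_scores: np.ndarray
    null_scores: np.ndarray
    bin_width: float = 1.0

    def __post_init__(self):
        self.crmc_scores = np.asarray(self.crmc_scores, float)
        self.null_scores = np.asarray(self.null_scores, float)
        if len(self.crmc_scores) != len(self.null_scores):
            raise ValueError(
                "null set must be matched in number to the CRMC set "
                f"({len(self.null_scores)} vs {len(self.crmc_scores)})"
            )
        self._sorted_null = np.sort(self.null_scores)


def empirical_pvalue(s, dist: ScoreDistributions):
    """p = n(s)/M with n(s) = #{null > s}, M = |CRMCs| (= |null|).

    Vectorized over ``s``. A score above every null score yields p = 0
    (reported as "< 1/M" in textual output).
    """
    m = len(dist._sorted_null)
    if m == 0:
        raise ValueError("null score set is empty")
    n_above = m - np.searchsorted(dist._sorted_null, s, side="right")
    return n_above / m


def format_pvalue(p: float, m: int) -> str:
    return f"< {1.0 / m:.3g}" if p == 0 else f"{p:.3g}"


def estimate_fdr(dist: ScoreDistributions) -> pd.DataFrame:
    """Per-bin and cumulative expected true/false positives.

    Bins of ``dist.bin_width`` score units span both score sets. Cumulative
    columns accumulate from the highest bin downward, matching prediction
    at decreasing score cutoffs; ``fdr`` is cumulative FP over cumulative
    CRMC count (NaN where no CRMC scores exceed the cutoff).
    """
    bw = dist.bin_width
    hi = max(dist.crmc_scores.max(), dist.null_scores.max(), 0.0)
    edges = np.arange(0.0, hi + 2 * bw, bw)
    crmc_n, _ = np.histogram(dist.crmc_scores, bins=edges)
    null_n, _ = np.histogram(dist.null_scores, bins=edges)
    fp = null_n.astype(float)
    tp = np.maximum(crmc_n - null_n, 0).astype(float)
    cum_crmc = crmc_n[::-1].cumsum()[::-1]
    cum_fp = fp[::-1].cumsum()[::-1]
    cum_tp = tp[::-1].cumsum()[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(cum_crmc > 0, cum_fp / cum_crmc, np.nan)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "crmc_count": crmc_n,
        "null_count": null_n,
        "expected_tp": tp,
        "expected_fp": fp,
        "cum_crmc": cum_crmc,
        "cum_expected_tp": cum_tp,
        "cum_expected_fp": cum_fp,
        "fdr": fdr,
    })
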