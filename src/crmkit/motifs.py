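"""PWM models, site scoring, genome scanning and baseline motif discovery.

Motif discovery here is a deterministic, documented baseline behind a
pluggable interface: production pipelines can swap in any external finder
through :func:`read_sites_tsv`, which ingests sites in a simple TSV schema.
The baseline finder:

1. counts all k-mers on both strands of the input windows (over
   deduplicated genomic positions when window coordinates are supplied, so
   overlapping windows do not inflate counts);
2. seeds with k-mers significantly recurrent against an order-0 background
   (Poisson tail, Bonferroni-corrected over the k-mer space — a plain
   z-rule degenerates when expected counts are far below one);
3. estimates the PWM by ZOOPS-style EM: one best-scoring site per window
   above a log-odds threshold, iterated to convergence;
4. keeps a motif only if its count of high-scoring sites significantly
   exceeds the number of windows expected to contain one by chance;
5. reports as sites every occurrence above a threshold calibrated to a
   fixed per-position background hit probability (``site_fpr``).

Scores are log-odds in bits: ``sum_k log2(p_k(base) / background(base))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A,C,G,T -> 0..3; anything else -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PWMModel:
    """Position weight matrix with background and pseudocount provenance."""

    probabilities: np.ndarray  # (4, width), columns sum to 1
    background: np.ndarray  # (4,)
    pseudocount: float = 0.5

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("probabilities must be a 4 x width matrix")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if np.any(p <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "background", np.asarray(self.background, float))

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.5, background=None) -> "PWMModel":
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        p = counts + pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        return cls(probabilities=p, background=np.asarray(background, float),
                   pseudocount=pseudocount)

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(5, width) log2(p/bg); row 4 (ambiguous base) is -inf."""
        lo = np.log2(self.probabilities / self.background[:, None])
        return np.vstack([lo, np.full((1, self.width), -np.inf)])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probabilities, axis=0))

    @property
    def max_score(self) -> float:
        return float(np.sum(np.max(self.log_odds[:4], axis=0)))

    def reverse_complement(self) -> "PWMModel":
        return PWMModel(
            probabilities=self.probabilities[::-1, ::-1],
            background=self.background[::-1],
            pseudocount=self.pseudocount,
        )


def score_site(model: PWMModel, kmer: str) -> float:
    """Log-odds score in bits of one k-mer; ambiguous bases give -inf."""
    codes = encode(kmer)
    if len(codes) != model.width:
        raise ValueError(f"k-mer length {len(codes)} != motif width {model.width}")
    return float(model.log_odds[codes, np.arange(model.width)].sum())


def score_positions(model: PWMModel, codes: np.ndarray) -> np.ndarray:
    """Forward-strand scores at every start position of an encoded sequence."""
    w = model.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = model.log_odds
    out = np.zeros(n)
    for k in range(w):
        out += lo[codes[k:k + n], k]
    return out


def scan_sequence(model: PWMModel, codes: np.ndarray, threshold: float = 0.0):
    """All sites on both strands with score > threshold.

    Returns (offsets, strands, scores); strand '+' means the motif as given,
    '-' means its reverse complement matched the forward sequence (the
    reported offset is still on the forward coordinate system).
    """
    fwd = score_positions(model, codes)
    rev = score_positions(model.reverse_complement(), codes)
    hits = []
    for strand, scores in (("+", fwd), ("-", rev)):
        idx = np.nonzero(scores > threshold)[0]
        for i in idx:
            hits.append((int(i), strand, float(scores[i])))
    hits.sort()
    if not hits:
        return np.empty(0, int), np.empty(0, "U1"), np.empty(0)
    off, st, sc = zip(*hits)
    return np.asarray(off), np.asarray(st), np.asarray(sc)


def _score_distribution(model: PWMModel, bin_width: float = 0.05):
    """Discretized distribution of the PWM score at one random background
    position, by column-wise convolution (the standard PWM p-value DP)."""
    lo = model.log_odds[:4]
    q = np.round(lo / bin_width).astype(int)
    lo_min, lo_max = int(q.min(axis=0).sum()), int(q.max(axis=0).sum())
    dist = np.zeros(lo_max - lo_min + 1)
    offset = -lo_min
    dist[offset] = 1.0  # score 0 before any column
    bg = model.background
    for col in range(model.width):
        new = np.zeros_like(dist)
        for b in range(4):
            shift = q[b, col]
            if shift >= 0:
                new[shift:] += bg[b] * dist[: len(dist) - shift if shift else None]
            else:
                new[:shift] += bg[b] * dist[-shift:]
        dist = new
    scores = (np.arange(len(dist)) - offset) * bin_width
    return scores, dist


def hit_probability(model: PWMModel, threshold: float, bin_width: float = 0.05) -> float:
    """P(score > threshold) for one random position under the background,
    exact up to score discretization."""
    scores, dist = _score_distribution(model, bin_width)
    return float(dist[scores > threshold].sum())


def threshold_for_fpr(model: PWMModel, fpr: float, bin_width: float = 0.05) -> float:
    """Smallest score threshold with background hit probability <= fpr.

    Never below 0: a site must at least beat the background (positive
    log-odds) to be called.
    """
    scores, dist = _score_distribution(model, bin_width)
    tail = dist[::-1].cumsum()[::-1]
    ok = np.nonzero(tail <= fpr)[0]
    if len(ok) == 0:
        return float(scores[-1])
    # tail[i] = P(score >= scores[i]); threshold just below scores[ok[0]]
    return max(0.0, float(scores[ok[0]] - bin_width))


class MotifSite(NamedTuple):
    peak_id: str
    offset: int
    strand: str
    sequence: str


@dataclass
class Motif:
    """A discovered motif: count matrix plus its site occurrences."""

    motif_id: str
    dataset_id: str
    counts: np.ndarray  # (4, width); column sums == number of sites
    sites: list[MotifSite] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def peak_ids(self) -> set[str]:
        return {s.peak_id for s in self.sites}

    def model(self, pseudocount: float = 0.5, background=None) -> PWMModel:
        return PWMModel.from_counts(self.counts, pseudocount=pseudocount,
                                    background=background)


@dataclass(frozen=True)
class DiscoveryParams:
    width: int = 10  # modal length of mammalian TF core motifs
    z_min: float = 4.0
    seed_alpha: float = 0.05  # Bonferroni-corrected Poisson tail for seeds
    site_threshold_frac: float = 0.45  # ZOOPS estimation, fraction of max score
    test_threshold_frac: float = 0.65  # null significance test threshold
    site_fpr: float = 1e-4  # background hit probability for final site calls
    min_sites: int = 10
    min_peaks: int = 20
    max_motifs: int = 10
    max_seeds: int = 200
    max_seed_trials: int = 40  # EM attempts per dataset (runtime bound)
    max_iter: int = 50
    tol: float = 1e-4
    pseudocount: float = 0.5


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (positions containing N are dropped)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    for i in range(k):
        window = codes[i:i + n]
        valid &= window < 4
        vals = vals * 4 + np.where(window < 4, window, 0)
    return vals[valid]


def _kmer_codes_masked(codes: np.ndarray, k: int, keep: np.ndarray) -> np.ndarray:
    """k-mer codes at the start positions flagged by ``keep`` (N-free only)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = keep[:n].copy()
    vals = np.zeros(n, dtype=np.int64)
    for i in range(k):
        window = codes[i:i + n]
        valid &= window < 4
        vals = vals * 4 + np.where(window < 4, window, 0)
    return vals[valid]


def _kmer_to_string(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _collect_sites(model: PWMModel, encoded: list[np.ndarray], threshold: float):
    """Best site per sequence (ZOOPS) with score > threshold."""
    picks = []  # (seq_index, offset, strand, score)
    rc = model.reverse_complement()
    for i, codes in enumerate(encoded):
        fwd = score_positions(model, codes)
        rev = score_positions(rc, codes)
        if len(fwd) == 0:
            continue
        bf, br = np.argmax(fwd), np.argmax(rev)
        if fwd[bf] >= rev[br]:
            best, strand, off = fwd[bf], "+", int(bf)
        else:
            best, strand, off = rev[br], "-", int(br)
        if best > threshold:
            picks.append((i, off, strand, float(best)))
    return picks


def discover_motifs(
    sequences: list[str],
    peak_ids: list[str] | None = None,
    params: DiscoveryParams = DiscoveryParams(),
    seed: int = 0,
    dataset_id: str = "",
    background=None,
    window_coords: list[tuple[str, int]] | None = None,
) -> list[Motif]:
    """Run the baseline ZOOPS finder on extended peak window sequences.

    When ``window_coords`` gives the (chrom, genomic start) of every
    window, seed k-mers are counted over deduplicated genomic positions, so
    regions repeated across overlapping windows (several peaks covering one
    locus) do not masquerade as recurrent motifs.

    Deterministic given ``seed`` (the seed only breaks ties in seed-k-mer
    ordering). Returns an empty list (with a log message) when the input is
    empty or smaller than ``params.min_peaks`` sequences.
    """
    if peak_ids is None:
        peak_ids = [f"peak{i}" for i in range(len(sequences))]
    if len(sequences) < params.min_peaks:
        logger.info("dataset %s: %d sequences < min_peaks=%d, no motifs",
                    dataset_id, len(sequences), params.min_peaks)
        return []
    k = params.width
    encoded = [encode(s) for s in sequences]
    if background is None:
        all_codes = np.concatenate(encoded)
        counts4 = np.bincount(all_codes[all_codes < 4], minlength=4).astype(float)
        background = (counts4 + 1.0) / (counts4.sum() + 4.0)

    # --- seed k-mers: count on both strands, order-0 expectation z-test ---
    chrom_index: dict[str, int] = {}
    seen_positions: set[int] | None = set() if window_coords is not None else None
    pooled = []
    n_positions = 0
    for si, codes in enumerate(encoded):
        n = max(0, len(codes) - k + 1)
        if n == 0:
            continue
        keep = np.ones(n, dtype=bool)
        if seen_positions is not None:
            chrom, gstart = window_coords[si]
            ci = chrom_index.setdefault(chrom, len(chrom_index))
            gpos = (np.arange(n) + gstart) + ci * (1 << 40)
            keep = np.fromiter(
                (int(p) not in seen_positions for p in gpos), bool, count=n
            )
            seen_positions.update(int(p) for p in gpos[keep])
        rc = (3 - codes[::-1]) % 4
        rc[codes[::-1] >= 4] = 4
        pooled.append(_kmer_codes_masked(codes, k, keep))
        pooled.append(_kmer_codes_masked(rc.astype(np.int8), k, keep[::-1]))
        n_positions += 2 * int(keep.sum())
    pooled = [p for p in pooled if len(p)]
    pooled = np.concatenate(pooled) if pooled else np.empty(0, np.int64)
    uniq, counts = np.unique(pooled, return_counts=True)

    # order-0 expected count of each observed k-mer
    bg_log = np.log(background)
    digits = np.empty((len(uniq), k), dtype=np.int64)
    rem = uniq.copy()
    for i in range(k - 1, -1, -1):
        digits[:, i] = rem % 4
        rem //= 4
    p_kmer = np.exp(bg_log[digits].sum(axis=1))
    expected = n_positions * p_kmer
    # Poisson tail with Bonferroni correction over the k-mer space: the
    # plain z-rule degenerates when expected counts are far below 1 (any
    # single occurrence looks like many standard deviations)
    from scipy.stats import poisson

    tail = poisson.sf(counts - 1, expected)
    cand = np.nonzero(tail * (4.0 ** k) < params.seed_alpha)[0]
    # deterministic ordering: tail p ascending, count descending, k-mer code
    rng = np.random.default_rng(seed)
    del rng
    order = cand[np.lexsort((uniq[cand], -counts[cand], tail[cand]))]
    order = order[: params.max_seeds]

    motifs: list[Motif] = []
    tried_seeds: list[str] = []
    reported_picks: list[set[tuple[int, int]]] = []  # {(seq_index, bin)} per motif
    trials = 0
    for idx in order:
        if len(motifs) >= params.max_motifs or trials >= params.max_seed_trials:
            break
        seed_kmer = _kmer_to_string(int(uniq[idx]), k)
        if any(
            _hamming(seed_kmer, c) <= 2 or _hamming(revcomp(seed_kmer), c) <= 2
            for c in tried_seeds
        ):
            continue
        tried_seeds.append(seed_kmer)
        trials += 1
        # initial PWM: consensus base 0.7, others 0.1
        p = np.full((4, k), 0.1)
        for j, b in enumerate(seed_kmer):
            p[_CODE[b], j] = 0.7
        model = PWMModel(p, background=background, pseudocount=params.pseudocount)

        picks = []
        for _ in range(params.max_iter):
            threshold = params.site_threshold_frac * model.max_score
            picks = _collect_sites(model, encoded, threshold)
            if len(picks) < 2:
                break
            counts_mat = np.zeros((4, k))
            for i, off, strand, _ in picks:
                site = encoded[i][off:off + k]
                if strand == "-":
                    site = (3 - site[::-1]) % 4
                for j, c in enumerate(site):
                    counts_mat[c, j] += 1
            new_model = PWMModel.from_counts(
                counts_mat, pseudocount=params.pseudocount, background=background
            )
            if np.max(np.abs(new_model.probabilities - model.probabilities)) < params.tol:
                model = new_model
                break
            model = new_model

        if len(picks) < params.min_sites:
            continue
        # duplicate check: a shifted or reverse-complemented rediscovery picks
        # largely the same window positions as an already-reported motif
        pick_bins = {(i, off // k) for i, off, _, _ in picks}
        pick_bins |= {(i, off // k + 1) for i, off, _, _ in picks}
        if any(
            len(pick_bins & prev) >= len(picks) // 2 for prev in reported_picks
        ):
            continue
        # null filter: count high-scoring sites (above the stricter test
        # threshold) against the number expected in random windows
        t_test = params.test_threshold_frac * model.max_score
        n_high = sum(1 for _, _, _, sc in picks if sc > t_test)
        p_pos = hit_probability(model, t_test)
        exp_hits = sum(
            1.0 - (1.0 - p_pos) ** (2 * max(0, len(c) - k + 1)) for c in encoded
        )
        sd_hits = np.sqrt(max(exp_hits * (1 - exp_hits / max(len(encoded), 1)), 1e-12))
        if n_high <= exp_hits + params.z_min * sd_hits:
            continue

        # final site report: every occurrence above the FPR-calibrated
        # threshold in every window (not just the ZOOPS pick used for PWM
        # estimation), so the site lists carry the full density the genome
        # projection needs; at a position hit on both strands the better
        # strand wins
        threshold = threshold_for_fpr(model, params.site_fpr)
        rc_model = model.reverse_complement()
        counts_mat = np.zeros((4, k))
        sites = []
        for i, codes in enumerate(encoded):
            fwd = score_positions(model, codes)
            rev = score_positions(rc_model, codes)
            if len(fwd) == 0:
                continue
            strand_best = np.where(fwd >= rev, fwd, rev)
            for off in np.nonzero(strand_best > threshold)[0]:
                strand = "+" if fwd[off] >= rev[off] else "-"
                site = encoded[i][off:off + k]
                if strand == "-":
                    site = (3 - site[::-1]) % 4
                for j, c in enumerate(site):
                    counts_mat[c, j] += 1
                sites.append(MotifSite(peak_ids[i], int(off), strand, decode(site)))
        if len(sites) < params.min_sites:
            continue
        motif = Motif(
            motif_id=f"{dataset_id or 'd'}.m{len(motifs)}",
            dataset_id=dataset_id,
            counts=counts_mat,
            sites=sites,
        )
        motifs.append(motif)
        reported_picks.append(pick_bins)
    if not motifs:
        logger.info("dataset %s: no motif passed the null filter", dataset_id)
    return motifs


def filter_by_distinct_loci(
    motif_list: list[Motif],
    locator: dict[str, tuple[str, int]],
    min_loci: int = 10,
) -> list[Motif]:
    """Drop motifs whose sites concentrate at too few genomic loci.

    Peak windows overlap whenever several peaks cover one genomic region,
    so a background pattern repeated across overlapping windows can look
    enriched by count alone. A genuine motif recurs at many distinct loci.
    ``locator`` maps peak_id to (chrom, window_start); site centers within
    one motif width of each other count as one locus.
    """
    kept = []
    for m in motif_list:
        centers: dict[str, list[int]] = {}
        for s in m.sites:
            if s.peak_id not in locator:
                continue
            chrom, ws = locator[s.peak_id]
            centers.setdefault(chrom, []).append(ws + s.offset + m.width // 2)
        loci = 0
        for chrom, cs in centers.items():
            cs.sort()
            loci += 1 + sum(
                1 for a, b in zip(cs, cs[1:]) if b - a > m.width
            )
        if loci >= min_loci:
            kept.append(m)
        else:
            logger.info("motif %s dropped: %d distinct loci < %d",
                        m.motif_id, loci, min_loci)
    return kept


# ---------------------------------------------------------------- exchange


def write_meme_minimal(models: dict[str, PWMModel], path) -> None:
    """MEME-minimal text output for a {name: PWMModel} mapping."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = next(iter(models.values())).background if models else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for name, m in models.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for col in m.probabilities.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> dict[str, PWMModel]:
    models: dict[str, PWMModel] = {}
    bg = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    name = None
    for line in lines:
        if line.startswith("Background letter frequencies"):
            parts = next(lines).split()
            bg = np.array([float(parts[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            cols = [[float(x) for x in next(lines).split()] for _ in range(w)]
            p = np.asarray(cols).T
            p = p / p.sum(axis=0, keepdims=True)
            p = np.clip(p, 1e-9, None)
            p = p / p.sum(axis=0, keepdims=True)
            models[name] = PWMModel(p, background=bg)
    return models


def write_sites_tsv(motifs: list[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("dataset_id\tmotif_id\tpeak_id\toffset\tstrand\tsequence\n")
        for m in motifs:
            for s in m.sites:
                fh.write(f"{m.dataset_id}\t{m.motif_id}\t{s.peak_id}\t"
                         f"{s.offset}\t{s.strand}\t{s.sequence}\n")


def read_sites_tsv(path) -> list[Motif]:
    """Adapter for external motif finders: rebuild Motifs from a sites TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str})
    motifs = []
    for (dataset_id, motif_id), grp in df.groupby(["dataset_id", "motif_id"], sort=True):
        sites = [
            MotifSite(str(r.peak_id), int(r.offset), str(r.strand), str(r.sequence))
            for r in grp.itertuples()
        ]
        w = len(sites[0].sequence)
        counts = np.zeros((4, w))
        for s in sites:
            for j, c in enumerate(encode(s.sequence)):
                if c < 4:
                    counts[c, j] += 1
        motifs.append(Motif(str(motif_id), str(dataset_id), counts, sites))
    return motifs
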