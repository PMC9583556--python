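"""Projection of UM sites to the genome and CRM candidate calling.

Pooled UM sites are projected onto genomic coordinates, re-scored against
their UM's PWM (only positively scoring sites are kept) and deduplicated.
Adjacent sites at most ``max_gap`` (default 300 bp, roughly two nucleosome
lengths) apart are linked into CRM candidates (CRMCs); every peak-covered
position outside a CRMC span becomes non-CRMC, so CRMCs and non-CRMCs form
an exact partition of the covered regions. Each CRMC with n >= 2 sites
(b_1..b_n) receives the score

    S_CRM = 2/(n-1) * sum_{i<j} S_INTER[U(b_i), U(b_j)] * (S(b_i) + S(b_j))

which rewards many, strong sites of UM pairs that interact across datasets.
Single-site CRMCs score 0 by convention (the formula is undefined at n=1)
and can be excluded downstream via the p-value cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import intervals
from .clustering import UniqueMotif
from .motifs import PWMModel, encode, score_site
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

MAX_GAP = 300


@dataclass(frozen=True)
class GenomicSite:
    chrom: str
    start: int
    end: int
    strand: str
    um_id: str
    score: float  # PWM log-odds, bits; > 0 by construction

    def __post_init__(self):
        if self.score <= 0:
            raise ValueError("only positive-scoring sites enter CRM scoring")


@dataclass
class CRMC:
    chrom: str
    start: int
    end: int
    sites: list[GenomicSite]
    s_crm: float = 0.0
    p_value: float | None = None
    n_sites_hint: int | None = None  # set when loaded from BED without sites

    @property
    def n_sites(self) -> int:
        if not self.sites and self.n_sites_hint is not None:
            return self.n_sites_hint
        return len(self.sites)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomePartition:
    covered: dict[str, np.ndarray]
    crmcs: list[CRMC]
    non_crmcs: dict[str, np.ndarray]

    def crmc_intervals(self) -> dict[str, np.ndarray]:
        per: dict[str, list] = {}
        for c in self.crmcs:
            per.setdefault(c.chrom, []).append((c.start, c.end))
        return {ch: intervals.as_array(v) for ch, v in per.items()}


def project_sites(
    ums: list[UniqueMotif],
    genome,
    models: dict[str, PWMModel] | None = None,
) -> list[GenomicSite]:
    """Map pooled UM sites to genomic coordinates and re-score them.

    ``genome`` is any mapping of chromosome name to sequence string (a
    ``pyfaidx.Fasta`` works; records are str()-ed). Sites are deduplicated
    on (chrom, start, end, um_id); non-positive scores are dropped. Sites
    extending beyond chromosome bounds raise.
    """
    out: list[GenomicSite] = []
    seen: set[tuple[str, int, int, str]] = set()
    for um in ums:
        if not um.viable:
            continue
        model = (models or {}).get(um.um_id) or um.model
        rc_model = model.reverse_complement()
        for s in um.sites:
            key = (s.chrom, s.start, s.end, um.um_id)
            if key in seen:
                continue
            seen.add(key)
            seq = str(genome[s.chrom][s.start:s.end])
            if s.start < 0 or len(seq) != s.end - s.start:
                raise ValueError(
                    f"site {s.chrom}:{s.start}-{s.end} outside chromosome bounds"
                )
            m = model if s.strand == "+" else rc_model
            score = score_site(m, seq)
            if score <= 0:
                continue
            out.append(GenomicSite(s.chrom, s.start, s.end, s.strand, um.um_id, score))
    out.sort(key=lambda x: (x.chrom, x.start, x.end, x.um_id))
    return out


def partition_crmcs(
    sites: list[GenomicSite],
    covered: dict[str, np.ndarray],
    max_gap: int = MAX_GAP,
) -> GenomePartition:
    """Link sites with inter-site gap <= max_gap into CRMCs; the covered
    complement becomes the non-CRMC set.

    The gap is edge-to-edge between half-open site intervals (sites 110 bp
    apart end-to-start have gap 110-... e.g. [100,110) and [400,410) gap
    290); the threshold is inclusive. CRMC spans run from the first site
    start to the last site end. Sites outside the covered regions are kept
    with a warning.
    """
    per_chrom: dict[str, list[GenomicSite]] = {}
    for s in sites:
        per_chrom.setdefault(s.chrom, []).append(s)

    crmcs: list[CRMC] = []
    for chrom in sorted(per_chrom):
        chrom_sites = sorted(per_chrom[chrom], key=lambda x: (x.start, x.end))
        cov = intervals.merge(covered.get(chrom, np.empty((0, 2), np.int64)))
        if len(cov):
            starts = np.array([s.start for s in chrom_sites])
            ends = np.array([s.end for s in chrom_sites])
            n_before = np.searchsorted(cov[:, 0], ends, side="left")
            n_closed = np.searchsorted(np.sort(cov[:, 1]), starts, side="right")
            if np.any(n_before - n_closed <= 0):
                logger.warning("some sites on %s fall outside covered regions", chrom)
        run: list[GenomicSite] = []
        run_end = None
        for s in chrom_sites:
            if run and s.start - run_end > max_gap:
                crmcs.append(CRMC(chrom, run[0].start, run_end, run))
                run = []
            run.append(s)
            run_end = s.end if run_end is None or len(run) == 1 else max(run_end, s.end)
        if run:
            crmcs.append(CRMC(chrom, run[0].start, run_end, run))

    crmc_per_chrom: dict[str, list] = {}
    for c in crmcs:
        crmc_per_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    non: dict[str, np.ndarray] = {}
    for chrom, cov in covered.items():
        cov = intervals.merge(cov)
        spans = crmc_per_chrom.get(chrom, [])
        non[chrom] = intervals.subtract(cov, spans) if len(cov) else cov
    return GenomePartition(covered=covered, crmcs=crmcs, non_crmcs=non)


def merge_islands(sites: list[GenomicSite]):
    """Transitive merge of sites sharing >= 1 bp into TFBS islands.

    Half-open abutting sites ([100,110) + [110,120)) stay separate. Returns
    a list of (chrom, start, end, um_ids) tuples.
    """
    per_chrom: dict[str, list[GenomicSite]] = {}
    for s in sites:
        per_chrom.setdefault(s.chrom, []).append(s)
    islands = []
    for chrom in sorted(per_chrom):
        ss = sorted(per_chrom[chrom], key=lambda x: (x.start, x.end))
        cur = [ss[0]]
        cur_end = ss[0].end
        for s in ss[1:]:
            if s.start < cur_end:  # strict: >= 1 shared bp
                cur.append(s)
                cur_end = max(cur_end, s.end)
            else:
                islands.append((chrom, cur[0].start, cur_end,
                                sorted({x.um_id for x in cur})))
                cur, cur_end = [s], s.end
        islands.append((chrom, cur[0].start, cur_end, sorted({x.um_id for x in cur})))
    return islands


def crm_score(crmc: CRMC, net: InteractionNetwork) -> float:
    """S_CRM of one CRMC under the interaction network (0 for n = 1)."""
    n = crmc.n_sites
    if n == 0:
        raise ValueError("cannot score an empty CRMC")
    if n == 1:
        return 0.0
    u = np.array([net.index_of(s.um_id) for s in crmc.sites])
    s = np.array([s.score for s in crmc.sites])
    sub = net.weights[np.ix_(u, u)]
    # sum_{i<j} w_ij (s_i + s_j) == sum_i s_i * sum_{j != i} w_ij
    row = sub.sum(axis=1) - np.diag(sub)
    return float(2.0 / (n - 1) * np.dot(s, row))


def score_partition(partition: GenomePartition, net: InteractionNetwork) -> None:
    for c in partition.crmcs:
        c.s_crm = crm_score(c, net)


def functional_state(crmc: CRMC, cell_type_peaks: dict[str, np.ndarray]) -> str:
    """"bound" iff any constituent site overlaps any original (unextended)
    peak of the cell type by >= 1 bp, else "unbound"."""
    peaks = cell_type_peaks.get(crmc.chrom)
    if peaks is None or len(peaks) == 0:
        return "unbound"
    for s in crmc.sites:
        if intervals.count_overlapping_pairs([(s.start, s.end)], peaks) > 0:
            return "bound"
    return "unbound"


def write_crmc_bed(crmcs: list[CRMC], path) -> None:
    """BED6+ output: name, score=S_CRM, strand '.', n_sites, p_value."""
    with open(path, "w") as fh:
        for i, c in enumerate(crmcs):
            p = "NA" if c.p_value is None else f"{c.p_value:.6g}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tCRMC{i}\t{c.s_crm:.4f}\t.\t"
                     f"{c.n_sites}\t{p}\n")
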