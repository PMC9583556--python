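"""Miniature-genome fixture generator.

Emulates the statistical structure the CRM-prediction pipeline exploits:
a background genome, planted CRMs containing clustered binding sites of
cooperative TF motifs (each cooperative pair is co-planted in a
configurable fraction of shared CRMs, which produces the high mode of the
co-occurrence score distribution), per-(TF, cell-type) narrowPeak datasets
whose non-decoy peak summits jitter around planted sites, decoy peaks
outside all CRMs, and a conservation track whose scores are shifted away
from the neutral band over CRM positions. Ground truth is written as BED
so every downstream stage is testable without downloads.

Deliberately not modelled: read-level ChIP-seq noise, peak calling,
fragment-length effects, and realistic genome composition (background is
i.i.d. with configurable base frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import BASES

DEFAULT_COOPERATION_PAIRS = tuple((2 * i, 2 * i + 1) for i in range(10))


class PlacementError(RuntimeError):
    """CRMs could not be placed without overlap after bounded retries."""


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_tfs: int = 20
    n_cell_types: int = 5
    motif_width: int = 10
    n_crms: int = 200
    crm_length_mean: int = 1000
    sites_per_crm: tuple[int, int] = (6, 12)
    cooperation_pairs: tuple[tuple[int, int], ...] = DEFAULT_COOPERATION_PAIRS
    cooperation_fraction: float = 0.9  # co-binding rate of a cooperative pair
    peaks_per_dataset: int = 50
    peak_length_mean: int = 300
    decoy_peak_fraction: float = 0.1
    summit_jitter_sd: float = 20.0
    conservation_neutral_sd: float = 0.3
    conservation_constrained_shift: float = 2.0
    motif_sharpness: float = 0.9  # consensus-base probability per column
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    crm_min_separation: int = 500  # > the 300-bp linking gap, keeps CRMs distinct
    max_placement_tries: int = 200

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_tfs", "n_cell_types",
                     "n_crms", "crm_length_mean", "peaks_per_dataset",
                     "peak_length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("decoy_peak_fraction", "cooperation_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.motif_width < 6:
            raise ValueError("motif_width must be >= 6")
        if not np.isclose(sum(self.background_freqs), 1.0):
            raise ValueError("background_freqs must sum to 1")
        lo, hi = self.sites_per_crm
        if not (0 < lo <= hi):
            raise ValueError("sites_per_crm must be a positive (lo, hi) range")


@dataclass
class GroundTruth:
    crm_intervals: list[tuple[str, int, int]]
    site_intervals: list[tuple[str, int, int, int, str]]  # chrom,s,e,tf,strand
    cooperation_pairs: tuple[tuple[int, int], ...]
    motif_matrices: list[np.ndarray]  # (4, w) probability matrix per TF

    def sites_of_tf(self, tf: int) -> list[tuple[str, int, int, str]]:
        return [(c, s, e, st) for c, s, e, t, st in self.site_intervals if t == tf]


@dataclass
class Fixture:
    config: FixtureConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    #: dataset_id -> list of narrowPeak rows (10 columns each)
    datasets: dict[str, list[tuple]]
    conservation: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    truth: GroundTruth


def _sample_motif_matrices(cfg: FixtureConfig, rng) -> list[np.ndarray]:
    mats = []
    for _ in range(cfg.n_tfs):
        consensus = rng.integers(0, 4, size=cfg.motif_width)
        m = np.full((4, cfg.motif_width), (1 - cfg.motif_sharpness) / 3)
        m[consensus, np.arange(cfg.motif_width)] = cfg.motif_sharpness
        mats.append(m)
    return mats


def _place_crms(cfg: FixtureConfig, rng) -> list[tuple[int, int, int]]:
    """(chrom_index, start, length) for each CRM, mutually disjoint with
    at least crm_min_separation bp between CRMs on the same chromosome."""
    sd = max(1.0, 0.15 * cfg.crm_length_mean)
    placed: list[tuple[int, int, int]] = []
    by_chrom: dict[int, list[tuple[int, int]]] = {i: [] for i in range(cfg.n_chroms)}
    for _ in range(cfg.n_crms):
        length = int(np.clip(rng.normal(cfg.crm_length_mean, sd),
                             0.5 * cfg.crm_length_mean, 2 * cfg.crm_length_mean))
        for attempt in range(cfg.max_placement_tries):
            ci = int(rng.integers(cfg.n_chroms))
            start = int(rng.integers(0, cfg.chrom_length - length))
            lo, hi = start - cfg.crm_min_separation, start + length + cfg.crm_min_separation
            if all(e <= lo or s >= hi for s, e in by_chrom[ci]):
                by_chrom[ci].append((start, start + length))
                placed.append((ci, start, length))
                break
        else:
            raise PlacementError(
                f"could not place CRM after {cfg.max_placement_tries} tries"
            )
    return placed


def _site_starts(length: int, n: int, w: int, rng) -> np.ndarray:
    """n sorted non-overlapping site starts inside [0, length)."""
    slack = length - n * w
    if slack < 0:
        raise PlacementError("CRM too short for its sites")
    cuts = np.sort(rng.random(n)) * slack
    return (np.floor(cuts).astype(int) + np.arange(n) * w)


def generate(cfg: FixtureConfig) -> Fixture:
    """Build the whole fixture in memory; byte-determinism follows from the
    single seeded generator and fixed iteration order."""
    rng = np.random.default_rng(cfg.seed)
    w = cfg.motif_width
    bg = np.asarray(cfg.background_freqs)
    mats = _sample_motif_matrices(cfg, rng)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_codes = [
        rng.choice(4, size=cfg.chrom_length, p=bg) for _ in range(cfg.n_chroms)
    ]

    crm_placements = _place_crms(cfg, rng)
    lo, hi = cfg.sites_per_crm
    crm_intervals: list[tuple[str, int, int]] = []
    site_intervals: list[tuple[str, int, int, int, str]] = []
    partner = {}
    for a, b in cfg.cooperation_pairs or ():
        partner[a], partner[b] = b, a
    for crm_idx, (ci, start, length) in enumerate(crm_placements):
        chrom = chrom_names[ci]
        crm_intervals.append((chrom, start, start + length))
        n_sites = int(rng.integers(lo, hi + 1))
        # cooperative TFs co-bind: whenever a paired TF is planted, its
        # partner joins with probability cooperation_fraction
        tfs: list[int] = []
        while len(tfs) < n_sites:
            tf = int(rng.integers(cfg.n_tfs))
            tfs.append(tf)
            if (
                tf in partner
                and len(tfs) < n_sites
                and rng.random() < cfg.cooperation_fraction
            ):
                tfs.append(partner[tf])
        starts = _site_starts(length, len(tfs), w, rng)
        order = rng.permutation(len(tfs))
        for off, tf in zip(starts, [tfs[i] for i in order]):
            s = start + int(off)
            cols = np.array([rng.choice(4, p=mats[tf][:, j]) for j in range(w)])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                cols = (3 - cols)[::-1]
            genome_codes[ci][s:s + w] = cols
            site_intervals.append((chrom, s, s + w, int(tf), strand))

    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        name: alphabet[codes].tobytes().decode()
        for name, codes in zip(chrom_names, genome_codes)
    }
    chrom_sizes = {name: cfg.chrom_length for name in chrom_names}

    # ---- per-(TF, cell-type) narrowPeak datasets -------------------------
    sites_by_tf: dict[int, list[tuple[str, int, int]]] = {}
    for chrom, s, e, tf, _ in site_intervals:
        sites_by_tf.setdefault(tf, []).append((chrom, s, e))
    crm_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in crm_intervals:
        crm_by_chrom.setdefault(chrom, []).append((s, e))

    half = cfg.peak_length_mean // 2
    datasets: dict[str, list[tuple]] = {}
    for tf in range(cfg.n_tfs):
        tf_sites = sites_by_tf.get(tf, [])
        for cell in range(cfg.n_cell_types):
            ds_id = f"TF{tf:02d}_CT{cell}"
            n_decoy = int(round(cfg.decoy_peak_fraction * cfg.peaks_per_dataset))
            n_main = cfg.peaks_per_dataset - n_decoy
            rows = []
            if tf_sites:
                if n_main >= len(tf_sites):
                    # deep sampling recovers every true site at least once
                    extra = rng.choice(
                        len(tf_sites), size=n_main - len(tf_sites), replace=True
                    )
                    idx = np.concatenate([np.arange(len(tf_sites)), extra])
                else:
                    idx = rng.choice(len(tf_sites), size=n_main, replace=False)
            else:
                idx = np.empty(0, int)
                n_decoy = cfg.peaks_per_dataset
            for k, i in enumerate(idx):
                chrom, s, e = tf_sites[int(i)]
                summit = (s + e) // 2
                if cfg.summit_jitter_sd > 0:
                    summit += int(round(rng.normal(0, cfg.summit_jitter_sd)))
                summit = int(np.clip(summit, 0, cfg.chrom_length - 1))
                ps = max(0, summit - half)
                pe = min(cfg.chrom_length, summit + (cfg.peak_length_mean - half))
                enr = round(20.0 + rng.exponential(30.0), 3)
                rows.append((chrom, ps, pe, f"{ds_id}_p{k}", 0, ".",
                             enr, -1, -1, summit - ps))
            for k in range(n_decoy):
                for _ in range(cfg.max_placement_tries):
                    ci = int(rng.integers(cfg.n_chroms))
                    chrom = chrom_names[ci]
                    summit = int(rng.integers(half, cfg.chrom_length - half))
                    margin = cfg.peak_length_mean
                    if all(summit < s - margin or summit >= e + margin
                           for s, e in crm_by_chrom.get(chrom, [])):
                        break
                else:
                    raise PlacementError("could not place a decoy peak outside CRMs")
                ps, pe = summit - half, summit + (cfg.peak_length_mean - half)
                enr = round(20.0 + rng.exponential(15.0), 3)
                rows.append((chrom, ps, pe, f"{ds_id}_d{k}", 0, ".",
                             enr, -1, -1, summit - ps))
            rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
            datasets[ds_id] = rows

    # ---- conservation track ---------------------------------------------
    conservation: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name, _ in zip(chrom_names, genome_codes):
        scores = rng.normal(0.0, cfg.conservation_neutral_sd, size=cfg.chrom_length)
        for s, e in crm_by_chrom.get(name, []):
            scores[s:e] = rng.normal(
                cfg.conservation_constrained_shift,
                cfg.conservation_neutral_sd,
                size=e - s,
            )
        scores = np.round(scores, 3)
        change = np.nonzero(np.diff(scores))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [cfg.chrom_length]])
        conservation[name] = (starts, ends, scores[starts])

    truth = GroundTruth(
        crm_intervals=crm_intervals,
        site_intervals=site_intervals,
        cooperation_pairs=tuple(cfg.cooperation_pairs),
        motif_matrices=mats,
    )
    return Fixture(config=cfg, genome=genome, chrom_sizes=chrom_sizes,
                   datasets=datasets, conservation=conservation, truth=truth)


def write_fixture(fx: Fixture, outdir, write_conservation: bool = True) -> dict[str, Path]:
    """Write all fixture files; returns the path of each artifact.

    Formats: genome FASTA; two-column chrom sizes; narrowPeak BED6+4 per
    dataset under peaks/; 1-bp-resolution run-length-merged bedGraph;
    ground-truth CRMs and sites as BED6. All intervals 0-based half-open.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in fx.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["genome"] = fasta

    sizes = outdir / "genome.chrom.sizes"
    with open(sizes, "w") as fh:
        for name, n in fx.chrom_sizes.items():
            fh.write(f"{name}\t{n}\n")
    paths["chrom_sizes"] = sizes

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for ds_id in sorted(fx.datasets):
        p = peak_dir / f"{ds_id}.narrowPeak"
        with open(p, "w") as fh:
            for row in fx.datasets[ds_id]:
                fh.write("\t".join(str(x) for x in row) + "\n")
        tf, cell = ds_id.split("_")
        # relative to the fixture directory: byte-deterministic and portable
        manifest_rows.append((ds_id, tf, cell, str(p.relative_to(outdir))))
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("dataset_id\ttf\tcell_type\tpath\n")
        for r in manifest_rows:
            fh.write("\t".join(r) + "\n")
    paths["manifest"] = manifest

    if write_conservation:
        bg = outdir / "conservation.bedGraph"
        with open(bg, "w") as fh:
            for name in sorted(fx.conservation):
                starts, ends, scores = fx.conservation[name]
                for s, e, v in zip(starts, ends, scores):
                    fh.write(f"{name}\t{s}\t{e}\t{v:g}\n")
        paths["conservation"] = bg

    crm_bed = outdir / "truth_crms.bed"
    with open(crm_bed, "w") as fh:
        for i, (chrom, s, e) in enumerate(sorted(fx.truth.crm_intervals)):
            fh.write(f"{chrom}\t{s}\t{e}\tCRM{i}\t0\t+\n")
    paths["truth_crms"] = crm_bed

    site_bed = outdir / "truth_sites.bed"
    with open(site_bed, "w") as fh:
        for chrom, s, e, tf, strand in sorted(fx.truth.site_intervals):
            fh.write(f"{chrom}\t{s}\t{e}\tTF{tf:02d}\t0\t{strand}\n")
    paths["truth_sites"] = site_bed
    return paths


def make_fixture(cfg: FixtureConfig, outdir, write_conservation: bool = True):
    """Generate and write a fixture; returns (paths, GroundTruth)."""
    fx = generate(cfg)
    paths = write_fixture(fx, outdir, write_conservation=write_conservation)
    return paths, fx.truth
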