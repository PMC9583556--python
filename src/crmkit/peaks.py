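"""Reading, filtering and extension of TF ChIP-seq peak datasets.

Peaks arrive as ENCODE narrowPeak (BED6+4) files, one file per
(TF, cell-type) experiment. Quality control removes individual peaks with a
low read-enrichment score and then drops whole datasets left with too few
peaks; surviving peaks are replaced by fixed-length windows (default
1,000 bp, roughly half the mean length of known mammalian enhancers)
centered on the peak summit, so that motifs of both the ChIP-ed TF and its
cooperating TFs fall inside the analysed sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]

#: narrowPeak column (0-based) holding the enrichment score used for
#: filtering. The standard narrowPeak signal column is column 7 (1-based);
#: overridable because upstream pipelines sometimes stash it elsewhere.
DEFAULT_ENRICHMENT_COLUMN = 7


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    name: str
    enrichment: float
    summit_offset: int | None = None  # None == absent (narrowPeak -1)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start >= end")
        if self.enrichment < 0:
            raise ValueError(f"peak {self.name}: negative enrichment")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(f"peak {self.name}: summit offset out of range")

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when absent."""
        if self.summit_offset is None:
            return (self.start + self.end) // 2
        return self.start + self.summit_offset


@dataclass
class PeakDataset:
    dataset_id: str
    tf: str
    cell_type: str
    peaks: list[PeakRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


class NarrowPeakParseError(ValueError):
    pass


def read_narrowpeak(
    path,
    dataset_id: str | None = None,
    tf: str = "",
    cell_type: str = "",
    enrichment_column: int = DEFAULT_ENRICHMENT_COLUMN,
) -> PeakDataset:
    """Read a narrowPeak BED6+4 file into a :class:`PeakDataset`.

    A summit offset (column 10) of -1 is mapped to "absent"; such peaks use
    their interval midpoint as the summit. Malformed lines raise
    :class:`NarrowPeakParseError` naming the offending line.
    """
    path = str(path)
    if dataset_id is None:
        dataset_id = path
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise NarrowPeakParseError(
                    f"{path}:{lineno}: expected >=10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                enrichment = float(fields[enrichment_column - 1])
                summit = int(float(fields[9]))
            except ValueError as exc:
                raise NarrowPeakParseError(
                    f"{path}:{lineno}: non-numeric coordinate or score ({exc})"
                ) from None
            peaks.append(
                PeakRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3],
                    enrichment=enrichment,
                    summit_offset=None if summit < 0 else summit,
                )
            )
    return PeakDataset(dataset_id=dataset_id, tf=tf, cell_type=cell_type, peaks=peaks)


def filter_dataset(
    ds: PeakDataset, min_enrichment: float = 20.0, min_peaks: int = 20
) -> PeakDataset | None:
    """Drop low-enrichment peaks; reject the dataset if too few survive.

    Both thresholds are strict on the low side: a peak with enrichment
    exactly ``min_enrichment`` is retained, and a dataset with exactly
    ``min_peaks`` surviving peaks is kept. Returns ``None`` for a rejected
    dataset (excluded from all downstream stages).
    """
    kept = [p for p in ds.peaks if p.enrichment >= min_enrichment]
    if len(kept) < min_peaks:
        logger.info(
            "dataset %s rejected: %d peaks with enrichment >= %s (< %d required)",
            ds.dataset_id, len(kept), min_enrichment, min_peaks,
        )
        return None
    return replace(ds, peaks=kept)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (chrom, length) whitespace-separated text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def extend_peaks(
    ds: PeakDataset, chrom_sizes: dict[str, int], length: int = 1000
) -> dict[str, np.ndarray]:
    """Replace each peak by a ``length``-bp window centered on its summit.

    Windows are clipped (not shifted) at chromosome ends, so a clipped
    window can be shorter than ``length``. Returns per-chromosome interval
    arrays (not merged — one window per peak, in input order per chrom).
    """
    half = length // 2
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in ds.peaks:
        if p.chrom not in chrom_sizes:
            raise KeyError(f"peak {p.name} on unknown chromosome {p.chrom!r}")
        c = p.summit
        s = max(0, c - half)
        e = min(chrom_sizes[p.chrom], c + (length - half))
        per_chrom.setdefault(p.chrom, []).append((s, e))
    return {
        chrom: np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
        for chrom, ivs in per_chrom.items()
    }


def coverage(windows: dict[str, np.ndarray]) -> int:
    """Union coverage in bp of a per-chromosome window dict."""
    return sum(intervals.union_length(ivs) for ivs in windows.values())


def union_windows(window_sets: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Merged union of several per-chromosome window dicts."""
    pooled: dict[str, list[np.ndarray]] = {}
    for ws in window_sets:
        for chrom, ivs in ws.items():
            pooled.setdefault(chrom, []).append(ivs)
    return {
        chrom: intervals.merge(np.concatenate(chunks))
        for chrom, chunks in pooled.items()
    }


def write_bed3(windows: dict[str, np.ndarray], path) -> None:
    rows = []
    for chrom in sorted(windows):
        for s, e in windows[chrom]:
            rows.append((chrom, int(s), int(e)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
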