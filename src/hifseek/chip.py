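"""Bin-level ChIP enrichment calling with replicate reproducibility.

Reads are assigned by their 5' start coordinate to fixed-width bins
(default 200 bp).  Enrichment over a matched input sample is tested per bin
with a one-sided Poisson upper-tail test against the depth-normalized input
count, floored at the genome-wide mean normalized input per bin so that
zero-input bins cannot produce unbounded enrichment.  Benjamini-Hochberg
control is applied jointly across all bins of all chromosomes; significant
adjacent bins are merged into peaks, peaks are filtered on minimum adjusted
p, averaged input count, averaged ChIP count and fold enrichment, and peaks
supported by both biological replicates become binding regions (intersection
intervals snapped to the bin grid).

All interval coordinates are internally 0-based half-open and bin-aligned;
1-based inclusive strings are produced only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "BinTrack",
    "PeakCall",
    "BindingRegion",
    "bin_reads",
    "call_peaks",
    "filter_peaks",
    "reproducible_regions",
]


@dataclass
class BinTrack:
    """Fixed-width bin counts for one chromosome of one sample.

    ``library_total`` is the whole-sample read count (all chromosomes), used
    for depth normalization.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    library_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_size <= 0:
            raise DataError("bin_size must be positive")
        if (self.counts < 0).any():
            raise DataError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass
class PeakCall:
    """One called peak in one replicate (0-based half-open, bin-aligned)."""

    chrom: str
    start: int
    end: int
    avg_chip: float
    avg_input: float
    avg_input_norm: float
    fold_enrichment: float
    min_adj_p: float
    replicate: str = ""

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BindingRegion:
    """A replicate-reproducible binding interval with per-replicate support."""

    chrom: str
    start: int
    end: int
    support: dict = field(default_factory=dict)  # replicate id -> list[PeakCall]
    genes: list = field(default_factory=list)  # filled by the targets stage

    @property
    def width(self) -> int:
        return self.end - self.start

    def report_coords(self) -> str:
        """Report-style 1-based inclusive coordinate string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def bin_reads(
    read_positions: Mapping[str, Sequence[int]],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 200,
) -> dict[str, BinTrack]:
    """Count read 5' positions into half-open bins per chromosome.

    Every chromosome in ``chrom_sizes`` gets a track (all-zero if it has no
    reads); the sum of all bin counts equals the number of input reads.
    """
    if bin_size <= 0:
        raise DataError("bin_size must be positive")
    bad: list[str] = []
    arrays: dict[str, np.ndarray] = {}
    for chrom, positions in read_positions.items():
        if chrom not in chrom_sizes:
            raise DataError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(positions, dtype=np.int64)
        size = chrom_sizes[chrom]
        out = (pos < 0) | (pos >= size)
        if out.any():
            bad.extend(f"{chrom}:{p}" for p in pos[out][:10])
            continue
        arrays[chrom] = pos
    if bad:
        raise DataError(f"read positions out of chromosome bounds: {bad}")
    total = int(sum(a.size for a in arrays.values()))
    tracks = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        counts = np.zeros(n_bins, dtype=np.int64)
        if chrom in arrays:
            np.add.at(counts, arrays[chrom] // bin_size, 1)
        tracks[chrom] = BinTrack(chrom, bin_size, counts, total)
    return tracks


def _check_grids(chip: Mapping[str, BinTrack], inp: Mapping[str, BinTrack]) -> None:
    if set(chip) != set(inp):
        raise DataError("ChIP and input tracks cover different chromosomes")
    for chrom in chip:
        c, i = chip[chrom], inp[chrom]
        if c.bin_size != i.bin_size or c.n_bins != i.n_bins:
            raise DataError(f"bin grids differ on {chrom}")


def call_peaks(
    chip: Mapping[str, BinTrack],
    inp: Mapping[str, BinTrack],
    fdr: float = 0.05,
    max_gap_bins: int = 0,
    replicate: str = "",
) -> list[PeakCall]:
    """Call enriched bins against depth-normalized input and merge neighbors.

    Per bin, lambda_i = input_i * (chip_total / input_total), floored at the
    genome-wide mean normalized input per bin; the ChIP count is tested with
    the Poisson upper tail P(X >= chip_i | lambda_i).  BH adjustment runs
    jointly over all bins of all chromosomes; bins with adjusted p <= fdr
    are merged when within ``max_gap_bins`` (default adjacency 0) and each
    merged run becomes a PeakCall with member-bin-averaged statistics.
    """
    _check_grids(chip, inp)
    if not 0 < fdr < 1:
        raise DataError("fdr must be in (0, 1)")
    # library_total is replicated on every chromosome track of a sample
    chip_total = next(iter(chip.values())).library_total
    input_total = next(iter(inp.values())).library_total
    if input_total <= 0:
        raise DataError("input track has zero depth")
    scale = chip_total / input_total

    chroms = sorted(chip)
    chip_counts = np.concatenate([chip[c].counts for c in chroms]).astype(float)
    input_counts = np.concatenate([inp[c].counts for c in chroms]).astype(float)
    lam_raw = input_counts * scale
    lam = np.maximum(lam_raw, lam_raw.mean())
    # P(X >= k) for X ~ Poisson(lam)
    p = stats.poisson.sf(chip_counts - 1, lam)
    _, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")

    calls: list[PeakCall] = []
    offset = 0
    for chrom in chroms:
        n = chip[chrom].n_bins
        bs = chip[chrom].bin_size
        sig = np.flatnonzero(p_adj[offset : offset + n] <= fdr)
        for run in _merge_runs(sig, max_gap_bins):
            bins = np.arange(run[0], run[1] + 1)
            sl = offset + bins
            avg_chip = float(chip_counts[sl].mean())
            avg_input = float(input_counts[sl].mean())
            avg_input_norm = float(lam[sl].mean())
            calls.append(
                PeakCall(
                    chrom=chrom,
                    start=int(run[0]) * bs,
                    end=(int(run[1]) + 1) * bs,
                    avg_chip=avg_chip,
                    avg_input=avg_input,
                    avg_input_norm=avg_input_norm,
                    fold_enrichment=avg_chip / avg_input_norm,
                    min_adj_p=float(p_adj[sl].min()),
                    replicate=replicate,
                )
            )
        offset += n
    return calls


def _merge_runs(indices: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Group sorted bin indices into (first, last) runs allowing gaps <= max_gap."""
    if indices.size == 0:
        return []
    runs = []
    start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i - prev <= max_gap + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def filter_peaks(
    calls: Iterable[PeakCall],
    min_input: float = 10.0,
    min_chip: float = 10.0,
    min_fe: float = 1.6,
    max_min_p: float = 0.05,
) -> list[PeakCall]:
    """Keep peaks passing all four criteria (inclusive thresholds):

    (1) minimum adjusted p <= max_min_p; (2) averaged input tag count >=
    min_input; (3) averaged ChIP tag count >= min_chip; (4) fold enrichment
    (averaged ChIP / normalized averaged input) >= min_fe.
    """
    return [
        c
        for c in calls
        if c.min_adj_p <= max_min_p
        and c.avg_input >= min_input
        and c.avg_chip >= min_chip
        and c.fold_enrichment >= min_fe
    ]


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def reproducible_regions(
    rep_a: Iterable[PeakCall],
    rep_b: Iterable[PeakCall],
    bin_size: int = 200,
) -> list[BindingRegion]:
    """Binding regions = intervals supported by a filtered peak in both replicates.

    Per chromosome the emitted interval set is the intersection of the two
    replicates' peak-interval unions, each piece snapped outward to the bin
    grid; peaks with no counterpart in the other replicate are dropped.
    Every region carries the supporting PeakCall statistics of both
    replicates.
    """
    rep_a, rep_b = list(rep_a), list(rep_b)
    by_chrom: dict[str, tuple[list[PeakCall], list[PeakCall]]] = {}
    for c in rep_a:
        by_chrom.setdefault(c.chrom, ([], []))[0].append(c)
    for c in rep_b:
        by_chrom.setdefault(c.chrom, ([], []))[1].append(c)

    regions: list[BindingRegion] = []
    for chrom in sorted(by_chrom):
        a_calls, b_calls = by_chrom[chrom]
        pieces = _intersect(
            _union([c.interval() for c in a_calls]),
            _union([c.interval() for c in b_calls]),
        )
        for s, e in pieces:
            s = (s // bin_size) * bin_size
            e = -(-e // bin_size) * bin_size
            support_a = [c for c in a_calls if c.start < e and c.end > s]
            support_b = [c for c in b_calls if c.start < e and c.end > s]
            regions.append(
                BindingRegion(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    support={"A": support_a, "B": support_b},
                )
            )
    return regions
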