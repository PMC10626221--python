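"""Variable-size genomic bins with equal expected uniquely-mapped reads.

Sparse-coverage copy-number calling works on bins sized so that every bin is
expected to receive the same number of uniquely mapped reads under a flat
(diploid, bias-free) genome.  Copy number is then proportional to raw read
density per bin.  Bins are built per chromosome by inverse-CDF splitting of
the cumulative mappability weight; boundaries snap to track-window edges.

Coordinates are 0-based half-open throughout; on disk a BinMap is BED5
(chrom, start, end, name=bin index, score=round(GC*1000)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["BinMap", "BinCounts", "build_variable_bins", "compute_bin_gc",
           "count_reads_in_bins"]

log = logging.getLogger(__name__)

#: number of bins used when none is requested; at this resolution the human
#: genome yields a median bin of roughly 276 kbp
DEFAULT_N_BINS = 10_000


@dataclass(frozen=True)
class BinMap:
    """Ordered variable-size bins tiling the covered chromosomes."""

    chrom: np.ndarray = field(repr=False)   # str per bin
    start: np.ndarray = field(repr=False)   # int bp, 0-based
    end: np.ndarray = field(repr=False)     # int bp, half-open
    gc: np.ndarray = field(repr=False)      # fraction in [0,1]
    weight: np.ndarray = field(repr=False)  # expected read weight per bin

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of bin indices per chromosome, in bin order."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out[str(chroms[i])] = slice(i, j)
            i = j
        return out

    def to_bed(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "chrom": self.chrom,
            "start": self.start.astype(int),
            "end": self.end.astype(int),
            "name": np.arange(self.n_bins),
            "score": np.round(self.gc * 1000).astype(int),
        })
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, genome: GenomeModel | None = None) -> "BinMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score"])
        bm = cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            gc=df["score"].to_numpy(dtype=float) / 1000.0,
            weight=np.ones(len(df)),
        )
        if genome is not None:
            w = _bin_weights(genome, bm)
            object.__setattr__(bm, "weight", w)
        return bm


@dataclass(frozen=True)
class BinCounts:
    """Raw read counts aligned to a BinMap."""

    sample_id: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(~np.isfinite(c.astype(float))) or np.any(c < 0):
            raise ValueError("counts must be finite and >= 0")

    def to_tsv(self, path: str | Path, binmap: BinMap) -> None:
        pd.DataFrame({
            "chrom": binmap.chrom,
            "start": binmap.start.astype(int),
            "end": binmap.end.astype(int),
            "count": np.asarray(self.counts).astype(int),
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "BinCounts":
        df = pd.read_csv(path, sep="\t")
        sid = sample_id or Path(path).stem
        return cls(sample_id=sid, counts=df["count"].to_numpy(dtype=np.int64))


def _bin_weights(genome: GenomeModel, binmap: BinMap) -> np.ndarray:
    """Total mappability weight per bin (bins snap to window edges)."""
    w = np.empty(binmap.n_bins)
    ws = genome.window_size
    for i in range(binmap.n_bins):
        chrom = str(binmap.chrom[i])
        mp = genome.mappability[chrom]
        first = int(binmap.start[i]) // ws
        last = (int(binmap.end[i]) - 1) // ws
        w[i] = mp[first:last + 1].sum()
    return w


def build_variable_bins(genome: GenomeModel, n_bins: int = DEFAULT_N_BINS) -> BinMap:
    """Split the genome into ``n_bins`` bins of equal expected read weight.

    Bins are allocated to chromosomes proportionally to their total
    mappability weight (largest-remainder rounding, at least one bin per
    chromosome with positive weight).  Within a chromosome, bin *k* closes at
    the first window where the cumulative weight reaches ``k`` quanta, so
    every bin's weight differs from the quantum by less than one window's
    weight and residual weight carries into the next bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    totals = {c: float(genome.mappability[c].sum()) for c in genome.chrom_names}
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("genome has no positive mappability")
    n_pos_windows = sum(int((genome.mappability[c] > 0).sum()) for c in genome.chrom_names)
    if n_bins > n_pos_windows:
        raise ValueError(
            f"n_bins={n_bins} exceeds the {n_pos_windows} windows with positive weight"
        )

    # largest-remainder apportionment of bins to chromosomes
    chroms = [c for c in genome.chrom_names if totals[c] > 0]
    raw = {c: n_bins * totals[c] / grand for c in chroms}
    alloc = {c: max(1, int(raw[c])) for c in chroms}
    while sum(alloc.values()) > n_bins:  # possible when many tiny chromosomes forced to 1
        c = max((c for c in chroms if alloc[c] > 1), key=lambda c: alloc[c] - raw[c])
        alloc[c] -= 1
    remainders = sorted(chroms, key=lambda c: (raw[c] - int(raw[c]), c), reverse=True)
    i = 0
    while sum(alloc.values()) < n_bins:
        alloc[remainders[i % len(remainders)]] += 1
        i += 1

    rows_chrom: list[str] = []
    rows_start: list[int] = []
    rows_end: list[int] = []
    rows_w: list[float] = []
    ws = genome.window_size
    for chrom in chroms:
        mp = genome.mappability[chrom]
        k_bins = alloc[chrom]
        quantum = totals[chrom] / k_bins
        cum = np.cumsum(mp)
        starts = genome.window_starts(chrom)
        win_ends = starts + genome.window_lengths(chrom)
        bin_start_win = 0
        for k in range(1, k_bins + 1):
            if k == k_bins:
                close = len(mp) - 1
            else:
                # first window index where cumulative weight >= k quanta
                close = int(np.searchsorted(cum, k * quantum - 1e-12 * totals[chrom]))
                close = min(close, len(mp) - 1)
            rows_chrom.append(chrom)
            rows_start.append(int(starts[bin_start_win]))
            rows_end.append(int(win_ends[close]))
            prev = cum[bin_start_win - 1] if bin_start_win > 0 else 0.0
            rows_w.append(float(cum[close] - prev))
            bin_start_win = close + 1
        if bin_start_win != len(mp):  # pragma: no cover - defensive
            raise AssertionError("bins do not tile the chromosome")

    bm = BinMap(
        chrom=np.array(rows_chrom, dtype=object),
        start=np.array(rows_start, dtype=np.int64),
        end=np.array(rows_end, dtype=np.int64),
        gc=np.zeros(len(rows_chrom)),
        weight=np.array(rows_w),
    )
    gc = compute_bin_gc(genome, bm)
    object.__setattr__(bm, "gc", gc)
    return bm


def compute_bin_gc(genome: GenomeModel, binmap: BinMap) -> np.ndarray:
    """Per-bin GC as the window-length-weighted mean of window GC."""
    ws = genome.window_size
    out = np.empty(binmap.n_bins)
    for i in range(binmap.n_bins):
        chrom = str(binmap.chrom[i])
        gc = genome.gc[chrom]
        lens = genome.window_lengths(chrom)
        first = int(binmap.start[i]) // ws
        last = (int(binmap.end[i]) - 1) // ws
        seg_gc = gc[first:last + 1]
        seg_len = lens[first:last + 1].astype(float)
        out[i] = float(np.average(seg_gc, weights=seg_len))
    if np.any((out < 0) | (out > 1)):  # pragma: no cover - defensive
        raise AssertionError("bin GC outside [0, 1]")
    return out


def count_reads_in_bins(
    read_positions: pd.DataFrame | list[tuple[str, int]],
    binmap: BinMap,
    sample_id: str = "sample",
) -> BinCounts:
    """Assign each read start to the unique half-open bin containing it.

    ``read_positions`` is a DataFrame with columns ``chrom`` and ``pos`` (or a
    list of ``(chrom, pos)``).  Unsorted input is sorted internally with a
    logged notice.  Reads outside covered bins are dropped.
    """
    if not isinstance(read_positions, pd.DataFrame):
        read_positions = pd.DataFrame(read_positions, columns=["chrom", "pos"])
    counts = np.zeros(binmap.n_bins, dtype=np.int64)
    slices = binmap.chrom_slices()
    for chrom, grp in read_positions.groupby("chrom", sort=False):
        if chrom not in slices:
            continue
        sl = slices[chrom]
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            log.info("read positions on %s unsorted; sorting internally", chrom)
            pos = np.sort(pos)
        starts = binmap.start[sl]
        ends = binmap.end[sl]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        np.add.at(counts[sl.start:sl.stop], idx[ok], 1)
    return BinCounts(sample_id=sample_id, counts=counts)
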