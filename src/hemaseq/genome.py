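"""Synthetic genome models and ground-truth copy-number profiles.

A :class:`GenomeModel` is a stand-in for a reference genome annotated with the
two tracks that variable binning needs: per-window GC fraction and a
per-window expected uniquely-mapped read weight (a mappability surrogate).
A :class:`TruthProfile` records the integer copy number of every genomic
region for a simulated specimen; regions not covered by a segment sit at the
baseline ploidy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "TruthProfile", "make_genome"]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus fixed-window GC and mappability tracks.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    window_size
        Track resolution in bp; the last window of a chromosome may be
        shorter so that windows tile the chromosome exactly.
    gc : dict of str -> ndarray
        Per-window GC fraction in ``[0, 1]``.
    mappability : dict of str -> ndarray
        Per-window expected uniquely-mapped read weight, finite and >= 0.
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size: int
    gc: dict[str, np.ndarray] = field(repr=False)
    mappability: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            n_win = -(-length // self.window_size)
            for track, label in ((self.gc, "gc"), (self.mappability, "mappability")):
                if len(track[name]) != n_win:
                    raise ValueError(
                        f"{label} track of {name} has {len(track[name])} windows, "
                        f"expected {n_win}"
                    )
            g = np.asarray(self.gc[name], float)
            if np.any((g < 0) | (g > 1)):
                raise ValueError(f"GC values of {name} outside [0, 1]")
            m = np.asarray(self.mappability[name], float)
            if not np.all(np.isfinite(m)) or np.any(m < 0):
                raise ValueError(f"mappability of {name} must be finite and >= 0")
            if not np.any(m > 0):
                raise ValueError(f"chromosome {name} has no window with positive mappability")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def window_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.gc[chrom])) * self.window_size

    def window_lengths(self, chrom: str) -> np.ndarray:
        length = self.length_of(chrom)
        starts = self.window_starts(chrom)
        ends = np.minimum(starts + self.window_size, length)
        return ends - starts

    # -- serialization: JSON manifest + one TSV per track --------------------

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        manifest = {
            "chromosomes": [[n, int(l)] for n, l in self.chromosomes],
            "window_size": int(self.window_size),
        }
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.genome.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        rows = []
        for chrom, _ in self.chromosomes:
            starts = self.window_starts(chrom)
            lens = self.window_lengths(chrom)
            for s, ln, g, m in zip(starts, lens, self.gc[chrom], self.mappability[chrom]):
                rows.append((chrom, int(s), int(s + ln), float(g), float(m)))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "mappability"]).to_csv(
            f"{prefix}.tracks.tsv", sep="\t", index=False
        )

    @classmethod
    def from_files(cls, prefix: str | Path) -> "GenomeModel":
        with open(f"{prefix}.genome.json") as fh:
            manifest = json.load(fh)
        tracks = pd.read_csv(f"{prefix}.tracks.tsv", sep="\t")
        gc = {c: g["gc"].to_numpy() for c, g in tracks.groupby("chrom", sort=False)}
        mp = {c: g["mappability"].to_numpy() for c, g in tracks.groupby("chrom", sort=False)}
        return cls(
            chromosomes=tuple((n, int(l)) for n, l in manifest["chromosomes"]),
            window_size=int(manifest["window_size"]),
            gc=gc,
            mappability=mp,
        )


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth integer copy number, half-open segments over a genome.

    ``segments`` holds ``(chrom, start, end, copy_number)``; anything not
    covered is at ``ploidy_baseline`` (near-diploid default 2).
    """

    segments: tuple[tuple[str, int, int, int], ...]
    ploidy_baseline: int = 2

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.segments:
            if end <= start:
                raise ValueError(f"empty segment {chrom}:{start}-{end}")
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping truth segments on {chrom}")

    def mean_cn(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean copy number over [start, end)."""
        total = (end - start) * self.ploidy_baseline
        for c, s, e, cn in self.segments:
            if c != chrom:
                continue
            ov = min(end, e) - max(start, s)
            if ov > 0:
                total += ov * (cn - self.ploidy_baseline)
        return total / (end - start)


def _gc_values(model: dict, starts: np.ndarray, length: int) -> np.ndarray:
    kind = model.get("kind", "constant")
    x = (starts + 0.5 * np.minimum(np.diff(np.append(starts, length)), length)) / length
    if kind == "constant":
        vals = np.full(len(starts), float(model.get("value", 0.41)))
    elif kind in ("linear", "linear-gradient"):
        lo = float(model.get("start", 0.3))
        hi = float(model.get("stop", 0.6))
        vals = lo + (hi - lo) * x
    elif kind == "sinusoid":
        mean = float(model.get("mean", 0.45))
        amp = float(model.get("amplitude", 0.1))
        period = float(model.get("period", 0.25))  # fraction of chromosome
        vals = mean + amp * np.sin(2 * np.pi * x / period)
    else:
        raise ValueError(f"unknown gc model kind {kind!r}")
    return np.clip(vals, 0.0, 1.0)


def _mappability_values(model: dict, starts: np.ndarray, win_lens: np.ndarray,
                        length: int) -> np.ndarray:
    kind = model.get("kind", "uniform")
    # weight scales with window length so partial tail windows do not over-count
    rel = win_lens / win_lens.max()
    if kind == "uniform":
        return float(model.get("weight", 1.0)) * rel
    if kind == "step":
        # step at a fractional breakpoint: weight `high` before, `low` after
        frac = float(model.get("breakpoint", 0.5))
        high = float(model.get("high", 1.0))
        low = float(model.get("low", 0.5))
        vals = np.where(starts < frac * length, high, low)
        return vals * rel
    raise ValueError(f"unknown mappability model kind {kind!r}")


def make_genome(
    n_chromosomes: int,
    lengths: Sequence[int],
    gc_model: dict | None = None,
    mappability_model: dict | None = None,
    window_size: int = 1000,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> GenomeModel:
    """Build a synthetic genome with deterministic GC and mappability tracks.

    ``gc_model`` is ``{"kind": "constant"|"linear-gradient"|"sinusoid", ...}``
    and ``mappability_model`` is ``{"kind": "uniform"|"step", ...}``; both
    tracks are deterministic functions of position, so the same call always
    yields byte-identical tracks (``seed`` is accepted for interface symmetry
    with the stochastic simulators and reserved for future noisy tracks).
    """
    if len(lengths) != n_chromosomes:
        raise ValueError("lengths must have one entry per chromosome")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    gc_model = gc_model or {"kind": "constant", "value": 0.41}
    mappability_model = mappability_model or {"kind": "uniform"}

    chroms: list[tuple[str, int]] = []
    gc: dict[str, np.ndarray] = {}
    mp: dict[str, np.ndarray] = {}
    for name, length in zip(names, lengths):
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {length}")
        length = int(length)
        chroms.append((name, length))
        starts = np.arange(0, length, window_size)
        win_lens = np.minimum(starts + window_size, length) - starts
        gc[name] = _gc_values(dict(gc_model), starts, length)
        mp[name] = _mappability_values(dict(mappability_model), starts, win_lens, length)
    return GenomeModel(chromosomes=tuple(chroms), window_size=window_size, gc=gc, mappability=mp)
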