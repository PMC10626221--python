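"""Seeded simulators for bin counts, variant-locus reads, and FISH tallies.

These emulate the three data modalities the pipeline consumes:

* per-bin read counts under a known integer copy-number profile, with a
  multiplicative quadratic GC bias and negative-binomial overdispersion
  (variance mu + alpha*mu^2; alpha = 0 degenerates to Poisson);
* reads overlapping a single variant locus at a set allele fraction and
  per-base error rate;
* multinomial FISH cell tallies split into scoring classes (plasma cells vs
  the rest).

Every simulator takes an explicit seed and touches no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinMap
from .genome import GenomeModel, TruthProfile
from .variants import LocusReadSet

__all__ = ["simulate_bin_counts", "simulate_locus_reads", "simulate_fish_tally",
           "simulate_read_positions"]


def _expected_bin_counts(
    genome: GenomeModel,
    binmap: BinMap,
    truth: TruthProfile,
    total_reads: int,
    gc_bias: tuple[float, float, float],
) -> np.ndarray:
    for i in range(binmap.n_bins):
        chrom = str(binmap.chrom[i])
        if chrom not in genome.gc:
            raise ValueError(f"bin on {chrom} outside the genome")
        if binmap.end[i] > genome.length_of(chrom):
            raise ValueError(f"bin {chrom}:{binmap.start[i]}-{binmap.end[i]} outside the genome")
    cn = np.array([
        truth.mean_cn(str(binmap.chrom[i]), int(binmap.start[i]), int(binmap.end[i]))
        for i in range(binmap.n_bins)
    ])
    b0, b1, b2 = gc_bias
    bias = np.maximum(0.0, b0 + b1 * binmap.gc + b2 * binmap.gc**2)
    raw = (cn / truth.ploidy_baseline) * binmap.weight * bias
    if raw.sum() <= 0:
        raise ValueError("expected counts are all zero; check truth/bias")
    return total_reads * raw / raw.sum()


def simulate_bin_counts(
    genome: GenomeModel,
    binmap: BinMap,
    truth: TruthProfile,
    total_reads: int,
    gc_bias: tuple[float, float, float] = (1.0, 0.0, 0.0),
    dispersion: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-bin raw read counts under a known copy-number truth.

    The expected count of bin *i* is proportional to
    ``(CN_i / ploidy) * weight_i * max(0, b0 + b1*gc_i + b2*gc_i^2)``,
    normalized so expectations sum to ``total_reads``.  Counts are drawn
    negative-binomially with variance ``mu + dispersion*mu^2``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mu = _expected_bin_counts(genome, binmap, truth, total_reads, gc_bias)
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        return rng.poisson(mu).astype(np.int64)
    # NB as gamma-mixed Poisson: shape r = 1/alpha, scale mu*alpha
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam).astype(np.int64)


def simulate_read_positions(
    genome: GenomeModel,
    truth: TruthProfile,
    total_reads: int,
    seed: int = 0,
) -> "np.ndarray":
    """Draw read start positions window-wise (mappability x CN weighted).

    Returns a record array with fields ``chrom`` (object) and ``pos`` (int),
    sorted by chromosome then position; a convenience front-end for
    :func:`hemaseq.binning.count_reads_in_bins`.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    frames = []
    weights = []
    metas = []
    for chrom, _ in genome.chromosomes:
        starts = genome.window_starts(chrom)
        lens = genome.window_lengths(chrom)
        mp = genome.mappability[chrom]
        cn = np.array([truth.mean_cn(chrom, int(s), int(s + l))
                       for s, l in zip(starts, lens)])
        w = mp * cn / truth.ploidy_baseline
        weights.append(w)
        metas.append((chrom, starts, lens))
    allw = np.concatenate(weights)
    p = allw / allw.sum()
    draws = rng.multinomial(total_reads, p)
    offset = 0
    for chrom, starts, lens in metas:
        k = len(starts)
        n_per_win = draws[offset:offset + k]
        offset += k
        for s, l, n in zip(starts, lens, n_per_win):
            if n:
                pos = s + rng.integers(0, l, size=n)
                frames.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos)}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos"])
    return pd.concat(frames, ignore_index=True)


def simulate_locus_reads(
    depth: int,
    vaf: float,
    error_rate: float,
    seed: int = 0,
    chrom: str = "chr1",
    position: int = 1,
    mean_baseq: float = 35.0,
    sd_baseq: float = 4.0,
) -> LocusReadSet:
    """Simulate reads covering one variant locus.

    Each read's true allele is ``alt`` with probability ``vaf``; sequencing
    error then flips the observed allele (ref <-> alt) with probability
    ``error_rate``.  Base qualities are drawn from a clipped normal.  A depth
    of 0 yields an empty read set.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    if depth == 0:
        return LocusReadSet(chrom=chrom, position=position, reads=())
    is_alt = rng.random(depth) < vaf
    flip = rng.random(depth) < error_rate
    observed_alt = is_alt ^ flip
    quals = np.clip(np.round(rng.normal(mean_baseq, sd_baseq, size=depth)), 2, 60)
    reads = tuple(
        ("alt" if a else "ref", int(q)) for a, q in zip(observed_alt, quals)
    )
    return LocusReadSet(chrom=chrom, position=position, reads=reads)


def simulate_fish_tally(
    true_fractions: dict[str, float],
    n_cells: int,
    cell_class_fractions: dict[str, float] | None = None,
    seed: int = 0,
    probe: str = "probe",
) -> dict[str, dict[str, int]]:
    """Multinomial FISH cell tallies per scoring class.

    ``true_fractions`` maps signal-pattern labels (e.g. ``"3 copies"``,
    ``"normal"``) to population fractions summing to 1.  Cells are first
    split multinomially into scoring classes (default: 10% plasma cells,
    90% non-PC, mirroring a marrow with a plasma-cell clone), then each
    class's cells are assigned patterns multinomially.  Returns
    ``{class: {pattern: count}}``; per-class counts sum to that class's cell
    count and overall to ``n_cells``.
    """
    fracs = np.array(list(true_fractions.values()), float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("pattern fractions must sum to 1")
    if cell_class_fractions is None:
        cell_class_fractions = {"PC": 0.1, "non-PC": 0.9}
    cf = np.array(list(cell_class_fractions.values()), float)
    if abs(cf.sum() - 1.0) > 1e-9:
        raise ValueError("cell class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    class_counts = rng.multinomial(n_cells, cf)
    out: dict[str, dict[str, int]] = {}
    patterns = list(true_fractions.keys())
    for cls, n_cls in zip(cell_class_fractions.keys(), class_counts):
        draws = rng.multinomial(int(n_cls), fracs)
        out[cls] = {p: int(c) for p, c in zip(patterns, draws)}
    return out
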