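"""Copy-number calling from per-bin read counts.

Pipeline: GC normalization (lowess, quadratic fallback) -> conversion to the
chromosomal copy-number scale assuming near-diploidy (median density maps to
the baseline ploidy) -> circular binary segmentation with a
permutation-calibrated max-t split statistic -> MergeLevels (rank-sum merging
of statistically indistinguishable segment levels) -> per-segment integer
copy-number calls -> aberration extraction (whole-chromosome / arm-level /
focal, with field-style labels like "polysomy 8" or "20q deletion").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinMap, BinCounts

__all__ = [
    "Segment", "CopyNumberProfile", "AberrationCall",
    "gc_normalize", "to_copy_number_scale", "cbs_segment", "merge_levels",
    "call_segment_cn", "extract_aberrations", "call_copy_number",
]

log = logging.getLogger(__name__)


@dataclass
class Segment:
    """Half-open bin-index segment with its level and integer call."""

    start: int                 # first bin index
    end: int                   # one past the last bin index
    mean: float = float("nan")  # mean CN ratio of the segment's own bins
    level: int = -1            # merged level id (shared across segments)
    level_mean: float = float("nan")
    call: int = -1             # integer CN of the level

    @property
    def last(self) -> int:
        """Last bin index, inclusive."""
        return self.end - 1


@dataclass
class CopyNumberProfile:
    sample_id: str
    density: np.ndarray = field(repr=False)   # GC-normalized, mean 1
    cn: np.ndarray = field(repr=False)        # chromosomal copy-number scale
    segments: list[Segment] = field(default_factory=list)
    ploidy_baseline: int = 2

    def bin_calls(self) -> np.ndarray:
        """Integer CN per bin, broadcast from segment calls."""
        out = np.empty(len(self.cn), dtype=int)
        for seg in self.segments:
            out[seg.start:seg.end] = seg.call
        return out

    def segments_frame(self, binmap: BinMap) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            rows.append({
                "chrom": binmap.chrom[seg.start],
                "start": int(binmap.start[seg.start]),
                "end": int(binmap.end[seg.end - 1]),
                "first_bin": seg.start,
                "last_bin": seg.last,
                "mean_cn": seg.mean,
                "level": seg.level,
                "integer_cn": seg.call,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AberrationCall:
    kind: str          # whole-chromosome gain/loss, arm-level gain/loss, focal
    chromosome: str
    arm: str | None    # "p"/"q" for arm-level, None otherwise
    interval: tuple[int, int] | None  # bp for focal calls
    cn: int
    label: str

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# normalization and scaling


def gc_normalize(
    counts: BinCounts | np.ndarray,
    gc: np.ndarray,
    method: str = "lowess",
    span: float = 0.3,
) -> np.ndarray:
    """Divide counts by a smooth fit of count on GC; rescale to mean 1.

    The fitted curve is floored at the 1st percentile of its positive values
    so no bin is divided by (near-)zero.  With fewer than 10 bins, curve
    fitting is meaningless and a global-mean normalization is used instead
    (with a warning).
    """
    x = np.asarray(counts.counts if isinstance(counts, BinCounts) else counts, float)
    gc = np.asarray(gc, float)
    if len(x) != len(gc):
        raise ValueError("counts and gc must be aligned")
    if len(x) < 10:
        warnings.warn("fewer than 10 bins; falling back to global-mean normalization")
        fitted = np.full(len(x), x.mean())
    elif method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        order = np.argsort(gc, kind="stable")
        sm = lowess(x[order], gc[order], frac=span, return_sorted=False)
        fitted = np.empty_like(sm)
        fitted[order] = sm
    elif method == "quadratic":
        coef = np.polynomial.polynomial.polyfit(gc, x, 2)
        fitted = np.polynomial.polynomial.polyval(gc, coef)
    else:
        raise ValueError(f"unknown GC normalization method {method!r}")
    pos = fitted[fitted > 0]
    floor = np.percentile(pos, 1) if pos.size else 1.0
    fitted = np.where(fitted > 0, fitted, floor)  # only degenerate fits are floored
    density = x / fitted
    return density / density.mean()


def to_copy_number_scale(density: np.ndarray, ploidy_baseline: int = 2) -> np.ndarray:
    """Scale densities so the median sits at the baseline ploidy.

    Idempotent: applying it twice equals applying it once.
    """
    d = np.asarray(density, float)
    med = np.median(d)
    if med <= 0:
        raise ValueError("median density must be > 0")
    return ploidy_baseline * d / med


# --------------------------------------------------------------------------
# segmentation


def _max_t_split(x: np.ndarray, min_width: int) -> tuple[float, int]:
    """Best single split of ``x`` by the pooled two-sample t statistic.

    Returns ``(|t|, k)`` maximizing over ``min_width <= k <= n - min_width``
    (split before index ``k``); ``(0.0, -1)`` when no admissible split.
    """
    n = len(x)
    if n < 2 * min_width:
        return 0.0, -1
    s = np.cumsum(x)
    q = np.cumsum(x * x)
    ks = np.arange(min_width, n - min_width + 1)
    s1 = s[ks - 1]
    q1 = q[ks - 1]
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = s1 / n1
    m2 = (s[-1] - s1) / n2
    ss1 = q1 - s1 * s1 / n1
    ss2 = (q[-1] - q1) - (s[-1] - s1) ** 2 / n2
    dof = n - 2
    sp2 = np.maximum(ss1 + ss2, 0.0) / dof
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / denom
    t = np.where(denom == 0, np.where(np.abs(m1 - m2) > 0, np.inf, 0.0), t)
    i = int(np.argmax(t))
    return float(t[i]), int(ks[i])


def _permutation_p_exceeds(
    x: np.ndarray,
    observed: float,
    min_width: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
) -> bool:
    """True iff the permutation p-value of ``observed`` is < alpha.

    Sequential early stop: once the hit count can no longer fall below the
    alpha threshold, the split is rejected without running the remaining
    permutations.
    """
    reject_at = alpha * (n_permutations + 1)  # p >= alpha once hits+1 >= this
    hits = 0
    for b in range(n_permutations):
        perm = rng.permutation(x)
        t, _ = _max_t_split(perm, min_width)
        if t >= observed:
            hits += 1
            if hits + 1 >= reject_at:
                return False
    return (hits + 1) / (n_permutations + 1) < alpha


def _segment_one(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
    out: list[Segment],
) -> None:
    t, k = _max_t_split(x, min_width)
    if k > 0 and np.isfinite(t) and t > 0 and _permutation_p_exceeds(
        x, t, min_width, n_permutations, alpha, rng
    ):
        _segment_one(x[:k], offset, alpha, n_permutations, min_width, rng, out)
        _segment_one(x[k:], offset + k, alpha, n_permutations, min_width, rng, out)
    else:
        out.append(Segment(start=offset, end=offset + len(x), mean=float(np.mean(x))))


def cbs_segment(
    cn: np.ndarray,
    chrom: np.ndarray | None = None,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> list[Segment]:
    """Segment per-bin CN ratios by recursive permutation-calibrated splitting.

    Each chromosome is segmented independently.  At every recursion the
    two-sample pooled t statistic is maximized over admissible breakpoints
    (both parts at least ``min_width`` bins); the split is accepted iff its
    within-segment permutation p-value is below ``alpha``.  The output
    partitions every chromosome.
    """
    cn = np.asarray(cn, float)
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives unstable p-values")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    if chrom is None:
        _segment_one(cn, 0, alpha, n_permutations, min_width, rng, segments)
    else:
        chrom = np.asarray(chrom, dtype=object)
        i = 0
        while i < len(chrom):
            j = i
            while j < len(chrom) and chrom[j] == chrom[i]:
                j += 1
            if j - i < 2:
                raise ValueError(f"chromosome {chrom[i]} has fewer than 2 bins")
            _segment_one(cn[i:j], i, alpha, n_permutations, min_width, rng, segments)
            i = j
    segments.sort(key=lambda s: s.start)
    return segments


# --------------------------------------------------------------------------
# MergeLevels


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == (a[0] if a.size else 0)) and np.all(b == (b[0] if b.size else 0)) \
            and a.size and b.size and a[0] == b[0]:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def merge_levels(
    segments: list[Segment],
    cn: np.ndarray,
    merge_p_threshold: float = 1e-4,
) -> list[Segment]:
    """Coarsen segment levels by merging statistically indistinguishable ones.

    Iteratively the pair of distinct levels with the closest means is tested
    by the Wilcoxon rank-sum on their bins' CN ratios; if ``p`` exceeds the
    threshold the two levels merge and means recompute.  Segment boundaries
    never change; only level ids coarsen.  Level ids are renumbered 0..L-1 in
    order of increasing level mean.
    """
    cn = np.asarray(cn, float)
    # level id -> member segment indices
    levels: dict[int, list[int]] = {i: [i] for i in range(len(segments))}

    def level_values(lid: int) -> np.ndarray:
        return np.concatenate([cn[segments[i].start:segments[i].end] for i in levels[lid]])

    changed = True
    while changed and len(levels) > 1:
        changed = False
        ids = sorted(levels)
        means = {lid: float(level_values(lid).mean()) for lid in ids}
        pairs = sorted(
            ((a, b) for ai, a in enumerate(ids) for b in ids[ai + 1:]),
            key=lambda ab: (abs(means[ab[0]] - means[ab[1]]), ab),
        )
        for a, b in pairs:
            p = _ranksum_p(level_values(a), level_values(b))
            if p > merge_p_threshold:
                levels[a].extend(levels[b])
                del levels[b]
                changed = True
                break

    # renumber by increasing mean, annotate segments
    order = sorted(levels, key=lambda lid: float(level_values(lid).mean()))
    for new_id, lid in enumerate(order):
        vals = level_values(lid)
        for i in levels[lid]:
            seg = segments[i]
            seg.level = new_id
            seg.level_mean = float(vals.mean())
            seg.mean = float(cn[seg.start:seg.end].mean())
    return segments


def call_segment_cn(segments: list[Segment]) -> list[Segment]:
    """Integer CN per segment: round-half-even of the merged level mean."""
    for seg in segments:
        mean = seg.level_mean if np.isfinite(seg.level_mean) else seg.mean
        seg.call = max(0, int(np.round(mean)))  # numpy rounds half to even
    return segments


# --------------------------------------------------------------------------
# aberration extraction


def _chrom_token(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def extract_aberrations(
    profile: CopyNumberProfile,
    binmap: BinMap,
    arm_boundaries: dict[str, int] | None = None,
    fraction: float = 0.9,
) -> list[AberrationCall]:
    """Classify off-baseline copy number as whole-chromosome, arm-level, or focal.

    A whole-chromosome call requires at least ``fraction`` of the
    chromosome's bins to share one off-baseline integer CN; an arm-level
    call, the same for a p/q arm (``arm_boundaries`` maps chromosome name to
    its centromere position in bp).  Remaining off-baseline runs become
    focal calls.  Without arm annotation only whole-chromosome and focal
    calls are made (logged).
    """
    if arm_boundaries is None:
        arm_boundaries = {}
        log.info("no arm annotation; emitting whole-chromosome and focal calls only")
    ploidy = profile.ploidy_baseline
    calls: list[AberrationCall] = []
    bin_cn = profile.bin_calls()
    for chrom, sl in binmap.chrom_slices().items():
        vals = bin_cn[sl.start:sl.stop]
        tok = _chrom_token(chrom)
        covered = np.zeros(len(vals), bool)
        off = vals != ploidy
        if not off.any():
            continue
        # whole-chromosome
        uniq, cnts = np.unique(vals[off], return_counts=True)
        top_cn = int(uniq[np.argmax(cnts)])
        if (vals == top_cn).sum() >= fraction * len(vals):
            kind = "whole-chromosome gain" if top_cn > ploidy else "whole-chromosome loss"
            label = (f"polysomy {tok}" if top_cn > ploidy
                     else f"monosomy {tok}" if top_cn == ploidy - 1
                     else f"loss of {tok}")
            calls.append(AberrationCall(kind, chrom, None, None, top_cn, label))
            covered |= vals == top_cn
        elif chrom in arm_boundaries:
            cen = arm_boundaries[chrom]
            starts = binmap.start[sl]
            arms = {"p": starts < cen, "q": starts >= cen}
            for arm, in_arm in arms.items():
                if not in_arm.any():
                    continue
                av = vals[in_arm]
                aoff = av != ploidy
                if not aoff.any():
                    continue
                u, c = np.unique(av[aoff], return_counts=True)
                cn_arm = int(u[np.argmax(c)])
                if (av == cn_arm).sum() >= fraction * in_arm.sum():
                    kind = "arm-level gain" if cn_arm > ploidy else "arm-level loss"
                    label = f"{tok}{arm} {'gain' if cn_arm > ploidy else 'deletion'}"
                    calls.append(AberrationCall(kind, chrom, arm, None, cn_arm, label))
                    covered |= in_arm & (vals == cn_arm)
        # focal: remaining off-baseline runs
        for i0, i1 in _runs(off & ~covered):
            cn_f = int(np.round(np.mean(vals[i0:i1])))
            if cn_f == ploidy:
                cn_f = int(vals[i0])
            bp0 = int(binmap.start[sl.start + i0])
            bp1 = int(binmap.end[sl.start + i1 - 1])
            word = "gain" if cn_f > ploidy else "loss"
            calls.append(AberrationCall(
                "focal", chrom, None, (bp0, bp1), cn_f,
                f"focal {word} {tok}:{bp0}-{bp1} (CN {cn_f})",
            ))
    return calls


# --------------------------------------------------------------------------
# one-call pipeline


def call_copy_number(
    counts: BinCounts,
    binmap: BinMap,
    ploidy_baseline: int = 2,
    gc_method: str = "lowess",
    gc_span: float = 0.3,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 3,
    merge_p_threshold: float = 1e-4,
    seed: int = 0,
) -> CopyNumberProfile:
    """Full counts-to-integer-CN pipeline on one sample."""
    density = gc_normalize(counts, binmap.gc, method=gc_method, span=gc_span)
    cn = to_copy_number_scale(density, ploidy_baseline)
    segments = cbs_segment(cn, chrom=binmap.chrom, alpha=alpha,
                           n_permutations=n_permutations, min_width=min_width, seed=seed)
    segments = merge_levels(segments, cn, merge_p_threshold)
    segments = call_segment_cn(segments)
    return CopyNumberProfile(
        sample_id=counts.sample_id, density=density, cn=cn,
        segments=segments, ploidy_baseline=ploidy_baseline,
    )
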