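"""GC normalization, CN scaling, segmentation, level merging, aberration calls."""

import numpy as np
import pytest

from hemaseq.binning import BinCounts, build_variable_bins
from hemaseq.cna import (Segment, call_copy_number, call_segment_cn, cbs_segment,
                         extract_aberrations, gc_normalize, merge_levels,
                         to_copy_number_scale)
from hemaseq.genome import TruthProfile, make_genome
from hemaseq.simulate import simulate_bin_counts


def exhaustive_max_t_changepoint(x: np.ndarray, min_width: int = 3) -> int:
    """Oracle: argmax over single changepoints of the pooled two-sample |t|."""
    n = len(x)
    best_t, best_k = -1.0, -1
    for k in range(min_width, n - min_width + 1):
        a, b = x[:k], x[k:]
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n - 2)
        t = abs(a.mean() - b.mean()) / np.sqrt(sp2 * (1 / k + 1 / (n - k)))
        if t > best_t:
            best_t, best_k = t, k
    return best_k


class TestGcNormalize:
    def test_gc_independent_counts_stay_flat(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, 200)
        counts = np.full(200, 100.0)
        density = gc_normalize(counts, gc)
        assert np.all(np.abs(density - 1.0) < 0.01)

    @pytest.mark.parametrize("method", ["lowess", "quadratic"])
    def test_injected_linear_bias_removed(self, method):
        rng = np.random.default_rng(1)
        gc = np.sort(rng.uniform(0.3, 0.7, 300))
        counts = 100.0 * (1 + 2 * (gc - 0.5))  # closed-form bias, no noise
        density = gc_normalize(counts, gc, method=method)
        assert np.all(np.abs(density - 1.0) < 0.01)

    def test_mean_is_one_after_rescale(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.6, 100)
        counts = rng.poisson(100, 100).astype(float)
        assert gc_normalize(counts, gc).mean() == pytest.approx(1.0, abs=1e-6)

    def test_few_bins_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            density = gc_normalize(np.array([5.0] * 5), np.array([0.4] * 5))
        assert np.allclose(density, 1.0)


class TestCopyNumberScale:
    def test_constant_density_maps_to_baseline(self):
        cn = to_copy_number_scale(np.ones(50), 2)
        assert np.allclose(cn, 2.0)

    def test_linearity(self):
        d = np.ones(100)
        d[:10] = 1.5
        cn = to_copy_number_scale(d, 2)
        assert np.allclose(cn[:10], 3.0)
        assert np.allclose(cn[10:], 2.0)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        d = rng.gamma(5, 0.2, 200)
        once = to_copy_number_scale(d, 2)
        twice = to_copy_number_scale(once, 2)
        assert np.allclose(once, twice)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            to_copy_number_scale(np.zeros(10))

    def test_trisomy_recovery_from_simulated_counts(self, gradient_genome,
                                                    gradient_binmap, desk_truth):
        counts = simulate_bin_counts(gradient_genome, gradient_binmap, desk_truth,
                                     1_000_000, dispersion=0.02, seed=9)
        density = gc_normalize(counts, gradient_binmap.gc)
        cn = to_copy_number_scale(density, 2)
        sl = gradient_binmap.chrom_slices()["chr2"]
        assert 2.8 <= cn[sl].mean() <= 3.2


class TestCbsSegment:
    def test_constant_series_single_segment(self):
        segs = cbs_segment(np.full(80, 2.0), seed=1)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 80)

    def test_single_step_breakpoint_matches_oracle(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([np.full(50, 2.0), np.full(50, 3.0)]) + rng.normal(0, 0.1, 100)
        segs = cbs_segment(x, seed=11)
        assert len(segs) == 2
        k = segs[0].end
        assert 49 <= k <= 51
        assert k == exhaustive_max_t_changepoint(x)

    def test_two_step_recovery_monte_carlo(self):
        # 2.0 -> 3.0 -> 2.0 over 40/30/30 bins, sd 0.1: both breakpoints
        # within +/-2 bins in >= 95/100 seeded runs
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            x = np.concatenate([np.full(40, 2.0), np.full(30, 3.0), np.full(30, 2.0)])
            x = x + rng.normal(0, 0.1, 100)
            segs = cbs_segment(x, seed=s)
            bps = sorted(seg.end for seg in segs[:-1])
            ok = (len(bps) == 2 and abs(bps[0] - 40) <= 2 and abs(bps[1] - 70) <= 2)
            hits += ok
        assert hits >= 95

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        x = rng.normal(2, 0.3, 120)
        chrom = np.array(["chr1"] * 60 + ["chr2"] * 60, dtype=object)
        segs = cbs_segment(x, chrom=chrom, seed=4)
        covered = sorted((s.start, s.end) for s in segs)
        pos = 0
        for s, e in covered:
            assert s == pos
            pos = e
        assert pos == 120
        # chromosomes segmented independently: no segment crosses the boundary
        assert any(e == 60 for _, e in covered)

    def test_low_permutations_warns(self):
        with pytest.warns(UserWarning, match="permutations"):
            cbs_segment(np.full(20, 1.0), n_permutations=50, seed=0)


class TestMergeLevels:
    def test_identical_distributions_merge_to_one_level(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(2, 0.1, 50)
        cn = np.concatenate([vals, vals])
        segs = [Segment(0, 50), Segment(50, 100)]
        merged = merge_levels(segs, cn)
        assert merged[0].level == merged[1].level

    def test_close_pair_merges_distant_level_stays(self):
        rng = np.random.default_rng(6)
        cn = np.concatenate([
            rng.normal(2.00, 0.10, 50),
            rng.normal(2.02, 0.10, 50),
            rng.normal(3.00, 0.10, 50),
        ])
        segs = [Segment(0, 50), Segment(50, 100), Segment(100, 150)]
        merged = merge_levels(segs, cn, merge_p_threshold=1e-4)
        assert merged[0].level == merged[1].level
        assert merged[2].level != merged[0].level
        assert len({s.level for s in merged}) == 2

    def test_single_segment_unchanged(self):
        cn = np.full(30, 2.0)
        merged = merge_levels([Segment(0, 30)], cn)
        assert len(merged) == 1 and merged[0].level == 0

    def test_level_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        cn = np.concatenate([rng.normal(m, 0.15, 40) for m in (2.0, 2.3, 2.6, 3.2)])
        segs_proto = [(0, 40), (40, 80), (80, 120), (120, 160)]
        n_levels = []
        for thr in (1e-8, 1e-4, 1e-2, 0.2):
            segs = [Segment(s, e) for s, e in segs_proto]
            merged = merge_levels(segs, cn, merge_p_threshold=thr)
            n_levels.append(len({s.level for s in merged}))
        assert n_levels == sorted(n_levels, reverse=True)


class TestCallSegmentCn:
    @pytest.mark.parametrize("mean,call", [(2.97, 3), (2.5, 2), (3.5, 4), (0.2, 0)])
    def test_round_half_even(self, mean, call):
        seg = Segment(0, 10, mean=mean, level=0, level_mean=mean)
        assert call_segment_cn([seg])[0].call == call

    def test_bin_level_recovery_on_simulation(self, gradient_genome,
                                              gradient_binmap, desk_truth):
        counts = simulate_bin_counts(gradient_genome, gradient_binmap, desk_truth,
                                     1_000_000, dispersion=0.02, seed=21)
        profile = call_copy_number(BinCounts("s", counts), gradient_binmap, seed=21)
        bm = gradient_binmap
        truth_bins = np.array([
            round(desk_truth.mean_cn(str(bm.chrom[i]), int(bm.start[i]), int(bm.end[i])))
            for i in range(bm.n_bins)
        ])
        assert (profile.bin_calls() == truth_bins).mean() >= 0.95


class TestExtractAberrations:
    def _profile(self, binmap, bin_cn):
        segs = []
        i = 0
        while i < len(bin_cn):
            j = i
            while (j < len(bin_cn) and bin_cn[j] == bin_cn[i]
                   and binmap.chrom[j] == binmap.chrom[i]):
                j += 1
            segs.append(Segment(i, j, mean=float(bin_cn[i]), level=0,
                                level_mean=float(bin_cn[i]), call=int(bin_cn[i])))
            i = j
        from hemaseq.cna import CopyNumberProfile
        return CopyNumberProfile("s", np.ones(len(bin_cn)),
                                 np.asarray(bin_cn, float), segs)

    def test_whole_chromosome_gain_labelled_polysomy(self, gradient_binmap):
        cn = np.full(gradient_binmap.n_bins, 2)
        sl = gradient_binmap.chrom_slices()["chr3"]
        cn[sl] = 3
        calls = extract_aberrations(self._profile(gradient_binmap, cn), gradient_binmap)
        assert len(calls) == 1
        assert calls[0].kind == "whole-chromosome gain"
        assert calls[0].label == "polysomy 3"

    def test_q_arm_loss_labelled_deletion(self, gradient_binmap, gradient_genome):
        cn = np.full(gradient_binmap.n_bins, 2)
        sl = gradient_binmap.chrom_slices()["chr4"]
        mid = (sl.start + sl.stop) // 2
        cn[mid:sl.stop] = 1
        cen = {"chr4": gradient_genome.length_of("chr4") // 2}
        calls = extract_aberrations(self._profile(gradient_binmap, cn),
                                    gradient_binmap, arm_boundaries=cen)
        assert [c.label for c in calls] == ["4q deletion"]
        assert calls[0].kind == "arm-level loss"

    def test_all_baseline_gives_empty_list(self, gradient_binmap):
        cn = np.full(gradient_binmap.n_bins, 2)
        assert extract_aberrations(self._profile(gradient_binmap, cn),
                                   gradient_binmap) == []

    def test_focal_event_reported_with_interval(self, gradient_binmap):
        cn = np.full(gradient_binmap.n_bins, 2)
        cn[10:14] = 4
        calls = extract_aberrations(self._profile(gradient_binmap, cn), gradient_binmap)
        assert len(calls) == 1
        assert calls[0].kind == "focal"
        assert calls[0].cn == 4
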