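"""Variant filtering, rescue, read-level presence, and VAF trajectories."""

import numpy as np
import pytest

from hemaseq.datasets import SPECIMEN_DAYS, case_variants
from hemaseq.simulate import simulate_locus_reads
from hemaseq.variants import (LocusReadSet, SpecimenObservation, VariantRecord,
                              dlp_variant_presence, filter_annotation,
                              filter_somatic, read_variants_tsv,
                              read_variants_vcf, vaf_trajectory,
                              write_variants_tsv, write_variants_vcf)


def make_variant(gene="GENE", pos=100, consequence="missense", maf=0.0, obs=None):
    return VariantRecord(
        gene=gene, cdna="c.1A>G", chrom="chr1", pos=pos, ref="A", alt="G",
        consequence=consequence, maf=maf, observations=obs or {},
    )


class TestFilterAnnotation:
    @pytest.mark.parametrize("consequence,maf,expected", [
        ("missense", 0.0001, "pass"),
        ("synonymous", 0.0, "excluded:synonymous"),
        ("noncoding", 0.0, "excluded:noncoding"),
        ("missense", 0.02, "excluded:common"),
        ("nonsense", 0.01, "pass"),  # threshold is "> 1%", boundary retained
    ])
    def test_rules(self, consequence, maf, expected):
        [v] = filter_annotation([make_variant(consequence=consequence, maf=maf)])
        assert v.filter_status["annotation"] == expected


class TestFilterSomatic:
    def test_passing_record(self):
        v = make_variant(obs={"s1": SpecimenObservation(300, 15, 15 / 300)})
        [out] = filter_somatic([v])
        assert out.filter_status["s1"] == "pass"

    def test_failing_record_without_companion_excluded(self):
        v = make_variant(obs={"s1": SpecimenObservation(200, 8, 8 / 200)})
        [out] = filter_somatic([v])
        assert out.filter_status["s1"].startswith("excluded:")
        assert "vaf" in out.filter_status["s1"]

    def test_serial_rescue_of_subthreshold_early_specimens(self):
        # rising clone: 3.6 -> 4.4 -> 9.5 -> 12.4 % at 500x
        obs = {}
        for spec, vafpct in zip(SPECIMEN_DAYS, (3.6, 4.4, 9.5, 12.4)):
            alt = round(vafpct / 100 * 500)
            obs[spec] = SpecimenObservation(500, alt, alt / 500)
        [out] = filter_somatic([make_variant(obs=obs)])
        assert out.filter_status["specimen1"] == "rescued"
        assert out.filter_status["specimen2"] == "rescued"
        assert out.filter_status["specimen3"] == "pass"
        assert out.filter_status["specimen4"] == "pass"

    def test_any_rule_is_more_permissive(self):
        # both specimens fail the full criteria; one meets a single threshold
        obs = {"s1": SpecimenObservation(300, 8, 8 / 300),
               "s2": SpecimenObservation(100, 4, 4 / 100)}
        [full] = filter_somatic([make_variant(obs=obs)], rescue_rule="full")
        assert all(s.startswith("excluded") for s in full.filter_status.values())
        [anyr] = filter_somatic([make_variant(obs=obs)], rescue_rule="any")
        assert all(s == "rescued" for s in anyr.filter_status.values())

    def test_idempotence(self):
        variants = case_variants()
        once = filter_somatic(variants)
        twice = filter_somatic(once)
        assert [v.filter_status for v in twice] == [v.filter_status for v in once]

    def test_rescue_never_demotes_a_pass(self):
        for v in filter_somatic(case_variants()):
            for spec, obs in v.observations.items():
                if obs.alt_depth >= 10 and obs.vaf >= 0.05 and obs.total_depth >= 250:
                    assert v.filter_status[spec] == "pass"

    def test_duplicate_records_merged(self, caplog):
        a = make_variant(obs={"s1": SpecimenObservation(300, 20, 20 / 300)})
        b = make_variant(obs={"s2": SpecimenObservation(300, 30, 30 / 300)})
        with caplog.at_level("WARNING"):
            out = filter_somatic([a, b])
        assert len(out) == 1
        assert set(out[0].observations) == {"s1", "s2"}


class TestDlpPresence:
    def test_no_reads_uncallable(self):
        call = dlp_variant_presence(LocusReadSet("chr1", 1, ()))
        assert call.status == "uncallable"

    def test_all_ref_absent(self):
        reads = LocusReadSet("chr1", 1, tuple(("ref", 30) for _ in range(10)))
        call = dlp_variant_presence(reads)
        assert call.status == "absent" and call.n_total == 10

    def test_simulated_present_within_binomial_interval(self):
        rs = simulate_locus_reads(depth=30, vaf=0.2, error_rate=0.001, seed=5)
        call = dlp_variant_presence(rs, min_baseq=0)
        assert call.status == "present"
        # 99% binomial interval around 6 alt reads
        sd = np.sqrt(30 * 0.2 * 0.8)
        assert abs(call.n_alt - 6) <= 2.58 * sd + 1

    def test_low_quality_bases_dropped(self):
        reads = LocusReadSet("chr1", 1, (("alt", 5), ("ref", 30)))
        call = dlp_variant_presence(reads, min_alt_reads=1, min_baseq=20)
        assert call.status == "absent" and call.n_total == 1

    def test_false_present_rate_bounded(self):
        # vaf 0, error 0.001, depth 30, min_alt_reads 2: <= 0.001 over 10,000 sims
        hits = 0
        for s in range(10_000):
            rs = simulate_locus_reads(depth=30, vaf=0.0, error_rate=0.001, seed=s)
            if dlp_variant_presence(rs, min_alt_reads=2, min_baseq=0).status == "present":
                hits += 1
        assert hits / 10_000 <= 0.001


class TestVafTrajectory:
    def _variant_with_vafs(self, vafs):
        obs = {}
        for spec, vp in zip(SPECIMEN_DAYS, vafs):
            if vp is not None:
                alt = round(vp / 100 * 1000)
                obs[spec] = SpecimenObservation(1000, alt, alt / 1000)
        return make_variant(obs=obs)

    def test_rising_series_persisting(self):
        traj = vaf_trajectory(self._variant_with_vafs((3.6, 4.4, 9.5, 12.4)),
                              SPECIMEN_DAYS)
        assert traj.label == "persisting"
        assert [p.vaf_percent for p in traj.points] == [3.6, 4.4, 9.5, 12.4]

    def test_cleared_at_last_specimen(self):
        traj = vaf_trajectory(self._variant_with_vafs((4.7, 2.6, 2.5, None)),
                              SPECIMEN_DAYS)
        assert traj.label == "cleared"
        assert traj.points[-1].vaf_percent is None

    def test_single_specimen_trivially_persisting(self):
        v = self._variant_with_vafs((5.0,))
        traj = vaf_trajectory(v, {"specimen1": 0})
        assert traj.label == "persisting"

    def test_emergent_variant(self):
        traj = vaf_trajectory(self._variant_with_vafs((None, None, 6.0, 9.0)),
                              SPECIMEN_DAYS)
        assert traj.label == "emergent"


class TestVariantIO:
    def test_tsv_roundtrip(self, tmp_path):
        variants = case_variants()
        path = tmp_path / "v.tsv"
        write_variants_tsv(variants, path)
        back = read_variants_tsv(path)
        assert len(back) == len(variants)
        orig = {v.key: v for v in variants}
        for v in back:
            assert v.observations == orig[v.key].observations

    def test_vcf_roundtrip_via_pysam(self, tmp_path):
        variants = case_variants()
        path = tmp_path / "v.vcf"
        write_variants_vcf(variants, path)
        back = read_variants_vcf(path)
        assert len(back) == len(variants)
        orig = {v.key: v for v in variants}
        for v in back:
            ref = orig[v.key]
            assert v.gene == ref.gene
            for spec, obs in ref.observations.items():
                got = v.observations[spec]
                assert got.total_depth == obs.total_depth
                assert got.alt_depth == obs.alt_depth
                assert got.vaf == pytest.approx(obs.vaf, abs=1e-3)
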