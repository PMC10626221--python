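"""Targeted-sequencing variant filtering and read-level presence calling.

Implements the filtering strategy used for serial bone-marrow specimens:

* annotation filter — drop synonymous and non-coding variants and anything
  with population minor-allele frequency above 1%;
* somatic depth filter with a rescue rule — per specimen a variant needs
  alt depth >= 10, VAF >= 5% and total depth >= 250; a failing record is
  rescued when the identical variant (same chrom/pos/ref/alt) fully passes
  in at least one other specimen of the same case, so sub-threshold early
  timepoints of a rising clone are retained;
* read-level presence calling for sparse pooled-cell libraries — after
  dropping low-quality bases, a variant is present when at least
  ``min_alt_reads`` alt-supporting reads remain;
* VAF trajectories over serial specimens with persisting / cleared /
  emergent labels.

VAF is stored as a fraction internally and rendered as a percentage with one
decimal in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenObservation", "VariantRecord", "LocusReadSet", "PresenceCall",
    "filter_annotation", "filter_somatic", "dlp_variant_presence",
    "vaf_trajectory", "read_variants_vcf", "write_variants_vcf",
    "read_variants_tsv", "write_variants_tsv",
]

log = logging.getLogger(__name__)

EXCLUDED_CONSEQUENCES = {"synonymous", "noncoding"}


@dataclass(frozen=True)
class SpecimenObservation:
    total_depth: int
    alt_depth: int
    vaf: float  # fraction

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError("alt depth exceeds total depth")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("VAF must be in [0, 1]")
        if self.total_depth > 0 and abs(self.vaf - self.alt_depth / self.total_depth) > 0.005:
            raise ValueError("VAF inconsistent with alt/total depths")


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    cdna: str                      # HGVS-like, e.g. "c.679A>G"
    chrom: str
    pos: int                       # 1-based
    ref: str
    alt: str
    consequence: str = "missense"  # synonymous|missense|nonsense|noncoding|other
    maf: float = 0.0               # population minor allele frequency
    observations: dict[str, SpecimenObservation] = field(default_factory=dict)
    filter_status: dict[str, str] = field(default_factory=dict)  # pass|excluded:*|rescued

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: genomic coordinates plus alleles."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def vaf_percent(self, specimen: str) -> float | None:
        obs = self.observations.get(specimen)
        return None if obs is None else round(obs.vaf * 100, 1)


@dataclass(frozen=True)
class LocusReadSet:
    """Reads overlapping one locus: (allele, base quality) per read."""

    chrom: str
    position: int
    reads: tuple[tuple[str, int], ...]
    source_population: str = ""

    def __post_init__(self) -> None:
        for allele, q in self.reads:
            if allele not in ("ref", "alt", "other"):
                raise ValueError(f"allele must be ref/alt/other, got {allele!r}")
            if q < 0:
                raise ValueError("base quality must be >= 0")


@dataclass(frozen=True)
class PresenceCall:
    status: Literal["present", "absent", "uncallable"]
    n_alt: int
    n_total: int


# --------------------------------------------------------------------------
# filtering


def filter_annotation(
    variants: Iterable[VariantRecord],
    maf_threshold: float = 0.01,
) -> list[VariantRecord]:
    """Keep protein-altering rare variants; annotate exclusion reasons.

    Excludes synonymous and non-coding variants and those with population
    MAF above the threshold.  Missing MAF is treated as 0 with a logged
    notice.  Every record is returned with a ``filter_status["annotation"]``
    entry; callers typically keep the ``"pass"`` ones.
    """
    out = []
    for v in variants:
        maf = v.maf
        if maf is None or (isinstance(maf, float) and np.isnan(maf)):
            log.info("variant %s %s has no MAF; treating as 0", v.gene, v.cdna)
            maf = 0.0
        if v.consequence in EXCLUDED_CONSEQUENCES:
            status = f"excluded:{v.consequence}"
        elif maf > maf_threshold:
            status = "excluded:common"
        else:
            status = "pass"
        out.append(replace(v, filter_status={**v.filter_status, "annotation": status}))
    return out


def _passes(obs: SpecimenObservation, alt_depth_min: int, vaf_min: float,
            total_depth_min: int) -> bool:
    return (obs.alt_depth >= alt_depth_min and obs.vaf >= vaf_min
            and obs.total_depth >= total_depth_min)


def _passes_any(obs: SpecimenObservation, alt_depth_min: int, vaf_min: float,
                total_depth_min: int) -> bool:
    return (obs.alt_depth >= alt_depth_min or obs.vaf >= vaf_min
            or obs.total_depth >= total_depth_min)


def filter_somatic(
    variants: Iterable[VariantRecord],
    alt_depth_min: int = 10,
    vaf_min: float = 0.05,
    total_depth_min: int = 250,
    rescue_rule: Literal["full", "any"] = "full",
) -> list[VariantRecord]:
    """Per-specimen depth/VAF filter with cross-specimen rescue.

    A specimen-level observation passes iff alt depth, VAF and total depth
    all meet their thresholds.  A failing observation is *rescued* when the
    same variant qualifies in at least one other specimen of the case:
    under the default ``rescue_rule="full"`` the companion must pass all
    three thresholds; under ``"any"`` meeting any single threshold suffices.
    Rescue never demotes a passing observation.  Records sharing a variant
    key are merged (with a warning) before filtering, so the rescue sees all
    specimens.
    """
    merged: dict[tuple, VariantRecord] = {}
    for v in variants:
        if v.key in merged:
            log.warning("duplicate records for %s:%d %s>%s merged",
                        v.chrom, v.pos, v.ref, v.alt)
            prev = merged[v.key]
            merged[v.key] = replace(prev, observations={**prev.observations, **v.observations})
        else:
            merged[v.key] = v

    qualifies = _passes if rescue_rule == "full" else _passes_any
    out = []
    for v in merged.values():
        statuses = dict(v.filter_status)
        any_qualifying = any(
            qualifies(o, alt_depth_min, vaf_min, total_depth_min)
            for o in v.observations.values()
        )
        for spec, obs in v.observations.items():
            if _passes(obs, alt_depth_min, vaf_min, total_depth_min):
                statuses[spec] = "pass"
            elif any_qualifying:
                statuses[spec] = "rescued"
            else:
                reasons = []
                if obs.alt_depth < alt_depth_min:
                    reasons.append("alt_depth")
                if obs.vaf < vaf_min:
                    reasons.append("vaf")
                if obs.total_depth < total_depth_min:
                    reasons.append("total_depth")
                statuses[spec] = "excluded:" + ",".join(reasons)
        out.append(replace(v, filter_status=statuses))
    return out


# --------------------------------------------------------------------------
# read-level presence


def dlp_variant_presence(
    reads: LocusReadSet,
    variant: VariantRecord | None = None,
    min_alt_reads: int = 1,
    min_baseq: int = 20,
) -> PresenceCall:
    """Call variant presence in a sparse pooled-cell read set.

    Bases below ``min_baseq`` are dropped; ``present`` requires at least
    ``min_alt_reads`` alt reads among the survivors, ``absent`` requires at
    least one surviving read, and an empty read set is ``uncallable``.
    """
    if variant is not None and (reads.chrom != variant.chrom
                                or reads.position != variant.pos):
        raise ValueError("read set does not overlap the variant locus")
    kept = [(a, q) for a, q in reads.reads if q >= min_baseq]
    n_total = len(kept)
    n_alt = sum(1 for a, _ in kept if a == "alt")
    if n_total == 0:
        return PresenceCall("uncallable", 0, 0)
    if n_alt >= min_alt_reads:
        return PresenceCall("present", n_alt, n_total)
    return PresenceCall("absent", n_alt, n_total)


# --------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class TrajectoryPoint:
    specimen: str
    day: int
    vaf_percent: float | None  # None = not detected

    @property
    def detected(self) -> bool:
        return self.vaf_percent is not None


@dataclass(frozen=True)
class VafTrajectory:
    gene: str
    cdna: str
    points: tuple[TrajectoryPoint, ...]
    label: str  # persisting | cleared | emergent | not detected


def vaf_trajectory(
    variant: VariantRecord,
    specimen_days: dict[str, int],
) -> VafTrajectory:
    """Order a variant's VAFs by days after diagnosis and label its course.

    ``persisting`` — detected at the last timepoint (and at the first, or
    throughout); ``emergent`` — undetected at first but detected at the last;
    ``cleared`` — detected earlier but not at the last timepoint;
    ``not detected`` — never seen.  A single specimen is trivially
    ``persisting`` when detected.
    """
    order = sorted(specimen_days, key=lambda s: specimen_days[s])
    points = []
    for spec in order:
        obs = variant.observations.get(spec)
        vp = None if obs is None or obs.alt_depth == 0 else round(obs.vaf * 100, 1)
        points.append(TrajectoryPoint(spec, specimen_days[spec], vp))
    detected = [p.detected for p in points]
    if not any(detected):
        label = "not detected"
    elif detected[-1]:
        label = "persisting" if detected[0] or len(points) == 1 else "emergent"
    else:
        label = "cleared"
    return VafTrajectory(variant.gene, variant.cdna, tuple(points), label)


# --------------------------------------------------------------------------
# I/O: minimal VCF 4.2 (CHROM POS REF ALT; DP/AD/AF per sample) and TSV


def write_variants_vcf(variants: list[VariantRecord], path: str | Path,
                       specimens: list[str] | None = None) -> None:
    if specimens is None:
        seen: list[str] = []
        for v in variants:
            for s in v.observations:
                if s not in seen:
                    seen.append(s)
        specimens = seen
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=hemaseq",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA change">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Population MAF">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(specimens),
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        info = f"GENE={v.gene};CDNA={v.cdna};CSQ={v.consequence};MAF={v.maf:g}"
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", info, "DP:AD:AF"]
        for s in specimens:
            obs = v.observations.get(s)
            if obs is None:
                fields.append(".:.:.")
            else:
                ref_d = obs.total_depth - obs.alt_depth
                fields.append(f"{obs.total_depth}:{ref_d},{obs.alt_depth}:{obs.vaf:.4f}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a minimal VCF via pysam; per-sample DP/AD/AF become observations."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            info = rec.info
            observations = {}
            for s in samples:
                smp = rec.samples[s]
                dp = smp.get("DP")
                if dp is None:
                    continue
                ad = smp.get("AD")
                alt_d = int(ad[1]) if ad is not None and len(ad) > 1 and ad[1] is not None else 0
                af = smp.get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                vaf = float(af) if af is not None else (alt_d / dp if dp else 0.0)
                observations[s] = SpecimenObservation(int(dp), alt_d, vaf)
            out.append(VariantRecord(
                gene=str(info.get("GENE", "")),
                cdna=str(info.get("CDNA", "")),
                chrom=rec.chrom, pos=rec.pos,
                ref=rec.ref, alt=rec.alts[0] if rec.alts else "",
                consequence=str(info.get("CSQ", "other")),
                maf=float(info.get("MAF", 0.0)),
                observations=observations,
            ))
    return out


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        for spec, obs in v.observations.items():
            rows.append({
                "gene": v.gene, "cdna": v.cdna, "chrom": v.chrom, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "consequence": v.consequence,
                "maf": v.maf, "specimen": spec,
                "total_depth": obs.total_depth, "alt_depth": obs.alt_depth,
                "vaf": obs.vaf,
                "status": v.filter_status.get(spec, v.filter_status.get("annotation", "")),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    grouped: dict[tuple, VariantRecord] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        obs = SpecimenObservation(int(row["total_depth"]), int(row["alt_depth"]),
                                  float(row["vaf"]))
        if key in grouped:
            grouped[key].observations[str(row["specimen"])] = obs
        else:
            grouped[key] = VariantRecord(
                gene=str(row["gene"]), cdna=str(row["cdna"]),
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                consequence=str(row.get("consequence", "other")),
                maf=float(row.get("maf", 0.0)),
                observations={str(row["specimen"]): obs},
            )
    return list(grouped.values())
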