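"""End-to-end orchestration: simulate -> bin -> CNA -> QC -> aberrations,
and the consolidated clinical-style case report.

All stage parameters live in a single validated :class:`RunConfig`
(unknown keys are rejected); every output file carries the config echo and
the package version so runs are reproducible and self-describing.
"""

from __future__ import annotations

import json
import logging
from importlib import metadata
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import binning, cna, qc
from .cytogenetics import (CutoffTable, apply_cutoff, format_ratio,
                           load_default_cutoffs, parse_iscn, ratio_nonpc_pc)
from .lineage import check_perfect_phylogeny, infer_clone_tree, load_template, map_to_template
from .variants import filter_annotation, filter_somatic, vaf_trajectory

log = logging.getLogger(__name__)


def _version() -> str:
    try:
        return metadata.version("hemaseq")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


class RunConfig(BaseModel):
    """All pipeline parameters; unknown keys are rejected on load."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    counts_path: str | None = None
    binmap_path: str | None = None
    out_dir: str = "hemaseq_out"

    n_bins: int = binning.DEFAULT_N_BINS
    ploidy_baseline: int = 2
    gc_method: str = "lowess"
    gc_span: float = 0.3
    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 3
    merge_p_threshold: float = 1e-4

    alt_depth_min: int = 10
    vaf_min: float = 0.05
    total_depth_min: int = 250
    maf_threshold: float = 0.01
    rescue_rule: str = "full"

    cutoff_table_path: str | None = None
    template_variant: str = "classical"

    def echo(self) -> dict:
        return {"config": self.model_dump(), "hemaseq_version": _version()}

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def run_cna(config: RunConfig):
    """Counts -> profile, QC report and aberration calls, written to disk.

    Requires ``counts_path`` (TSV: chrom/start/end/count) and
    ``binmap_path`` (BED5).  Returns ``(profile, qc_report, aberrations)``.
    """
    if config.counts_path is None or not Path(config.counts_path).exists():
        raise FileNotFoundError(f"counts file not found: {config.counts_path}")
    if config.binmap_path is None or not Path(config.binmap_path).exists():
        raise FileNotFoundError(f"binmap file not found: {config.binmap_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    binmap = binning.BinMap.from_bed(config.binmap_path)
    counts = binning.BinCounts.from_tsv(config.counts_path)
    if len(counts.counts) != binmap.n_bins:
        raise ValueError("counts length does not match the binmap")
    log.info("cna: %d bins, sample %s", binmap.n_bins, counts.sample_id)

    profile = cna.call_copy_number(
        counts, binmap,
        ploidy_baseline=config.ploidy_baseline,
        gc_method=config.gc_method, gc_span=config.gc_span,
        alpha=config.alpha, n_permutations=config.n_permutations,
        min_width=config.min_width, merge_p_threshold=config.merge_p_threshold,
        seed=config.seed,
    )
    report = qc.qc_report(counts.counts, sample_id=counts.sample_id)
    aberrations = cna.extract_aberrations(profile, binmap)

    seg = profile.segments_frame(binmap)
    seg.to_csv(out / "segments.tsv", sep="\t", index=False)
    with open(out / "qc.json", "w") as fh:
        json.dump({**report.to_dict(), **config.echo()}, fh, indent=1)
    with open(out / "aberrations.json", "w") as fh:
        json.dump({"calls": [a.to_dict() for a in aberrations], **config.echo()},
                  fh, indent=1, default=list)
    return profile, report, aberrations


def run_case_report(
    fish_tallies: dict,
    karyotypes: dict[str, str],
    variants: list,
    matrix,
    specimen_days: dict[str, int],
    config: RunConfig,
) -> dict:
    """Consolidated serial-specimen report: FISH, karyotypes, variants, tree.

    ``fish_tallies`` follows the :func:`hemaseq.datasets.case_fish_tallies`
    layout.  Writes a report JSON plus the clone tree (Newick + JSON) under
    ``config.out_dir`` and returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cutoffs = (load_default_cutoffs() if config.cutoff_table_path is None
               else CutoffTable.from_json(config.cutoff_table_path))

    fish_rows = []
    for spec, probes in fish_tallies.items():
        for probe_pattern, cells in probes.items():
            row = {"specimen": spec, "probe_pattern": probe_pattern}
            for cls in ("TNC", "PC", "non-PC"):
                cell = cells.get(cls)
                if cell is None:
                    continue
                pct = cell.tally.percent
                row[f"{cls}_percent"] = pct
                row[f"{cls}_counts"] = f"{cell.tally.positive}/{cell.tally.scored}"
                if cls == "TNC":
                    row["cutoff_flag"] = apply_cutoff(
                        pct, probe_pattern, cell.tally.scored, cutoffs)
            ratio = cells.get("ratio")
            if ratio is not None:
                row["nonpc_pc_ratio"] = format_ratio(
                    ratio_nonpc_pc(ratio.non_pc_positive, ratio.pc_positive))
            fish_rows.append(row)

    karyotype_rows = {}
    for spec, text in karyotypes.items():
        kt = parse_iscn(text)
        karyotype_rows[spec] = {
            "n_clones": len(kt.clones),
            "clones": [
                {
                    "modal_count": list(c.modal_count)
                    if isinstance(c.modal_count, tuple) else c.modal_count,
                    "cell_count": c.cell_count,
                    "composite": c.composite,
                    "aberrations": [a.render() for a in kt.resolved_aberrations(i)],
                }
                for i, c in enumerate(kt.clones)
            ],
            "unparsed": kt.unparsed,
        }

    variant_rows = []
    if variants:
        annotated = filter_annotation(variants, config.maf_threshold)
        kept = [v for v in annotated if v.filter_status["annotation"] == "pass"]
        filtered = filter_somatic(
            kept, config.alt_depth_min, config.vaf_min, config.total_depth_min,
            rescue_rule=config.rescue_rule,  # type: ignore[arg-type]
        )
        for v in filtered:
            traj = vaf_trajectory(v, specimen_days)
            variant_rows.append({
                "gene": v.gene, "cdna": v.cdna,
                "vaf_percent": {p.specimen: p.vaf_percent for p in traj.points},
                "status": {s: st for s, st in v.filter_status.items()
                           if s != "annotation"},
                "trajectory": traj.label,
            })

    tree_block = None
    if matrix is not None:
        compat = check_perfect_phylogeny(matrix)
        if compat == "compatible":
            tree = infer_clone_tree(matrix)
            tree = map_to_template(tree, load_template(config.template_variant))
            (out / "clone_tree.nwk").write_text(tree.to_newick() + "\n")
            tree_block = {"compatible": True, "tree": tree.to_dict()}
        else:
            tree_block = {"compatible": False, "conflicts": [list(c) for c in compat]}

    report = {
        "fish": fish_rows,
        "karyotypes": karyotype_rows,
        "variants": variant_rows,
        "lineage": tree_block,
        **config.echo(),
    }
    with open(out / "case_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
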