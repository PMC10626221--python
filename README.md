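# hemaseq

Tools for resolving the clonal architecture of hematologic neoplasms from
sparse whole-genome sequencing of small, cytogenetically sorted cell pools —
the setting where a few dozen FISH- or morphology-identified marrow cells
(plasma cells, myeloblasts, neutrophils, erythrocytes, ...) are isolated
from stained smears and sequenced at shallow depth without whole-genome
amplification.

The package covers the full downstream computational workflow:

* **Copy-number calling** from per-bin read counts: the genome is split into
  *variable-size bins* holding an equal expected number of uniquely mapped
  reads, so read density is proportional to copy number. Counts are
  GC-normalized (lowess), scaled so the median bin sits at the baseline
  ploidy (near-diploid assumption, `cn_i = 2 · d_i / median(d)`), segmented
  by circular binary segmentation with a permutation-calibrated max-*t*
  split statistic, coarsened by **MergeLevels** (Wilcoxon rank-sum merging of
  statistically indistinguishable segment levels), and called to integer CN
  per segment. Whole-chromosome, arm-level and focal aberrations are labeled
  in the field's idiom ("polysomy 8", "20q deletion").
* **QC metrics**: coefficient of variation (sd/mean of bin counts) and MAPD
  on mean-scaled adjacent-bin differences `d_i = (x_{i+1} − x_i)/mean(x)`,
  in both the `Median(|d − Median(d)|)` and `Median(|d|)` readings.
* **Variant analysis** for serial targeted-sequencing specimens: annotation
  filters (synonymous/non-coding/MAF > 1% excluded), the somatic depth
  filter (alt ≥ 10, VAF ≥ 5%, depth ≥ 250) with a cross-specimen *rescue*
  rule that retains sub-threshold timepoints of variants qualifying
  elsewhere in the series, read-level presence calling in sparse pooled-cell
  libraries, and VAF trajectory labels (persisting / cleared / emergent).
* **Cytogenetics**: an ISCN karyotype parser (gains, losses, deletions,
  `idem`/`sl`/`sdl` stemline references, `slx2` doubling, composite `[cp]`
  clones, modal ranges) and FISH tally arithmetic with probe-specific,
  scored-cell-dependent cutoffs.
* **Clonal lineage inference**: binary aberration-groups × populations
  matrices are tested for perfect-phylogeny compatibility (supports must
  form a laminar family), the unique clone tree is built, and its edges are
  mapped onto classical or composite hematopoiesis templates
  (HSC → MPP → LMPP/CMP → ...).
* A **synthetic-data module** simulates every input: per-bin counts under a
  known integer CN profile with multiplicative GC bias and negative-binomial
  overdispersion (`var = μ + αμ²`), variant-locus read sets at a set VAF and
  error rate, and multinomial FISH tallies — all seeded and reproducible.

## Worked example

`examples/` holds one short script per capability. For instance, copy-number
calling on a simulated pool with a chr2 trisomy and a chr4q loss
(`python examples/01_copy_number_calling.py`) prints:

```
bins: 500, reads: 1,000,048
CV = 0.307  MAPD(paper) = 0.125  MAPD(standard) = 0.126
integer-CN accuracy vs simulated truth: 100.0%
segments (chrom, bins, level mean, integer CN):
   chr1 bins   0- 99  mean 1.97 -> CN 2
   chr2 bins 100-199  mean 3.05 -> CN 3
   ...
aberration calls:
  whole-chromosome gain: polysomy 2
  arm-level loss: 4q deletion
```

Every bin receives the correct integer copy number, the arm-level breakpoint
lands on the true arm boundary, and the aberrations are labeled the way a
cytogenetics report would state them. `examples/04_clonal_lineage.py` builds
the clone tree of the packaged worked-example case; its shared root edge
carries only change A — both the myeloma plasma cells and the AML
myeloblasts descend from one A-bearing progenitor, placed at the LMPP level
of the classical hematopoiesis model.

A thin CLI mirrors the pipeline stages:

```sh
hemaseq simulate --out-prefix sim --seed 2
hemaseq cna --counts sim.counts.tsv --binmap sim.bins.bed --seed 2
hemaseq fish --positive 44 --scored 200 --probe-pattern "TCF3 3 copies"
hemaseq lineage --out tree.nwk
hemaseq report
```

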