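# songqtl

Quantitative-genetic and population-genetic analysis of *Drosophila
melanogaster* courtship-song trait differentiation between an
ancestral-range population (Zambia, ZI) and a derived European population
(France, FR).

Male flies "sing" by wing vibration in two modes — continuous sine song and
pulsed song, the latter split into slow and fast pulse classes — and
recording rigs plus automated segmentation reduce each 30-minute assay to
~37 quantitative traits.  `songqtl` takes such replicate trait tables (and
companion genomic inputs) through a complete mapping pipeline:

* **trait_io** — replicate exclusion rules (≥ 1 s song/min, ≤ 55 s sine
  total), strain trait means with per-trait zero exclusion, Pearson
  trait–trait correlations with significance tiers;
* **popdiff** — Mann–Whitney population comparisons (exact two-sided p by
  dynamic programming when tie-free), a min-p family-wise permutation
  correction with one shared strain relabeling per permutation, and
  Q_ST = V_b/(V_b + V_w) located within a per-SNP F_ST distribution matched
  to the phenotyped sample sizes;
* **qtl_scan** — an additive single-QTL genome scan over RIL
  ancestry-window dosages, LOD = −(n/2)·log₁₀(1−R²), with phenotype
  permutations for the genome-wide threshold and effect sizes as the
  fitted homozygote contrast |2β̂|/|Δ| relative to the parental difference;
* **qtl_peaks** — peak calling with the 1.5-LOD merge rule (peaks merge
  when the valley stays above the shorter peak's max − 1.5), contiguous
  *inclusive* and possibly noncontiguous *restrictive* confidence
  intervals, and CI extension through ancestry-skewed masked windows;
* **residual_map** — residual trait construction for correlated trait
  pairs, re-mapped with fresh permutation thresholds to separate pleiotropy
  from distinct linked loci;
* **popgen_scan** — Hudson-form F_ST per window (ratio-of-averages and
  max-SNP variants) and comparative haplotype identity (chi_MD) with
  per-arm top-1% outlier flags;
* **annotate** — exon-overlap and nearest-exon gene–window association
  with curated candidate-list flags;
* **synthetic_data** — generators for every input (ancestry mosaics from a
  12-generation intercross, replicate trait records, FR/ZI strain panels,
  Balding–Nichols haplotype panels with optional sweeps, gene models) with
  ground-truth records for recovery tests.

A thin CLI (`songqtl filter|means|correlations|popdiff|qst|scan|peaks|
residual|popgen|annotate|simulate`) wraps the library for shell pipelines;
all formats are plain text (TSV, BED, GFF3, VCF).

## Worked example

Simulate the study design — 305 RILs, 500 ancestry windows, one planted QTL
whose homozygote contrast is 42% of the parental strain difference in the
slow-pulse fraction — then scan, threshold and call peaks:

```python
import numpy as np
from songqtl import synthetic_data as sd, qtl_scan, qtl_peaks

cfg = sd.SimConfig(qtls=(sd.QtlSpec(window=250, effect_fraction=0.42),))
panel, _ = sd.simulate_ril_panel(cfg, seed=1)
records, table, truth = sd.simulate_ril_traits(panel, cfg, seed=2)

y = table.means["slow_pulse_fraction"].loc[[str(r) for r in panel.ril_ids]].values
mask = qtl_scan.mask_skewed_windows(panel)             # >90% ancestry skew
profile = qtl_scan.additive_lod_scan(panel, y, mask=mask)
perm = qtl_scan.permutation_threshold(panel, y, n_perm=1000, seed=3, mask=mask)
profile.threshold, profile.perm_maxima = perm.threshold, perm.maxima

for region in qtl_peaks.call_qtl_regions(profile):
    eff = qtl_scan.qtl_effect_size(panel.dosage[:, region.peak_index], y,
                                   cfg.parent_fr_value, cfg.parent_zi_value)
    print(f"QTL on {region.arm}: peak window {region.peak_index}, "
          f"max LOD {region.max_lod:.1f} (threshold {perm.threshold:.2f}, "
          f"genome-wide p {region.genome_wide_p:.3f})")
    print(f"  effect: {100 * eff.fraction:.0f}% of the parental difference")
```

prints

```
QTL on 2R: peak window 250, max LOD 14.8 (threshold 3.07, genome-wide p 0.000)
  effect: 45% of the parental difference
```

— the scan recovers the planted window exactly: its LOD towers over the
permutation threshold (none of 1,000 shuffled phenotypes produced a maximum
this high, hence p = 0.000 at 1/1000 resolution), and the effect estimate
(45%) sits within sampling error of the planted 42%.

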