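# nichepart

Quantitative tools for studying how closely related gut bacteria coexist —
or competitively exclude each other — across serial-passage experiments.
The motivating system is the honey-bee gut, where four *Lactobacillus*
species (Lapi, Lhel, Lmel, Lkul) share a niche that depends on the host's
pollen diet: on a single simple sugar one species excludes the rest, while
pollen's diverse substrates support stable four-species coexistence through
resource partitioning. The package is for microbial ecologists who run
defined-community transfer experiments (in gnotobiotic hosts or culture
tubes) and profile them with strain-resolved amplicon sequencing, total-load
counting, and metabolomics.

Four modules cover the chain end to end:

* **`nichepart.amplicon`** — paired-end amplicon reads → per-sample strain
  counts: barcode demultiplexing, Trimmomatic-style quality trimming
  (LEADING/TRAILING/SLIDINGWINDOW/MINLEN), best-ungapped-overlap mate
  merging with quality-aware consensus, and assignment by the bases at
  discriminatory SNP positions of a shared 199-bp marker (`MarkerPanel`).
* **`nichepart.dynamics`** — strain proportions x total load (CFU or qPCR)
  → absolute abundance trajectories; per-replicate limit of detection
  `LOD = total_load / assigned_read_depth` (the one-read equivalent) with
  t-based mean confidence intervals; community stability = temporal mean /
  temporal SD over a sliding window of passages (default 5, step 1);
  persistence summaries.
* **`nichepart.metabolomics`** — technical-replicate merging with
  correlation reporting; per-ion Student's t-tests with Benjamini–Hochberg
  correction within species (significant decrease: log2FC ≤ −1, adjusted
  p ≤ 0.01); pollen-derived-ion classification from a 2x dilution series
  (linear fit R² > 0.75 and pollen-vs-water log2FC > 2); species-specificity
  tallies of depleted ions; GC-MS internal-standard normalization and
  fold changes (|log2FC| ≥ 2, adjusted p ≤ 0.01 at 24 h).
* **`nichepart.simulate`** — ground-truthed synthetic data: a batch
  consumer-resource serial-passage model (resources allocated
  proportionally to abundance x affinity, Poisson transfer bottleneck) with
  exclusion/partition/in-vivo presets, an amplicon read simulator with
  per-base errors, log-normally noisy total loads, and a metabolome
  simulator with pollen dilution series and designed per-species depletion.

## Worked example

Simulate the pollen-like regime (four exclusive resources, 21 passages at a
1:20 bottleneck), sequence the final passage at depth 10⁴ with 0.1% per-base
error, and push the reads through the full pipeline:

```python
import numpy as np
from nichepart import (default_panel, scenario, simulate_passages,
                       simulate_reads, simulate_totals, count_sample,
                       relative_abundance, absolute_abundance,
                       detection_limit, community_stability)

panel = default_panel()
model, design = scenario("partition", seed=1, n_replicates=1)
truth = simulate_passages(model, design)
rng = np.random.default_rng(1)
totals = simulate_totals(truth.abundances, design.cfu_cv, rng)

pairs, _ = simulate_reads(truth.abundances[0, 20], panel, depth=10_000,
                          error_rate=0.001, seed=rng, sample_id="P21")
counts = count_sample("P21", pairs, panel)
props = relative_abundance(counts)
load = totals[0, 20]
abund = absolute_abundance(props, load)
lod = detection_limit(load, counts.assigned_depth)

print(f"passage 21 load: {load:.3g} cells/ml, assigned reads: {counts.assigned_depth}")
for s in panel.strain_names:
    print(f"  {s}: proportion {props[s]:.3f}  abundance {abund[s]:.3g}  (LOD {lod:.3g})")
stab = community_stability(truth.abundances[0], window=5)
print(f"stability, first window (P1-P5): {stab[0].stability:.1f}")
print(f"stability, last window (P17-P21): {stab[-1].stability:.1f}")
```

Output:

```
passage 21 load: 2.58e+09 cells/ml, assigned reads: 9962
  Lapi: proportion 0.399  abundance 1.03e+09  (LOD 2.59e+05)
  Lhel: proportion 0.289  abundance 7.46e+08  (LOD 2.59e+05)
  Lmel: proportion 0.193  abundance 4.98e+08  (LOD 2.59e+05)
  Lkul: proportion 0.120  abundance 3.1e+08  (LOD 2.59e+05)
stability, first window (P1-P5): 188.1
stability, last window (P17-P21): 222112.7
```

All four species remain far above the ~2.6x10⁵ cells/ml detection limit at
passage 21, their abundances track the four resource capacities
(10⁹ … 3x10⁸), and the community's stability (inverse coefficient of
variation of total abundance) is high and grows once the Poisson bottleneck
is the only remaining source of fluctuation. Re-running with
`scenario("exclusion", ...)` — one shared resource — instead drives three
species below the detection limit by about passage 11.

A command-line interface mirrors the library (`nichepart amplicon`,
`dynamics`, `ions`, `gcms`, `simulate`, `validate-panel`); every threshold
above is a flag.

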