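# Methods

`nichepart` reimplements, as a tested library, the quantitative chain used to
study how four closely related *Lactobacillus* species of the honey-bee gut
coexist under different diets: strain-resolved amplicon quantification,
absolute-abundance dynamics across serial passages with detection limits and a
stability statistic, untargeted/semi-targeted metabolomics processing, and a
ground-truthed synthetic-data generator that makes every stage testable
without the original sequencing data.

## Strain-resolved amplicon typing

The four species share a 199-bp housekeeping-gene amplicon that differs at a
small set of discriminatory SNP positions; a `MarkerPanel` holds one reference
sequence per strain plus the positions and expected bases. Raw paired-end
reads are processed in four steps:

1. **Demultiplexing** routes each mate pair to a sample by exact barcode
   match (default); a `max_mismatch` knob permits Hamming-distance rescue,
   with ties left undetermined. Demultiplexing always partitions the input.
2. **Quality trimming** follows Trimmomatic's LEADING:28 / TRAILING:29 /
   SLIDINGWINDOW:4:15 / MINLEN:90 semantics: strip low-quality leading and
   trailing bases, then cut at the start of the first 4-base window whose
   mean quality drops below 15. After the window cut, trailing bases below
   the trailing threshold are removed once more; this cleanup is what makes
   trimming idempotent (a window cut can expose a low-quality final base),
   and it is part of the documented contract checked by the brute-force
   oracle in the tests.
3. **Merging** reverse-complements the reverse mate and scans every ungapped
   offset (the forward mate is taken as the 5' end of the fragment; offsets
   are 0-based, half-open). The offset with the most matching bases wins;
   ties break toward the longer overlap, then the 5'-most offset. At
   disagreeing overlap positions the higher-Phred base is kept with its own
   score (quality ties go to the forward base); agreeing positions get the
   larger of the two scores. This is a deliberate simplification of PEAR:
   the observed/expected alignment statistic is replaced by a minimum
   overlap identity (default 0.8) below which the pair is `no_overlap`, and
   the `-q 26` option is interpreted as a consensus-quality floor — consensus
   positions below Phred 26 are masked to `N`, which sends reads with masked
   SNP positions to the unassigned bin. Assemblies outside
   `[min_assembly, max_assembly]` are rejected (`length_out_of_range`); the
   pipeline defaults this window to exactly the marker length.
4. **Assignment** requires the consensus length to equal the marker length,
   reads off the bases at the SNP positions, and demands an exact match to
   exactly one strain's profile. There is no partial-profile scoring by
   default because the source protocol states no mismatch tolerance; a
   `max_profile_mismatch` knob exists, reporting equally close strains as
   `ambiguous`. Relative abundance is computed over assigned reads only;
   ambiguous and unassigned reads are excluded and reported alongside.

## Community dynamics

Absolute abundance is `proportion x total load` (CFU or qPCR copies), so
per-sample abundances sum to the measured load exactly. The limit of
detection is defined as the abundance equivalent of a single assigned read,
`LOD = total_load / assigned_read_depth` — the simplest depth-dependent
bound consistent with per-replicate grey bands that vary with sequencing
depth. A sample with zero assigned reads has no evaluable LOD and raises
rather than silently returning 0. Mean LODs across replicates carry a
two-sided Student-t confidence interval (default 95%); a single replicate
yields a mean with the interval flagged unavailable.

Community stability over a sliding window (default five passages, step one)
is the temporal mean divided by the temporal standard deviation — the
inverse coefficient of variation. Two conventions were genuinely open and
are both exposed: the default aggregates the summed community abundance per
window (`mode="aggregate"`), matching the behaviour of the community-ecology
implementations this statistic is borrowed from, while `mode="per_species"`
returns the statistic per strain. The sample SD (denominator n−1) is used
throughout; with five-passage windows the distinction is material. A
zero-SD window reports a non-finite stability with a flag instead of
raising. Strains with zero assigned reads are drawn at LOD/2 on log-scale
plots only; analysis tables keep true zeros.

## Metabolomics

Technical-replicate injections are averaged arithmetically after recording
the Pearson correlation of each replicate pair's intensity vector across
ions. Time-point changes per ion use a two-sided Student's t-test
(equal-variance, as in the source protocol; Welch behind a flag) on
biological-replicate means, with Benjamini–Hochberg adjustment applied
within each species across all ions — the family matching per-species
volcano plots. Fold changes are
`log2(mean(T_final)+ε) − log2(mean(T0)+ε)` with pseudocount ε = half the
smallest nonzero intensity in the table, applied only inside log ratios
(water blanks and absent ions contain zeros). Zero-variance degenerate
cases are defined, not errors: equal constant groups give p = 1; unequal
constant groups give p = 0 with a `degenerate` flag. An ion is a
*significant decrease* when log2FC ≤ −1 and adjusted p ≤ 0.01; the
*significant change* flag uses |log2FC| ≥ 1.

Pollen-derived ions are classified from a dilution series (ten serial 2x
dilutions, three replicates each): ordinary least squares of intensity on
the **linear dilution fraction** (every replicate a point; a flag switches
the regressor to the step index), plus the log2 ratio of undiluted pollen to
water blanks. An ion is pollen-derived when R² > 0.75 and log2FC > 2.
All-zero ions define R² = 0. Both the R² and the fold change are invariant
to global intensity rescaling.

The per-ion *decrease specificity* is the number of species in which the ion
significantly decreases; ions decreasing nowhere are excluded, and counts
are reported for all-species, subset (2 to n−1 species), and single-species
categories, which partition the decreasing ions.

GC-MS peak areas are normalized per run (one timepoint x replicate
injection) to the geometric mean of the internal standards; runs with a
zero or missing standard are flagged and excluded from means. Fold changes
at 8/16/24 h are taken against the mean normalized T0 area; significance at
24 h requires |log2FC| ≥ 2 and BH-adjusted p ≤ 0.01 across metabolites.
The untargeted (≤ −1) and GC-MS (≥ |2|) thresholds are distinct defaults,
both parameters.

## Synthetic data

The generator defines the study conditions the tests run under.

**Passage model.** Each passage is a batch culture grown to resource
exhaustion: resource *r* contributes `supply_r x yield` cells, divided among
strains proportionally to `abundance x affinity`. This proportional-
allocation update was chosen over ODE integration because transfers are
batch cultures to stationary phase and the closed-form update is exactly
checkable (total cells produced equals total supply consumed x yield — a
conservation law asserted in the tests). Transfers take a 1:20 dilution
(the protocol's stated transfer ratio) with Poisson sampling of the
bottleneck, so strains near detection can stochastically go extinct. The in
vivo mode instead founds each new host with a fixed-size multinomial
inoculum (default 1e5 cells) and partitioned within-host capacities — a
documented simplification of host colonization.

**Regimes.** No quantitative growth parameters exist to fit, so the presets
were chosen by forward simulation to reproduce the qualitative regimes and
the printed abundance scales (1e5–1e9 per ml or per gut), then frozen:

* `exclusion` — one shared resource, affinities (1.0, 0.3, 0.25, 0.2),
  community capacity 2e9. The per-passage share update multiplies each
  strain's ratio to the winner by roughly its relative affinity, so the
  weaker three competitors fall below the 1e5 detection bound by about
  passage 11 of 21 — the glucose co-culture outcome.
* `partition` — four exclusive resources with capacities 1e9, 7e8, 5e8,
  3e8: all four strains persist through 21 passages with finite stability —
  the pollen outcome.
* `invivo` — partitioned niches at gut-scale capacities (1e8 down to 3e6)
  over 7 passages.

**Reads.** Fragment strains are multinomial in the true abundances;
substitution errors are i.i.d. per base (erroneous base uniform over the
three alternatives); per-base qualities are uniform over Phred 33–41 and
deliberately independent of the error process (no quality-error coupling).
Mates are the fragment's first and last `read_len` (default 120) bases, so
they overlap by 41 bp on the 199-bp marker. Because each strain carries one
private SNP, a single error can only void a profile, never convert it: the
expected unassigned fraction is `1 − (1 − e)^k` for k discriminatory
positions, a closed form the tests check.

**Totals.** CFU/qPCR loads receive unit-mean log-normal noise with a given
coefficient of variation (default 0.2).

**Metabolome.** Defaults mirror the study scale: 657 ions of which 406 are
pollen-derived (linear in the dilution fraction, absent from water);
medium-derived ions are flat and present in water. Of the pollen ions, 24
are depleted in all four species, 24 in a 2–3 species subset, and 28 in one
species, with log2 effects drawn uniformly from (2, 4) — i.e. 4- to 16-fold
depletion, comfortably above the flagging threshold. Noise is multiplicative
log-normal (CV 0.1 biological, half that technical; 3 biological x 2
technical replicates). The GC-MS table carries three internal standards per
run and depleted metabolites ramping linearly in log2 space to 24 h.

What the generator does **not** emulate: chimeric amplicons, quality-error
correlation and position-dependent error profiles, PCR amplification bias,
batch effects or drift in metabolomics intensities, missing values, and
cross-feeding between strains. Passing recovery tests therefore demonstrate
correctness of the analysis chain under multinomial sampling and log-normal
noise, not robustness to these real-data artefacts.

## Numerical choices and limitations

* Proportions must sum to 1 within 1e-9; abundance conservation is exact to
  float rounding. Stability windows use sample SD; `n − window + 1` windows
  at step 1.
* Overlap-scoring ties are resolved deterministically (longest overlap,
  then 5'-most offset); quality ties take the forward base. Outputs are
  byte-identical across runs for a fixed seed.
* Statistical power at the study's replication level is intrinsically
  limited: with three biological replicates per group (4 degrees of
  freedom) and BH-adjusted p ≤ 0.01 over a ~650-ion family, the
  probability of detecting even a very large true depletion plateaus near
  95% per ion-species pair, because small-sample variance estimates
  occasionally inflate the denominator of the t statistic. Consequently
  ions truly depleted in all four species are recovered as category 4 in
  roughly 80% of cases at these settings, and the category tallies the
  package reports on simulated data undercount the designed all-species
  group. This is a property of the experimental design being emulated, not
  of the implementation; the tests assert the behaviour actually supported
  by the design.
* The transfer ratio is described inconsistently in the source protocol
  (1:20 vs 1%); the simulator follows 1:20.
* Acceptance-style checks run at desk scale: 20 simulator seeds per regime,
  sequencing depth 1e4, 500–1000 ions per calibration — sizes chosen so the
  whole suite completes in well under a minute per module while keeping
  binomial error bars far tighter than the asserted margins.
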