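# Methods

This note documents the statistical procedures implemented in `introscan`,
the defaults and the reasoning behind choices the underlying methodology
leaves open, and what the synthetic data generator does and does not
emulate.

## Admixture profiles and outlier blocks

The unit of analysis is the per-SNP admixture profile: for SNP j,
`admix_prop[j]` is the mean donor-ancestry dosage over the admixed
individuals divided by 2, a value in [0, 1].  Dosages are consumed as
produced by a local-ancestry HMM (ELAI-style expected donor copy number in
[0, 2]); ancestry inference itself is out of scope.

A block of overrepresented hybrid ancestry (OHA) is a maximal run of
consecutive same-chromosome SNPs, each **strictly** above
μ + k·σ (default k = 3).  Choices worth stating:

- **Scope.** Default statistics are per chromosome, each chromosome being
  an independently recombining unit; a genome-wide (`global`) scope is
  available.  On heterogeneous genomes the global SD is inflated by
  between-chromosome mean differences, which suppresses local outliers —
  the per-chromosome default avoids this.
- **SD convention.**  Population SD (denominator n) by default, since the
  profile is the full population of genotyped loci; `ddof=1` is
  configurable.  Outlying SNPs are *not* excluded from μ and σ — the
  threshold is a single pass, not an iterative trim.
- **Runs.**  A sub-threshold gap of even one SNP splits a run; runs
  shorter than `min_snps = 10` are discarded to control false positives.
  Block coordinates span the first to last SNP of the run and block size
  is `end_bp − start_bp` (the span between flanking SNP positions, no +1),
  matching the convention of the reference block tables bundled in
  `introscan.datasets`.
- **Deserts.**  The default desert criterion is admixture < 0.1%
  (absolute), the threshold in use for introgression-resistant regions;
  the symmetric μ − 3σ rule is available (`mode="sd_below"`) but on
  low-admixture data it reduces to "no hybrid ancestry at all" and
  typically finds nothing.

## Randomised-chromosome validation

Error rates of block detection are estimated by resampling: 38 segments,
each of 10–150 consecutive SNPs (both uniform), are drawn with replacement
from the autosomal profile and concatenated into a "randomised
chromosome", which is scanned with the same rule using **its own** mean
and SD.  Segments overrunning a chromosome end are truncated, and redrawn
if truncation leaves fewer than 10 SNPs.  A segment is *significant* in a
context when more than half of its SNPs lie inside a detected block — the
majority rule is symmetric between contexts and insensitive to 1-SNP
boundary jitter.  False positives are segments significant only in the
randomised context; false negatives only in the original.  Counts always
sum to 38; rates are reported as exact fractions plus nearest-integer
percentages.

## EHH, iHH and iHS

For a core SNP and allele, carriers are the haplotypes holding that allele
at the core.  EHH at offset x is the probability that two random carriers
are identical at every SNP from the core through x, computed by
incremental group refinement (pair counts over identity groups).  Numerical
and data-handling choices:

- EHH(0) = 1 by definition; the curve is non-increasing.
- A carrier hitting a missing call is dropped from the group structure at
  that site, but the denominator stays at the initial carrier count — a
  conservative choice that preserves monotonicity (shrinking the
  denominator could make EHH rise).
- Fewer than two carriers → the curve is flagged invalid.

iHH integrates EHH over distance by the trapezoid rule, truncated at the
first crossing of the 0.05 cutoff with linear interpolation to the
crossing point.  Cores whose EHH does not reach 0.05 before the chromosome
end (either allele, either direction) are flagged invalid and excluded —
no boundary penalty is applied.  Integration is over physical distance
(bp) by default, the natural choice for chip data without a matched
per-sample genetic map; passing a `RecombinationMap` switches to genetic
distance.  An optional `max_gap` (off by default) invalidates cores whose
integration span crosses an inter-SNP gap larger than the given bp, for
sparse chips.

The unstandardised statistic is ln(iHH_A / iHH_D).  Standardisation is
within derived-allele-frequency bins of width 0.025; bins with fewer than
10 valid records are merged with the nearest occupied neighbour (by bin
centre) until all groups qualify, keeping bin SDs stable.  Two-sided
p-values come from the standard normal, which the standardisation
contract justifies under neutrality.  The joint significance rule is
p < 0.05 **and** |iHS| > 2, both strict; a per-chromosome Bonferroni
variant divides α by the number of valid tested SNPs on the chromosome.
The scan standardises genome-wide and intersects significant SNPs with
OHA blocks afterwards; restricting standardisation to blocks would bias
the bins toward the blocks' frequency spectrum.

Derived/ancestral orientation is taken from a supplied per-SNP ancestral
allele code; without one, the reference (0-coded) allele is treated as
ancestral — on real data this is a caveat, since misorientation flips the
sign of individual scores (|iHS| is unaffected at mirrored frequencies).

## Gene context, empirical FDR and CAI genes

Each significant SNP inside an OHA block is assigned exactly one category
with precedence *in protein-coding gene* > *in lncRNA* > *within 100 kb of
either* > *far*.  Distance is SNP-to-nearest-gene-boundary, inclusive at
exactly 100,000 bp; gene intervals are 1-based inclusive; genes of other
biotypes are ignored.  Since a sweep signal must be anchored by a
functional element, the far fraction estimates the selection scan's FDR
(conservatively — unannotated functional sequence counts against it).

A CAI (candidate adaptive-introgression) gene is a protein-coding gene
overlapping an OHA block with ≥ 1 significant SNP inside its interval.
Signals just outside a gene are reported separately with a proximal flag
(default window 10 kb).  CAI proportions count distinct genes (a gene
spanning two blocks counts once) and are rounded to two significant
figures by default, the precision such proportions are conventionally
reported at.

Note: in the bundled published context counts the free-ranging-dog
categories are not mutually exclusive (they sum past the stated total);
the worked-example percentages are therefore computed from printed count
and printed total, while the package's own classifier always produces
exclusive categories.

## Admixture vs recombination

Recombination rate is attributed to each SNP by enclosing-interval lookup
on the map (piecewise-constant; positions outside the map take the
boundary interval's rate and are flagged).  Correlations are Pearson r
with the t-transform p-value on df = n − 2, plus the least-squares line of
admixture on rate; tests are two-sided and run genome-wide and per
chromosome.  No multiple-testing correction is applied across the
per-chromosome tests by default (counts of significant chromosomes are
the object of interest); Benjamini–Hochberg is available via a flag.
Cross-taxon correlation aligns the two profiles on their shared
(chrom, pos) set.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
not a full population-genetic simulation:

- **Sources.**  Balding–Nichols: ancestral frequency p ~ U(0.05, 0.95),
  each population's frequency Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = F_ST (default 0.205, the divergence of the motivating wolf/dog
  system).  Haplotypes are independent across sites — background LD is
  **not** modelled; haplotype structure, where needed, is planted
  explicitly.  This keeps every downstream statistic analytically
  checkable (e.g. neutral EHH decays geometrically and the iHS null is
  clean).
- **Admixture.**  Per haplotype, ancestry switch points form a Poisson
  process at rate g per Morgan (default g = 10 generations since
  admixture; the continuous-time rate g rather than g − 1, a negligible
  distinction at g = 10), each tract donor with probability m.  Presets
  m = 0.0274 (dog-into-wolf) and m = 0.0075 (wolf-into-dog) match the
  motivating system; 88 admixed individuals by default.  The true dosage
  is the sum of the two haplotypes' donor indicators.
- **Planted blocks.**  Within an interval, ~target·n_hap randomly chosen
  haplotypes are forced to donor ancestry (alleles redrawn from donor
  frequencies, truth updated); targets mirror the 0.055–0.315 ancestry
  range of the reference block tables.  Planting below the background is
  a warned no-op.
- **Planted sweeps.**  One derived-carrier haplotype's segment
  (default 500 kb) is copied onto a chosen share of haplotypes (default
  0.8) which are set derived at the core — the extended-homozygosity
  footprint of a hard sweep, without simulating selection dynamics.
- **Geometry.**  Default 5 chromosomes × 4,000 SNPs at 25-kb spacing
  under a uniform 1 cM/Mb map: desk-scale, while leaving room for
  ≥ 10-SNP blocks and 100-kb windows.

Not emulated: demography (bottlenecks, growth), mutation, genotyping
error, background LD, selection acting over generations, sex chromosomes.
Passing tests therefore demonstrate correctness of the statistics and
recovery under the assumed structure, not robustness to real-data
artefacts such as phasing error or array ascertainment.

## Problem sizes used in tests and the acceptance script

Simulation-based checks are sized for statistical soundness at desk
scale: F_ST calibration uses 20,000 SNPs × 200+200 haplotypes (estimator
SE ≪ the ±0.025 band); admixture-proportion recovery uses 4,000
haplotypes × 10,000 SNPs (~30 tracts per haplotype, SE ≈ 5 × 10⁻⁴ against
the ±0.002 band); the neutral iHS identity uses a 5,000-SNP, 120-haplotype
panel; block and sweep recovery use 50 seeded replicates on 1,000-SNP
chromosomes with 88 admixed individuals; resampling validation uses 200
seeded replicates.  Per-stage seeds are derived from a single master seed
via SHA-256, so every run is reproducible.

## Known limitations

- Missing genotypes in the iHS scan are handled by carrier dropping, not
  imputation; heavily missing data shrink the effective carrier sets.
- With ref/alt standing in for ancestral/derived, individual iHS signs
  are unreliable (see above).
- The LD pruner is the classic greedy sliding-window heuristic
  (window 50 SNPs, step 5, r² on genotype dosages); it does not find a
  maximum independent set.
- `annotate` treats an annotation without biotypes as all protein-coding;
  the lncRNA category is then empty.
- The pipeline assumes autosomes; no X-specific handling exists.
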