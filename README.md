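# introscan

Detection of introgressed chromosomal blocks and candidate
adaptive-introgression genes in admixed genomes.

`introscan` is aimed at population geneticists studying hybridisation
between a wild taxon and its domestic relative (the motivating system is
dog–wolf hybridisation in Eurasian grey wolves and free-ranging dogs,
genotyped on a ~100k SNP chip), but the pipeline is generic: it consumes
per-SNP local-ancestry dosages (ELAI-style), phased genotypes, a
recombination map and a gene annotation, and answers three questions:

1. **Where is hybrid ancestry over- or under-represented?**  For each SNP
   the admixture proportion is the mean donor dosage over admixed
   individuals divided by 2.  A block of *overrepresented hybrid ancestry*
   (OHA) is a maximal run of ≥ 10 consecutive SNPs each with admixture
   proportion > μ_c + 3σ_c, where μ_c, σ_c are the mean and SD of the SNP's
   chromosome (a genome-wide variant is available).  *Ancestry deserts* are
   runs of ≥ 10 SNPs with admixture < 0.1%.  False-positive and
   false-negative rates of the detection are estimated by resampling: 38
   random segments of 10–150 SNPs are concatenated into a "randomised
   chromosome", re-scanned with its own 3-SD threshold, and each segment's
   significance status is compared between the two contexts.

2. **Are OHA blocks under positive selection?**  From phased haplotypes the
   extended haplotype homozygosity of a core allele is
   EHH(x) = Σᵢ C(eᵢ,2) / C(n,2) with n carrier haplotypes split into groups
   of size eᵢ identical from the core through x.  iHH is the trapezoid
   integral of EHH over distance down to EHH = 0.05, and
   iHS = standardised ln(iHH_A / iHH_D), standardised to zero mean and unit
   SD within derived-allele-frequency bins, so neutral iHS ≈ N(0,1).  A SNP
   is significant when p < 0.05 and |iHS| > 2 (per-chromosome Bonferroni
   also available).

3. **Which genes are candidates for adaptive introgression?**  Significant
   SNPs inside OHA blocks are classified against the annotation
   (within a protein-coding gene / within a lncRNA / within 100 kb of
   either / farther).  Because a sweep must be driven by a functional
   element, the "far" fraction is an empirical FDR for the selection scan.
   A protein-coding gene in an OHA block containing ≥ 1 significant SNP is
   a candidate adaptive-introgression (CAI) gene.

A synthetic-data module generates admixed two-population panels with known
truth — Balding–Nichols divergence at F_ST ≈ 0.205, Poisson ancestry-tract
structure (rate g per Morgan, donor probability m), planted OHA blocks and
planted sweeps — so the whole pipeline is testable without any downloads.
An admixture–recombination correlation module (Pearson r, df = n − 2,
least-squares fit, genome-wide and per chromosome) completes the analysis.

## Worked example

```python
from introscan import (SimulationConfig, simulate_dataset, snp_admixture_profile,
                       chromosome_stats, detect_outlier_blocks, summarize_blocks,
                       ihs_scan, significant_snps, validate_detection)

cfg = SimulationConfig(
    n_chromosomes=2, n_snps_per_chrom=1000, n_admixed=88,
    planted_blocks=[("chr1", 5_000_000, 5_500_000, 0.25)],
    planted_sweeps=[("chr1", 5_250_000, 0.8, 400_000)],
)
sim = simulate_dataset(cfg, seed=1)

profile = snp_admixture_profile(sim.truth.dosage_matrix())
blocks = detect_outlier_blocks(profile, chromosome_stats(profile))
print(summarize_blocks(blocks, profile).to_string(index=False))

report = validate_detection(profile, seed=1)
print("FP rate: %.3f  FN rate: %.3f" % (report.fp_rate, report.fn_rate))

records = ihs_scan(sim.panel)
sig = significant_snps(records)
print(f"{len(sig)} selection-significant SNPs of {int(records['valid'].sum())} valid cores")
```

prints

```
chrom start_bp  end_bp  size_bp  mean_ancestry  n_snps
 chr1  5000000 5500000 500000.0       0.272727    21.0
 Mean     <NA>    <NA> 500000.0       0.272727    21.0
FP rate: 0.000  FN rate: 0.000
83 selection-significant SNPs of 1584 valid cores
```

The 21-SNP planted block (donor frequency 0.25 on a 0.027 background) is
recovered with exact boundaries; the randomised-chromosome control finds
no spurious blocks; and the planted sweep produces a cluster of
|iHS| > 2 SNPs, 12 of which fall inside the detected block — exactly the
pattern used to call CAI genes.

The same stages are available from the shell:

```sh
introscan run --config pipeline.yaml --seed 1 --out rundir/
introscan simulate | profile | scan | validate | ihs | annotate | correlate | report
```

## Layout

| module | contents |
| --- | --- |
| `introscan.io_formats` | VCF / PLINK-text / dosage / map / BED / GFF3 readers-writers, MAF-missingness filters, LD pruning |
| `introscan.block_scan` | admixture profiles, chromosome stats, OHA-block and desert detection, Table-style summaries |
| `introscan.resampling` | randomised-chromosome construction and FP/FN classification |
| `introscan.selection` | EHH, iHH, iHS scan, significance thresholds |
| `introscan.annotate` | SNP gene-context classification, empirical FDR, CAI gene calls |
| `introscan.recomb` | rate interpolation, Pearson/regression tests, cross-taxon correlation |
| `introscan.simulate` | synthetic admixed panels with ground truth |
| `introscan.pipeline`, `introscan.cli` | YAML-driven orchestration and the `introscan` command |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
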