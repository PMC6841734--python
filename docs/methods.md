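# Methods

## Scope and model

mirmethyl analyses a probes × samples matrix of Infinium-style beta values
restricted to miRNA-associated probes, from a two-group (case/control)
cohort.  All testing happens on the M scale, M = log₂(β/(1−β)), the
variance-stabilised scale standard for such arrays; beta values are
clipped into [ε, 1−ε] with ε = 10⁻⁶ before the transform.  The per-probe
statistic is the M-scale mean difference (case − control), tested with a
two-sided Welch t-test, or — when covariates are supplied — as the group
term of an OLS fit of M on group plus covariates.  The two paths give the
same coefficient exactly when no covariates are present.

Probe selection follows the volcano rule: *p* < 0.05 (strict) and
|fold change| > 1.3 (strict), with fold change defined as 2^coeff; the
1.3-fold boundary therefore sits at |coeff| = log₂ 1.3 ≈ 0.379 M units.
Selection deliberately uses the raw p-value, not the BH q-value: the
published rankings this package reproduces include rows with q-values up
to ≈ 0.8, so an FDR-based selection could not have produced them.
Benjamini–Hochberg q-values are still computed and reported for context.
Reported percentages round half away from zero to integers, matching how
such studies print 71% for 154/216 or 96% for 208/216; the two halves of a
partition therefore sum to 100 ± 1.

The original cohort-level coefficients were published on an unstated
scale.  We define coeff as the M-scale group difference and the volcano
fold change as 2^coeff; this reproduces the structure and thresholds of
the published analysis but not its exact per-probe numerics, which would
require the raw cohort data and the original (unpublished) model.

Ranking mirrors published top tables: the hypermethylated block first in
descending coefficient, then the hypomethylated block in descending
magnitude; ties break by ascending p-value then probe id, so output is
deterministic.

## Annotation model

Promoter vs body is carried as an explicit annotation column, not
recomputed from TSS distances — promoter windows differ between studies,
and for array data the vendor categories map naturally
({TSS1500, TSS200, 5′UTR, 1stExon} → promoter, {Body, 3′UTR} → body).
Host-gene fields (gene, sense/antisense relationship, intronic / exonic /
boundary context) must be mutually consistent: a probe is intergenic
exactly when it has no host gene.  Probes that interrogate a host gene
directly (rather than a miRNA) carry `mirna_gene = none` and a
`host_region_class` of promoter or body.

## Host-gene co-methylation

The host-probe universe is restricted to hosts of differentially
methylated miRNA genes.  A miRNA/host pair is called co-methylated when at
least one miRNA promoter probe and at least one host promoter probe are
selected with the same direction — a qualitative concordance criterion;
no quantitative beta-correlation threshold is imposed, because none is
established for this design.  Host promoter support must come from probes
other than the miRNA's own (a probe doubly annotated to the miRNA promoter
and the host promoter cannot by itself establish a pair).  Pairs are
ordered by the magnitude of the mean coefficient over their member probes.

## Assay quantification

MethyLight: relative quantities are derived from Ct values as
(1 + E)^(−Ct) with PCR efficiency E = 1 by default (no standard curves are
assumed; E is exposed as a parameter), replicates are averaged in the
linear domain, and PMR = 100 · (GENE/ALU)_sample / (GENE/ALU)_reference
against an M.SssI fully methylated reference.  PMR is invariant to adding
a constant number of cycles to every well.  Group comparison defaults to
the two-sided Wilcoxon rank-sum test (small n, non-normal PMR
distributions), with Welch's t as an option.

qRT-PCR uses the standard 2^−ΔΔCt method against a housekeeping gene and a
control condition; dual-luciferase activities are normalised per well to
β-galactosidase and then to the negative-control condition, which is 1 by
definition.  Both fold changes are strictly positive and equal 1 on
self-comparison.

## Seed-site scanning

A seed match is complementarity between the target mRNA and miRNA
positions 2–7, classified with the canonical hierarchy (6mer, 7mer-A1 with
a target adenine opposite position 1, 7mer-m8 extending the match to
position 8, 8mer with both).  The miRNA (RNA) is mapped to DNA before
complementing; N in a UTR never matches.  Coordinates are 1-based
inclusive relative to the UTR's first base and span the full matched
window, so a 7mer-m8 site whose core starts at 726 is reported as 725–731
— the convention used when such sites are quoted against RefSeq 3′-UTRs.
Mutant UTRs for reporter constructs carry exactly n (default 3)
transversions inside the 6-nt pairing core, chosen deterministically and
verified by rescanning: the mutant must lose the targeted site, keep all
other sites, and gain none.

## Synthetic data

The generator emulates the study design the pipeline expects: 2,227
miRNA-associated probes over 463 miRNA genes, 10 cases vs 9 controls.
Per-probe baselines are bimodal on the M scale — unmethylated promoters at
N(−3, 0.5) (β ≈ 0.11), methylated gene bodies at N(+2, 0.5) (β ≈ 0.8) —
and group effects are planted gene-wise in miRNA promoter probes as a
constant M-shift (+2.0 for hypermethylated genes, −2.0 for
hypomethylated) before adding N(0, 0.5) per-observation noise and mapping
back through β = 2^M/(1+2^M), which keeps β strictly inside (0, 1).
Defaults plant hypermethylation in ~7% and hypomethylation in ~3% of
promoter probes, so a default run selects a probe count of the same order
as the real cohort's 216/2,227.  One planted gene (the "star") receives
twice the effect, emulating the single standout hypermethylated miRNA the
real cohort shows; 10% of hypermethylated genes also have their host
gene's promoter probes shifted, planting co-methylation.  Host genes get
8 dedicated probes each (20% promoter / 80% body, echoing the observed
body-heavy host methylation).  The cohort's baseline variance and beta
distribution were never published, so these baselines are stated choices,
not fits.  Clinical covariates (age, sex, pachymetry, guttata grade) are
generated independently of the methylation signal, so covariate
associations are null by construction.

What the generator does **not** emulate: probe-level intensity artefacts
(dye bias, type I/II probe chemistry), spatially correlated probes within
a CpG island, batch structure, or cell-composition effects.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data artefacts.

The MethyLight generator fixes each sample's ALU Ct and sets its GENE Ct
to the ALU baseline minus log₂(PMR/100), with the reference at ratio 1;
this makes the PMR formula exactly invertible, so the zero-noise round
trip is exact to floating-point precision (a planted PMR of exactly 0 is
represented by a GENE Ct 60 cycles past the baseline).  The UTR generator
writes exact seed-match windows at requested positions and
rejection-samples the background until a rescan finds exactly the
requested sites.

## Operating-characteristic benchmarks

`mirmethyl.evaluate` measures the pipeline against its own ground truth:

- **Parameter recovery** uses the cohort's planted effect (2.0 M units),
  noise (0.5) and group sizes (10 vs 9) on 2,000 probes, averaged over 20
  seeds.  For this benchmark true effects are planted in half of the
  promoter probes (hyper) and a fifth (hypo): the empirical FDR of raw-p
  selection is dominated by the null fraction π₀, so a benchmark at the
  emulated cohort's ~10% planted fraction would measure π₀ rather than the
  method (at π₀ ≈ 0.9, raw-p selection at α = 0.05 necessarily yields an
  FDR near 0.3 regardless of implementation).  With the enriched design
  the pipeline's sensitivity is ≈ 1.0 and its empirical FDR ≈ 0.04.
- **Null calibration** regenerates 10,000 probes with no planted effects
  and checks that the Welch test's type-I error sits at the nominal 5%.
- **Scanner equivalence** compares the seed scanner against an independent
  window-by-window complementarity scan on 1,000 random UTRs.
- **End-to-end** runs the default emulated cohort through selection,
  expression overlap (87 down-regulated names, 18 overlapping, the star
  gene forced in), UTR scanning at a planted position (725), mutant
  design, and simulated luciferase/qPCR readouts in which repression
  applies only when the scanner finds a site — so a correct mutant design
  restores activity to ≈ 1.

Problem sizes are chosen so the full benchmark suite runs in seconds on a
single CPU.

## Known limitations

- No surrogate-variable or batch correction, and no moderated-variance
  (empirical-Bayes) testing; with n ≈ 10 per group a limma-style shrinkage
  would add power but is outside this package's scope.
- The exact statistical model behind the published per-probe coefficients
  is unknown; fixture-level numbers are reproduced from the published
  table, not re-derived from raw data.
- TargetScan/miRmap context and conservation scores are not reimplemented;
  the scanner reports exact seed matches and a simple cross-species
  intact-site fraction only.
- Scanning the named RefSeq 3′-UTRs themselves requires fetching those
  sequences; the packaged tests use generated UTRs with planted sites
  instead.
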