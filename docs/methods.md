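# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the procedure was
genuinely underdetermined.

## Study design assumed

A case-control marker-validation design: two phenotype groups (low-salinity
*tolerant* / *intolerant*) of about 50 genotyped animals each, four
biallelic SNPs in one candidate gene (g.72037G>T, g.72122G>C, g.74293G>T,
g.74433G>T — the second intronic, the others exonic), unphased genotypes
from direct Sanger sequencing, growth traits for a subset of tolerant
animals, and qPCR expression for a few animals per genotype class.  All
statistics treat samples as exchangeable within a group; sample and locus
order are preserved from input but every estimator is order-invariant
(property-tested).

## Peak-ratio genotype calling

A Sanger trace at a heterozygous site shows two superimposed peaks.  The
caller uses the standard height-ratio rule: secondary/primary ≥ 0.30 →
heterozygote; < 0.20 → the secondary peak is noise, homozygote for the
primary base.  The 0.20–0.30 band is not covered by either rule; such calls
are returned as *missing* rather than forced, on the reasoning that
ambiguous traces are what manual cross-checking is for.  This band policy
is a deliberate design choice, exposed through the `het_ratio` /
`noise_ratio` parameters, and makes calling monotone: raising the secondary
peak can move a call only homozygote → missing → heterozygote.  A zero
primary peak is no signal (missing, with a warning).

The MAF filter compares exact rational allele-count fractions against the
threshold (default 5%), so 4 minor alleles out of 64 (= 1/16) passes while
3/64 fails regardless of floating-point representation of 0.05.

Loci are strictly biallelic: a third observed allele is an ingestion error
naming the sample and locus, not a silent recode.

## Per-locus association

Genotypes are pooled as carrier (het + hom-mutant) vs homozygous wild type
— the coding that matches how mutant-genotype frequencies are compared in
this design; a 3-row per-genotype count view is available for completeness.
On the 2×2 table the package computes:

* **OR** = N₁N₄/(N₂N₃), undefined (reported `-`) when either product is 0.
* **Woolf CI**: exp(ln OR ± z·SE), SE = √(1/N₁+1/N₂+1/N₃+1/N₄), z = 1.96.
  The CI method had to be chosen; the Woolf log-normal interval reproduces
  the published haplotype-table intervals to the printed precision, which
  is why it was adopted.
* **Pearson χ²** in the closed 2×2 form with *no* Yates continuity
  correction — the corrected statistic does not reproduce the published
  values.  Cells may be nonnegative reals so the same code serves EM
  expected counts.
* **Fisher's exact test** (two-sided, minimum-likelihood definition) via
  scipy; it requires integer counts, so fractional EM tables must first be
  rounded half-to-even and the result is labelled approximate.
* **Logistic regression** of phenotype on carrier status via IRLS
  (statsmodels GLM, binomial family, cell counts as frequency weights).
  For a single binary predictor the ML slope equals ln OR and its standard
  error equals the Woolf SE; the test suite asserts this identity to 1e-6,
  which doubles as a cross-check between the closed form and the iterative
  fit.  A zero cell is (quasi-)complete separation: the effect is reported
  undefined with a `separation` flag rather than a diverging estimate.

No multiple-testing correction is applied; p-values are raw, and with four
loci the reader should weigh the family-wise rate accordingly.

## Diversity estimators

Per group and locus over typed genotypes, with allele frequencies pᵢ:
Ho = #het/n, He = 1 − Σpᵢ² (plug-in gene diversity), Ne = 1/Σpᵢ²,
PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ².  The *uncorrected* plug-in He was chosen
deliberately: it makes He = 1 − 1/Ne an exact identity (shared Σp² term),
which the published group summaries satisfy row by row, whereas the
small-sample 2n/(2n−1) correction breaks it.  A monomorphic locus gives
(0, 0, 1, 0).

## EM haplotype inference

An individual heterozygous at *h* of the loci is consistent with
max(1, 2^(h−1)) unordered haplotype pairs.  Under random mating, the
complete-data likelihood of a pair (h₁, h₂) is f(h₁)f(h₂)(2 − [h₁=h₂]); the
E-step distributes each individual over its pairs proportionally, the
M-step sets each haplotype frequency to its expected share of the 2n
chromosomes.  The observed-data log-likelihood is nondecreasing (asserted
per iteration in tests) and frequencies stay on the simplex.

Conventions: individuals with any missing call at the haplotype loci are
excluded (near-complete typing makes integration over missing genotypes
not worth its complexity here); convergence at max |Δf| < 1e-8 (far tighter
than the 2-decimal reporting scale) capped at 1000 iterations with a
`converged` flag; initialization at linkage equilibrium (product of
observed allele frequencies), which is deterministic, plus 3 seeded
Dirichlet restarts keeping the best final likelihood — a guard against the
non-identifiable corner where nearly all individuals are multiple
heterozygotes.  Identical genotype rows are collapsed before iteration, so
cost scales with the number of distinct genotypes (≤ 3⁴ here), not n.
Expected counts are 2n·f; fractional values record how phase-ambiguous
individuals were split.

## Haplotype association table

Each haplotype is tested one-vs-rest on the expected chromosome counts.
Two conventions matter:

* **Rare-haplotype exclusion.** Haplotypes below a frequency threshold in
  *both* groups are listed with their counts but excluded from the group
  totals and carry no statistics.  The published table is only reproducible
  under such an exclusion; any threshold in (0.011, 0.061] yields the same
  included set there (property-tested), and 0.03 — the common default of
  haplotype-association software — was adopted and exposed as a flag.
* **Undefined statistics.** OR (and CI) are `-` whenever a zero cell makes
  the cross-product undefined; χ² needs only nondegenerate margins, so a
  haplotype absent from one group can have a defined χ² with an undefined
  OR — exactly the published pattern.

Expected counts below 1e-6 chromosomes are treated as exact zeros: they are
numerical residue of the EM split, and keeping them nonzero would turn
"undefined" cells into absurd intervals.  Fisher p on rounded tables is
flagged approximate (see above); note the published table's Fisher column
equals its Pearson column everywhere, so it cannot itself be an exact test
on the printed counts.

## Frequency-product classifier

Per group and locus, genotype relative frequencies over typed samples; a
sample is scored by the product across loci and assigned the group with the
higher score.  Design choices:

* **Smoothing.** A genotype unseen in one group would annihilate that
  group's product.  Unseen genotypes get a pseudo-frequency of 0.005
  (≈ half of 1/(2·50), i.e. half a count at the design's group size);
  0 restores the strict literal rule.
* **Ties** go to *intolerant* — the conservative direction when the marker
  is used to select tolerant broodstock; flag-switchable.
* **Evaluation** is resubstitution by default (the procedure described for
  this design); leave-one-out is provided because resubstitution optimism
  is a known hazard, and on well-separated data the two agree within a few
  points (regression-tested).  Samples missing a call at any used locus are
  excluded from R, not imputed.

## Growth PCA and group contrast

PCA is on the trait *correlation* matrix (traits standardized), so
eigenvalues sum to 3 and the result is invariant to unit changes; the
published loadings (0.974–0.996 with eigenvalue 2.89) are consistent with
loadings = eigenvector·√eigenvalue on a correlation matrix, which fixed
that convention.  Eigenvector signs are arbitrary; each column is oriented
to a nonnegative loading sum, and PC1 is additionally oriented so larger
animals score higher (positive body-weight loading) before ranking.  The
top/bottom 25 PC1 scores form the fast/slow groups (ties broken by input
order, deterministically).

For the carrier contrast, the published frequency denominators are
internally inconsistent across rows (one row implies counts/total-carriers,
another fits no simple convention); the implementation defines frequency =
group carrier count / total carriers in both groups — the convention that
reproduces the unambiguous rows exactly — and reports no frequency when
there are no carriers at all.

## Expression (2^−ΔΔCt)

Technical replicates are averaged on the Ct scale before ΔCt = Ct_target −
Ct_reference (the standard convention); ΔΔCt subtracts the calibrator
genotype's mean ΔCt per locus, so the calibrator averages fold 1 by
construction.  The calibrator defaults to the homozygous wild genotype
("GG" at every locus in this panel).  Group comparison is one-way ANOVA;
pairwise testing defaults to Tukey HSD with Duncan's multiple range test
(step-down protected, αᵣ = 1 − (1−α)^(r−1) critical points from the
studentized range) behind a flag — the two appear interchangeably in
practice and Tukey is the less permissive default.  Letters come from an
insert-and-absorb compact-letter display.  ANOVA with zero within-group
variance everywhere is rejected as degenerate.  In the pipeline summary, a
genotype class observed in a single animal is summarised but excluded from
the test (its SE is also undefined).

## Synthetic-data generator

The generator encodes the study conditions, not a tuning surface:

* **Genotypes.** Each individual draws two haplotypes from its group's
  haplotype distribution; defaults are the published group distributions
  (renormalized to the simplex): tolerant ≈ {GGGG .464, TCGG .157,
  TGGG .133, GGTT .097, TCTT .076, GGTG .061, TCGT .011, TCTG .001},
  intolerant ≈ {GGGG .969, TGGG .021, GGTT .010}.  Group sizes default to
  the genotyped cohort (50/50), not the challenge cohort, since only the
  former is analysed.  Missing calls at 2%.  Drawing haplotypes (rather
  than independent per-locus alleles) makes the loci linked, as the real
  panel is.
* **Growth.** traitᵢ = μᵢ + σᵢ(√ρ·F + √(1−ρ)·eᵢ) with a single latent size
  factor F, giving exactly the configured equicorrelation ρ (default 0.95,
  which puts PC1 variance ≈ (1+2ρ)/3 ≈ 97% — the observed regime); mutant
  carriers get +0.8 SD on F, producing the fast-group enrichment.  Means
  and SDs (20±3 mm length, 28±4 mm width, 5±1.5 g weight) are
  juvenile-scale values; they only set the scale, since the PCA is
  correlation-based.  ρ must lie in [0, 1] for the one-factor construction.
* **Expression.** Reference Ct ~ N(15, 0.3); target Ct = reference + 8 −
  shift + N(0, 0.1), with shifts of 0.5 cycles (het) and 1.0 cycle
  (hom-mutant), i.e. ≈1.4- and 2-fold upregulation; 3 individuals × 3
  technical replicates per observed genotype class per locus.
* **Peaks.** Heterozygotes emit ratio ∈ [0.35, 0.90], homozygotes
  [0, 0.15] (bands that avoid the calling thresholds, so calling
  round-trips exactly); a configurable fraction, plus every missing
  genotype, emits the ambiguous band [0.20, 0.30).

Each generator draws from an independent stream seeded as (seed, stream),
so outputs are individually and jointly reproducible.

What the generator does **not** emulate: the salinity-challenge survival
process, family structure, Hardy–Weinberg departures within groups,
genotyping error, allele dropout, locus-specific missingness, or
amplification-efficiency differences in qPCR.  Passing tests therefore
demonstrate the estimators' correctness and the pipeline's behaviour under
the assumed generating model, not robustness to those real-data artefacts.

## Problem sizes used in tests and the acceptance script

Synthetic validation cohorts use 500 animals per group (large enough that
EM error against the generating frequencies is dominated by sampling noise,
small enough to iterate over ten replicate seeds), with 10 replicates for
the recovery and classifier properties; exhaustive Fisher cross-checking
enumerates every 2×2 table with total ≤ 16 plus 300 seeded random tables up
to total 40.  The acceptance script evaluates classifier accuracy at the
design's own cohort size (50/group) and growth PCA at 56 animals.

## Known limitations

* Fisher's exact test on EM expected counts is approximate by construction
  (rounding); an exact haplotype test would need permutation of the raw
  genotypes.
* Resubstitution accuracy is optimistic; leave-one-out is provided but no
  cross-validated model selection is attempted.
* The EM does not integrate over missing genotypes, phase individual
  animals, or scale beyond ~20 heterozygous loci (it errors rather than
  explode).
* No Hardy–Weinberg testing, F-statistics, LD coefficients, omnibus
  haplotype tests, ROC analysis, or covariate-adjusted logistic models.
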