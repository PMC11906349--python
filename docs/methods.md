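# Methods

## Problem setting

Circulating protein levels are biologically proximal quantitative traits:
most of their genetic regulation sits in *cis*, in and around the cognate
gene.  Deep whole-genome sequencing observes the full allele-frequency
spectrum down to singletons, so the discovery problem becomes (a) finding
statistically independent single-variant associations across that spectrum
and (b) testing *aggregates* of rare noncoding variants — which are
individually underpowered — grouped by regulatory annotation.  This package
implements that procedure as a pipeline of small, independently tested
stages, and ships a synthetic-locus generator so the whole chain is
verifiable against known truth without access-controlled cohort data.

## Synthetic loci

`simulate.simulate_locus` draws variant positions uniformly without
replacement in a configurable window around a two-transcript gene model
(UTRs, exons, introns; the second transcript has a more extreme 3′ end so
the union-vs-longest transcript modes genuinely differ).  Allele counts are
assigned per variant from a mixture over frequency bins — singleton,
MAC 2–5, MAF < 0.1%, 0.1–1%, > 1% with default weights
(0.30, 0.25, 0.15, 0.15, 0.15), a singleton-heavy spectrum typical of deep
population sequencing — and alleles are placed on chromosomes exactly, so
realized MAC equals the target and genotypes are Hardy–Weinberg
conditional on MAC.  Variants are independent by default, which keeps every
downstream oracle exact; an optional block-LD mode draws both haplotypes of
each individual from a shared founder pool within blocks, inducing the
correlation structure that stresses conditional-joint selection.
Consequence labels follow gene geometry (UTR / exonic coding classes with
LOFTEE-style high-confidence flags / intronic / 5-kb flank / regulatory /
intergenic), and GERP, CADD, JARVIS and SpliceAI scores are drawn from
simple class-conditional distributions.  All randomness descends from one
seed through `SeedSequence` spawning; the per-component sub-seeds are
recorded on the locus.

Phenotypes are linear: y = Σ βⱼ gⱼ + covariates + N(0, σ²), with a reduced
covariate set (age, age², sex, four PC-like axes, one batch factor)
standing in for the full cohort covariate list.  Rare-effect magnitudes are
half-normal — scaled so the mean |β| matches the configured value, because
only the mean/median of the real effect distribution is known — with signs
negative (protein-decreasing) at the configured probability.  Defaults are
mean |β| = 1.15 s.d. with 65.2% decreasing for rare noncoding causals and
86.3% decreasing (mean 1.55 s.d., between the reported missense and LoF
relative magnitudes) for rare coding causals; common effects default to a
modest 0.15 s.d.  Causal aggregate units assign effects to a fraction of a
window's rare noncoding members, optionally at a fixed per-carrier β.
Raw calls (`simulate_raw_calls`) draw per-genotype depth from a Poisson at
32.5× (typical short-read WGS coverage), split it into ref/alt allele
depths by genotype, derive GQ from depth with an independent low-GQ
contamination rate, and emit a per-base pass-count track (samples with
depth > 8) that is binomial off variant sites and exactly consistent with
the simulated depths at variant sites.  Low-coverage segments zero the
depth rate.

What the generator does *not* emulate: coalescent haplotype structure,
relatedness, structural variants, sequencing-error-driven genotype errors
correlated with context, batch covariance of the proteomic platform, or
selection-driven frequency–effect coupling.  Passing tests therefore
establish correctness of the statistical machinery and calibration under
idealized sampling, not robustness to those real-data features.

## Genotype QC

A call becomes missing when sum of allele depths < 8 or GQ < 10 (both
strict); variants with missingness > 10% (strict, per the quoted rule;
exactly 10% is retained) are dropped; MAC/MAF are recomputed after masking;
missing dosages are mean-imputed only at regression time (standard
practice — imputation before frequency computation would bias MAC).

## Windows, classification, masks

Coordinates are 0-based half-open internally; VCF positions convert on
read/write and BED is native.  The *cis*-window is the outermost UTR bounds
± 1 Mb, clipped at chromosome bounds; the default uses the union of
transcript extremes with a longest-transcript switch (both conventions are
defensible and the sources differ; neither is asserted as ground truth).
Classification is a strict priority: coding consequence on any transcript
→ `coding`; else within the UTRs, introns, or 5 kb of any UTR →
`proximal_regulatory`; else `intergenic_regulatory`.  The mask catalogue
implements the named predicates — LOFTEE high-confidence LoF, missense with
CADD > 25, all-coding, all-noncoding, GERP > 2, JARVIS > 0.99,
SpliceAI > 50 — all with strict inequalities and a strict MAF < 0.1% rare
cut; a missing score excludes a variant from score-dependent masks.  The
unscored "all-noncoding" mask exists per unit because most real aggregate
signals are detectable without score thresholds.  Sliding windows are 2 kb
at 1-kb step, coding variants excluded; trailing partial windows at the 3′
edge are emitted (coverage of edge variants beats tidy uniformity); empty
windows are retained but flagged untestable.  Constraint windows require
z ≥ 4 (inclusive); conserved windows require the 99th phastCon percentile
and are discarded on any exon overlap, even 1 bp.

## Single-variant association

Protein levels are rank-inverse normalised at runtime with the Blom offset
(c = 3/8, average ranks for ties).  The scan tests MAC ≥ 5 variants by OLS
with covariates, implemented by one Frisch–Waugh projection (covariates
swept from y and all dosages once; equivalence with the full regression is
a test, not an assumption).  P values use df = n − k − 2; the standalone
log-P routine defaults to df = N − 2, matching the convention used when
recomputing underflowed P from β and s.e. alone, with the covariate-aware
mode available.  The log-space tail is a Lentz continued fraction for the
regularized incomplete beta evaluated entirely in logs; for small |t|
(where nothing can underflow) the direct survival function is used.  It
agrees with a 50-digit oracle to ~1e-15 relative up to |t| = 300 at
N = 50,000.

Independent signals come from forward–backward selection: add the smallest
conditional-P variant while it clears 2.95e-10 (ties: smaller P, then
larger MAC, then position), then drop any selected variant whose joint P
rises to or above the threshold, until stable.  Because the LD panel *is*
the discovery sample, conditional statistics are computed by exact
individual-level residualisation, so the final joint estimates coincide
with the direct all-in-one regression to machine precision — that
equivalence is the acceptance oracle.  The variance-explained-ratio
collinearity filter of the original summary-statistic implementation is
deliberately absent (it discards genuine large-effect signals in this
setting); a pairwise r² > 0.99 guard prevents singular fits instead.
`diff_freq` is kept in the interface but cannot trigger with an in-sample
panel.

## Aggregate tests

Weights are the Beta(MAF; 1, 25) density (the regenie/SKAT convention; the
source is silent on weights, and a flat-weight option exists).  BURDEN
regresses the weighted allele count, projected off the conditioning space,
on the adjusted phenotype (t-test, df = residual dof − 1).  SKAT uses
Q = Σⱼ wⱼ²Sⱼ² with Sⱼ the score of the projected genotype against the
adjusted phenotype.  Its null is evaluated in the exact finite-sample ratio
form: with σ² estimated from the same residuals, {Q/σ̂² ≥ r} is an event
about a linear combination of independent chi-squares with signed weights
(λᵢ − r/ν on the kernel eigenvalues, −r/ν with multiplicity ν − m), whose
tail is computed by Imhof characteristic-function inversion with the
integration variable rescaled to the mixture's natural frequency, and by a
Kuonen saddlepoint in the far tail (finite in log space arbitrarily far
out).  This matches 20,000-permutation nulls within Monte-Carlo error at
n = 200, where the usual asymptotic mixture is visibly biased.  A
permutation fallback exists for oracle use in tests.  ACAT-V combines
per-variant t-test P values with squared Beta-density weights through the
Cauchy transformation, with P clipped to [1e-300, 1 − 1e-16] to keep tan()
finite; ACAT-O combines the three frameworks with equal weights.  The
singleton test is the burden test on MAC = 1 members.  All-mask combines
per-mask ACAT-O values per unit and refuses to mix coding with noncoding
masks (gene units are split into coding and proximal halves for exactly
this reason).

Reduction laws anchor correctness: on a one-variant unit, BURDEN, SKAT,
ACAT-V and the singleton test all collapse to the same single-variant
t-test (tolerances 1e-10 / 1e-8 / 1e-12).

## Layered conditioning and independence

Step (1) residualises the phenotype on covariates, the common (MAF > 0.1%)
joint leads and *every* cognate coding variant regardless of significance;
duplicate conditioning columns are dropped by pivoted QR.  The 0.1% cut is
the default; the 1% variant of the rule is available by configuration (the
two appear in different places in the source material).  Step (2) ranks
significant aggregates by ACAT-O P (ties: smaller span, then position),
records the top one, adds all its member variants to the conditioning set
and re-tests the remaining initially-significant aggregates until none
clears 8.71e-9; non-convergence raises with partial results attached.
Step (3) counts joint-lead members per recorded aggregate; step (4)
re-tests them conditioning additionally on every identified pQTL and
reports P before/after.

## Coverage QC and enrichment

A base passes when strictly more than 90% of assessed samples exceed depth
8; a protein passes when strictly more than 99.5% of bases pass over both
the gene span and the full window (the assessed-sample subset is a
parameter, since real coverage is typically computed on a sub-cohort).  The
discrepancy filter excludes proteins whose largest |β_marginal − β_joint|
lies strictly beyond the linear-interpolation 90th percentile across
proteins, computed across all proteins supplied (whether to restrict to
coverage-passing proteins first is left to the caller).  The logistic
enrichment of problematic-region overlaps adjusts for window length (the
column is dropped when it is constant, as in fixed-window simulations) and
falls back to an L2-penalised fit, flagged, under separation.

Fisher consequence enrichment is the exact two-sided test per category with
a Bonferroni flag at 0.05/k and Haldane-corrected odds ratios on zero
margins.  Bootstrap regulatory enrichment draws, per simulation, as many
pool elements as there are observed signals (without replacement by
default; a with-replacement flag exists), counts any-overlap per stratum,
and reports the plus-one empirical P, (1 + #{null ≥ observed})/(1 + n_sim)
— never zero, decreasing in the observed overlap.  Aggregate intervals
count as overlapping a stratum if they overlap any of its regions
(any-overlap; per-region counting is not implemented).  Empirical
significance thresholds re-run the full single-variant and aggregate scans
on 20 independent standard-normal traits and return the class-wise minimum
P values; the pipeline accepts the study-scale constants (2.95e-10,
8.71e-9) as defaults since desk-scale fixtures have far fewer tests.

## Numerical and design notes

* Determinism: every stochastic component takes an explicit seed; pipeline
  tables are written with fixed float formatting, so identical
  config + inputs + seed reproduce byte-identical outputs (tested).
* Degenerate inputs: constant phenotypes, monomorphic variants in LD
  computations, empty conditioning sets, single-class logistic outcomes,
  and zero-carrier units all raise or flag explicitly rather than produce
  numbers.
* Problem sizes: simulations in the test suite run at 200–5,000 samples and
  400–1,600 variants per locus with thresholds interpreted via their
  carrier-count analogues; these sizes were chosen so each statistical
  check retains clear power while a full run of the suite stays
  interactive.  The demonstration cohort under `analysis/` uses 2,000
  samples with thresholds of 1e-7 for the same reason.
* Limitations: no mixed-model/relatedness handling (samples are exchangeable
  by construction), no multi-allelic or structural variants, no transcript-
  level consequence prediction (annotations are inputs), batch effects are
  independent additive factors, and the bootstrap enrichment treats strata
  independently.
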