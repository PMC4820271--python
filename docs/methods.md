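# Methods

This note documents the models, estimators and design choices behind
`musselmix`, and what the synthetic data generator does and does not
emulate.

## Setting

Two blue-mussel taxa — *Mytilus edulis* (ME) and *M. trossulus* (MT) —
meet in subarctic contact zones and hybridise to a limited degree.
Individuals are genotyped at four co-dominant allozyme loci (Est-D, Gpi,
Pgm, Odh) that are *partially* diagnostic: the compound allele more
frequent in MT (the T-allele) differs from the ME reference frequency by
roughly 70–95 percentage points per locus, not 100.  Everything in the
package follows from the interplay of three facts: (i) only 8 allele
copies are observed per individual, (ii) the loci are imperfectly
diagnostic, (iii) populations are physical mixtures of two gene pools
plus a minority of true hybrids.

## Compound pooling and hybrid indices

An allele is pooled to T when its reference frequency in MT strictly
exceeds that in ME; exact ties go to E with a warning (a deterministic,
conservative rule — a tie carries no diagnostic signal).  The T-score of
an individual is its T-allele count over the scored loci (0–8 for four
complete loci); individuals missing loci keep a score plus
`n_loci_scored`, and are excluded from T-score classification below four
scored loci because the 0–8 class bands are not rescalable without
changing their operating characteristics.

The sample-level T-frequency rescales each locus's observed compound
frequency linearly between the parental references,
(f_obs − f_ME)/(f_MT − f_ME), clips into [0, 1] (observed frequencies
can fall outside the reference span by sampling noise) and averages over
loci.  Scaling before averaging weights every locus equally on the
ancestry scale regardless of how diagnostic it is; the two orders
coincide when reference differentials are homogeneous.

## Disequilibrium statistics and mixture maxima

F_IS = 1 − H_obs/H_exp per locus with H_exp = 2p(1−p) from the sample
compound frequency, uncorrected for sample size (the plain estimator; a
small-sample correction would belong in `_het_stats` if ever wanted).
R′ is the composite (phase-free) correlation of T-dosages per locus
pair: Burrows' Δ standardised by √((p₁q₁+D₁)(p₂q₂+D₂)), where D is the
within-locus Hardy–Weinberg departure — algebraically the Pearson
correlation of the two dosage vectors.  The composite form is the right
one for unphased diploid genotypes; a gametic measure would require
phase we do not observe.

Because the loci are not fully diagnostic, raw F_IS/R′ values are
referred to **mixture maxima**: the values a non-interbreeding 50:50-style
mixture of the two pure taxa would show at the same mean allele
frequencies.  Per locus the mixing proportion m solves
f_obs = m·f_MT + (1−m)·f_ME (clipped to [0,1]); m̂ averages the per-locus
solutions (a least-squares joint fit gives the same answer to within
noise at four loci and is not exposed).  At that m:

* F_IS max = 1 − H_within/H_pooled, the Wahlund deficit, with
  H_within = m·2f_MT(1−f_MT) + (1−m)·2f_ME(1−f_ME);
* R′ max per pair = 4m(1−m)·Δf_j·Δf_k / √(V_j·V_k) with
  Δf = f_MT − f_ME and V the mixture dosage variance (within-component
  binomial variance plus the between-component term).

Both equal 1 for fully diagnostic loci at m = 0.5 and vanish at
m ∈ {0, 1}.

## Expected T-score distributions and the exact test

Under local panmixia the dosage at locus ℓ is Binomial(2, t_ℓ); the
total-score distribution is the convolution over loci (verified in the
tests against full 3⁴ enumeration).  Under a non-interbreeding mixture
the distribution is the m-weighted average of the two parental panmictic
distributions.  Observed score counts are tested against either null
with a Monte-Carlo exact test: the chi-square distance over score
categories (adjacent categories with expected count < 1 pooled
left-to-right; an under-threshold remainder is kept separate so that
observations in a zero-probability tail stay visible), null replicates
drawn multinomially at the observed N, and the add-one p-value
(1 + #{χ²_sim ≥ χ²_obs})/(1 + n_reps), which is never exactly zero.
Default 2000 replicates; the seed is a required argument.

## Two-population admixture model

The Gibbs sampler implements the standard admixture model for unlinked
loci with uncorrelated allele frequencies: per population and locus a
Dirichlet(1) prior on frequencies, per individual an ancestry proportion
q with symmetric Beta(α, α) prior, and each observed allele copy
descending from population 1 with probability q.  Sweeps alternate
copy-origin indicators, conjugate Dirichlet frequency updates and
conjugate Beta ancestry updates; α is updated by a Metropolis step
(uniform prior on (0, 10], normal proposal, sd 0.025) by default.

Updating α matters: with α fixed at 1, a pure individual's posterior
mean ancestry cannot exceed 9/10 with 8 allele copies, which destroys
the near-0/1 purebred scores this analysis relies on.  On hybrid-zone
data the posterior α settles around 0.1–0.15 and purebred scores
concentrate within ~0.02 of the boundaries.  `update_alpha=False` is
available for sensitivity checks.

Defaults are 30,000 burn-in and 50,000 kept sweeps.  The individual
score (ISS) is the posterior mean of q; label switching is resolved
after the fit by orienting the population with the higher estimated
compound T-frequency as MT (the chain never switches labels in practice
at this degree of differentiation, so post-hoc orientation suffices).
PSS is the arithmetic sample mean of ISS.  A split-half comparison of
the kept chain flags possible non-convergence (warning, not failure)
when the two half-means differ by more than 0.1 for over 5% of
individuals.

What the model estimates deserves emphasis: ISS estimates the *realized*
genome fraction (share of the 8 copies inherited from MT), not a latent
mixing parameter; with 4 loci the two differ by binomial noise with sd
up to √(q(1−q)/8) ≈ 0.18.  Parameter-recovery checks therefore score ISS
against realized ancestry.  The K=2 fit also systematically *purifies*
its parental frequency estimates relative to the true parental
populations, because allele copies of admixed individuals are softly
assigned toward the population that makes them likelier.  This bias is
why calibration cohorts (below) are simulated from the registry's
reference frequencies when those are available, not from fit estimates.

## Known-ancestry simulation and threshold calibration

Six genotype classes are simulated from parental frequency tables — ME,
MT, F1, F2 and both first backcrosses — assuming Hardy–Weinberg
proportions within taxa and free recombination between loci (the four
allozymes sit on different linkage groups).  Calibration samples mix the
classes 80:80:10:10:10:10 (N = 200, six replicates by default),
emulating field samples of roughly equal parental shares with ~20%
hybrids.

Classification operates on the three-way compound classes (ME, MT,
hybrid; finer hybrid categories are not attempted — four loci cannot
support them).  The T-score rule maps 0–1 → ME, 7–8 → MT, 2–6 → hybrid.
The ISS rule uses two thresholds calibrated on the labeled simulated
scores by one of four criteria: the purebred criteria place the lower
threshold at the 95th (or 90th) percentile of true-ME ISS and the upper
at the 5th (10th) percentile of true-MT ISS; the hybrid criteria split
the complement symmetrically, using the ((100−e)/2)-th and
(100−(100−e)/2)-th percentiles of true-hybrid ISS.  Percentiles
interpolate linearly between order statistics (threshold values are
sensitive to the convention, so it is fixed and documented).  Boundary
values classify as purebred.  Methods are compared by per-class
efficiency (recall) and accuracy (precision) from the 3×3 confusion
table — a class never predicted has undefined precision and enters the
mean as 1 with a warning — and overall performance = mean efficiency ×
mean accuracy; the best criterion (ties broken toward higher hybrid
efficiency) classifies the empirical data.

Calibration can run in two modes: `simulated_only` (default; each
replicate mixture is fitted alone) and `joint` (each replicate is
co-analyzed with the empirical genotypes, and empirical individuals are
then classified by their co-analyzed scores averaged over replicates, so
thresholds and empirical scores share one scale).  The joint mode is the
more faithful protocol when empirical data exist; the simulated-only
mode is cheaper and performs equivalently on the synthetic study.

## Morphology and substrate ecology

The dark-strip index is Z = a/l; Z = 0 exactly (an unbroken strip)
defines the T-morphotype, any positive gap the E-morphotype.  The
threshold is exact by design — measurement noise belongs in the data
generator, not the classifier.  A completely absent strip is coded
a = l (Z = 1).  Genotype–morphotype concordance reuses the
efficiency/accuracy vocabulary on the two purebred classes (expected
morphotypes MT → T, ME → E), with hybrids excluded or reported
separately.  Densities: bottom cores count/side² (default 16×16 cm);
algal samples scale the tuft count by total-to-tuft algae weight over
the frame area (default 0.25 m²); both estimators are linear in counts
and invariant to splitting a tuft.  Substrate contrasts are per-site
algae-minus-bottom frequency differences with percentile bootstrap CIs
(default 1000 resamples, seeded) — deliberately simpler than a
mixed-model analysis, which is out of scope here.

## Synthetic study generator

The generator emulates a 31-site survey along a linear MT-ancestry
gradient (site targets 0.02–0.93, ~48 mussels per site, ~1500 total).
Defaults, chosen once as realistic study conditions:

* parental compound T-frequencies Est-D (0.05, 0.95), Gpi (0.02, 0.97),
  Pgm (0.10, 0.85), Odh (0.05, 0.90) — differentials 0.90/0.95/0.75/0.85
  with ME references near zero, the asymmetry characteristic of this
  panel; each locus carries one T-pooled and two E-pooled alleles
  (E mass split 70:30) so pooling is exercised non-trivially;
* hybrid fraction 0.20 at maximally mixed sites, attenuated by
  4s(1−s) toward pure sites (pure populations cannot harbour many
  hybrids), split equally over F1/F2/BC_ME/BC_MT;
* morphotype emission P(T-morph) = 0.03 for pure ME and 0.80 for pure
  MT, interpolated linearly in the true MT genome fraction for hybrids
  (the simplest monotone model; real hybrid morphology tracks sample
  background in more complicated ways — this emission model is
  synthetic-only and nothing downstream depends on its form);
* shell length lognormal with CV 0.3, ME mean 20% above MT (30 vs
  25 mm); ligament length 0.45·L; measurements rounded to 0.1 mm with
  an 0.1 mm floor on the strip gap of E-morphotypes so rounding cannot
  silently flip a morphotype;
* substrate P(algae) rising linearly from 0.30 (ME) to 0.70 (MT);
* per site three bottom cores and three weighed algal tufts with
  Poisson counts around a lognormal site density (mean 200 m⁻²).

Everything is reproducible from the master seed, and the truth manifest
(classes, genome fractions, morphotype and substrate draws) supports
parameter-recovery scoring.  The generator does **not** emulate: spatial
autocorrelation among sites, larval dispersal, assortative mating or
selection within sites, later-generation hybrids (F3+, double
backcrosses), genotyping error, or linkage.  Passing recovery tests on
this generator therefore demonstrates the estimators' correctness under
the stated sampling model, not robustness to those real-world features.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to run
on one CPU in minutes: the classification experiment uses the standard
six replicates of N = 200 with full-length chains (30k + 50k sweeps,
~7 s per fit); the whole-pipeline recovery check runs the default
synthetic study with 3k + 6k sweeps, which the split-half diagnostic
accepts at these data sizes; unit tests use shorter chains still.
Monte-Carlo exact tests default to 2000 replicates (the add-one p-value
floor is 1/2001).  Seeds are mandatory wherever randomness enters;
child seeds are spawned from the master seed, so any run is exactly
reproducible.

Degenerate inputs are handled explicitly: monomorphic loci drop out of
F_IS/R′ with warnings; loci with coincident parental references are
excluded from T-frequency and mixture maxima; individuals with no scored
locus are flagged unscorable; empty samples are omitted from PSS;
infeasible threshold criteria (lower ≥ upper) are reported infeasible
rather than silently reordered.

## Known limitations

* Hybrid-fraction estimates from threshold classification are slightly
  biased upward in purebred-dominated surveys (~4 points at the
  synthetic defaults): the pure-95 criterion tolerates 5% purebred
  leakage into the hybrid class by construction, which outweighs the
  hybrids lost below nominal hybrid efficiency.  Users comparing hybrid
  fractions across studies should compare criteria, not just point
  estimates.
* With four loci the ISS posterior for genuinely admixed individuals is
  wide; per-individual hybrid calls are far less reliable than
  sample-level summaries (the per-class accuracies quantify this).
* The two-population model assumes exactly two source gene pools;
  a third contributing taxon would bias both frequencies and scores.
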