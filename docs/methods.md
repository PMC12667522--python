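# Methods

This note documents the statistical model behind `phosphodyn`, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Calibration of phosphosite abundance

Each protein row and each site row is divided by its across-sample mean,
and the site is then divided sample-wise by its mean-scaled parent
protein, giving the unit-free relative abundance r(s, j).  Two explicit
rules handle degenerate intensities:

* **Protein zeros** are replaced, before scaling, by the smallest
  non-zero intensity of the entire protein dataset (a single global
  floor, not per-row).  Replaced cells are counted and flagged.
* **Site zeros** are kept as zeros (r = 0); the replacement rule is a
  protein-side device to keep the division defined, and inventing a
  site-side imputation would manufacture signal.  Sites that are zero in
  every sample cannot be mean-scaled and are dropped with a log entry.

Sites whose protein is absent from the protein table fall back to their
mean-scaled values and are flagged `site-only`; protein-level variation
then remains in r for those sites, which is the honest behavior — there
is nothing to calibrate against.

The localization filter keeps sites with probability strictly above the
threshold (default 0.75, the class-I convention).  A threshold of 0 is
allowed and keeps every site with positive probability.

**Analysis scale.** Downstream tests run on log2(r + ε) by default, with
ε = 10⁻³ × the smallest positive r; the log stabilizes the variance of
multiplicative MS noise and makes the ANOVA normality assumption
reasonable.  `scale: raw` switches to untransformed r; the choice is
recorded in the run manifest.  Fold changes are always ratios of raw
group means — a fold change is a ratio by definition, whatever scale the
test used.

## Differential screening

* Multi-group: classical (pooled-variance) one-way ANOVA; BH step-up
  adjustment across features; FC = max/min of stage means; significance
  = P.adjust < α and FC > cut, both strict.  Pairwise calls use
  Tukey-adjusted p (Tukey–Kramer for unbalanced designs) and the
  pairwise max/min FC with the same strict gates.
* Two-group: two-tailed Student's t (equal variance), raw p < α,
  FC > cut in either direction, and the `Intensity_1 > 0` rule — the
  feature's summed raw intensity in the first-listed condition must be
  positive.  The first-listed stage of the design is the reference
  condition; "down" means the second (test/knockout) group is lower.
* Zero-variance degeneracies (exact on zero-noise synthetic data):
  all groups identical ⇒ F = 0, p = 1; zero within-group variance with
  unequal means ⇒ F diverges and p is floored at the smallest positive
  double (5e-324) and flagged `zero_variance`, so noiseless fixtures
  never produce NaNs.

Tukey p-values are computed from an in-package vectorized Gauss–Legendre
quadrature of the studentized range distribution (120 nodes per axis on
its standard double-integral form).  It agrees with the reference
implementation to ~1e-14 and evaluates thousands of quantiles per
second, which per-feature screens require.

## Temporal modules

Significant sites are represented by their stage-mean trajectory,
z-scored across stages with the sample-SD (n−1) convention; rows with
zero variance across stages are excluded and logged.  Clustering is
Bezdek fuzzy c-means with Euclidean distance:

    u(i,k) = 1 / Σ_j (d(i,k)/d(i,j))^(2/(m−1)),
    c(k) = Σ_i u^m x_i / Σ_i u^m,   J = Σ u^m d².

Points coinciding exactly with a centroid receive full membership there
(singularity rule).  Initialization is a seeded k-means++-style draw;
5 restarts keep the lowest final J (FCM is non-convex); convergence is
max centroid displacement < 1e-6 with a 1000-iteration cap.  J is
non-increasing across iterations, which the tests assert on every run.

The fuzzifier defaults to the empirical estimate
m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134),
≈ 2.61 at N = 1000, D = 4.

The default cluster count is c = 5.  With four underlying temporal
patterns, c = 5 typically splits one pattern into two highly correlated
clusters; the centroid-correlation `merge_report.tsv` surfaces this so
that reducing five clusters to four modules is an explicit, auditable
user step rather than a hidden heuristic.  Hard labels are argmax
membership (ties broken toward the lowest cluster index, logged), with
an optional membership floor below which sites stay unassigned.

## Kinase–substrate enrichment

Background = quantified, localization-passing sites that are neither
significant nor assigned to any module, frozen after module assignment;
significant-but-unassigned sites belong to neither population.  For each
kinase (≥1 substrate resolved in the analyzed site universe; kinases
with none are dropped with a log entry) and each module:

* two-sided Fisher exact p by the minimum-likelihood rule, computed with
  exact integer combinatorics (the p is the correctly rounded float of
  an exact rational), so it matches exhaustive enumeration to rounding;
* sample odds ratio (a·d)/(b·c), with the Haldane–Anscombe +0.5 applied
  to all cells when any cell is zero (flagged).  The conditional-MLE
  odds ratio is a reasonable alternative; the sample OR was chosen for
  determinism and transparency.
* classification: hyperrepresented iff OR > 1.2 and p < 0.05;
  hyporepresented iff OR < 1/1.2 and p < 0.05; strict comparisons.
  No multiplicity adjustment is applied across kinase–module pairs —
  the classification thresholds raw p by design, and consumers should
  treat the calls as a screen, not as FDR-controlled discoveries.

A site with several annotated kinases counts once for each of them.

## Motif summaries

Windows are centered, odd-length, 1-based-position strings padded with
`_` beyond protein ends (default half-width 10, i.e. 21-mers; 13-mer
truncation is exactly equivalent to extracting at w = 6).  Frequency
matrices exclude padding from each position's denominator, avoiding
edge-of-protein bias.  Information content is R = log2 20 − H in bits;
the small-sample correction e_n = 19/(2·ln 2·n) is off by default (it
keeps the analytic examples exact) and available as an option.

## The synthetic generator

The generator emulates a TMT-style stage series: protein cells are
exp(base_g + stage effect + replicate noise), and a site cell is its
protein cell × a per-site stoichiometry × 2^(trajectory log2 effect) ×
lognormal noise, so sites genuinely co-vary with their proteins and the
calibration step is load-bearing.  Defaults (the study conditions):

* 4 stages × 4 replicates; 1000 proteins, 2000 sites; sites per protein
  drawn from a categorical over 1..10 with mean ≈ 2.4 (≈55% of
  phosphoproteins carrying ≥2 sites);
* four planted trajectories on the log2 scale — gradual decrease
  (1.5, 0.5, −0.5, −1.5), a dip at the third stage, a peak at the third
  stage, a peak at the last stage — each holding 15% of sites, the rest
  flat nulls;
* site-level lognormal noise σ = 0.5 (natural log), protein replicate
  noise 0.15 and protein stage effects 0.25 — with 4 replicates this
  puts the stage-mean signal-to-noise ratio near 3 for module sites;
* 1% sporadic zeros; 5% of proteins withheld from the protein table
  (their sites exercise the site-only fallback);
* localization probabilities from a Beta mixture (85% Beta(40, 2),
  15% Beta(2, 2)), so a realistic minority of sites fails the 0.75
  filter;
* residues drawn at 89.7 / 9.9 / 0.3% S/T/Y; a proline is planted at +1
  for 30% of S/T sites so logo matrices show the dominant
  proline-directed motif;
* 20 kinases with 100 substrates each — the density of a
  medium-confidence kinase–substrate predictor export, and enough for
  planted enrichment to survive the localization and significance
  attrition of the full pipeline; each planted kinase draws a substrate
  from its module with probability min(1, 5 × module fraction), decoys
  uniformly.

The knockout generator plants a configurable fraction of sites at an
expected KO/control ratio of 1/effect (default 15% at effect 2) under a
two-group, 4-replicate design; all other sites are null.

All randomness flows through one `numpy` Generator seeded by the config,
so a seed fully determines every emitted byte.

**What it does not emulate** — and hence what passing tests do not show
about real data: isobaric reporter-ion interference and ratio
compression, retention-time or fraction structure, peptide-level
ambiguity, correlated missingness (zeros are independent coin flips),
batch effects, and biological covariance between sites on the same
protein beyond shared protein abundance.  Within-stage biological
variance of real spermatid preparations is unknown; the defaults are
chosen for testability at realistic orders of magnitude.

## Problem sizes in the test-suite

Synthetic checks run at 2000 sites (screens, null calibration, module
recovery with 10 seeds) and 400-site configurations for pipeline smoke
and determinism tests; the exact-test oracle sweeps all 2×2 tables with
total ≤ 40.  These sizes keep the whole suite at a few minutes while
leaving every statistical check well-powered.

## Known limitations

* The classical ANOVA assumes homoscedastic groups; a Welch variant is
  not provided.
* No moderated (empirical-Bayes) variance estimation; at 4 replicates
  per stage the per-site variance estimates are noisy, and power numbers
  on synthetic data will be optimistic relative to limma-style analyses
  of real data.
* Site multiplicity (MaxQuant `___1/2/3` columns) is collapsed by
  summation, preserving total signal but discarding multiply-
  phosphorylated-peptide resolution.
* The enrichment background definition excludes significant-but-
  unassigned sites from both populations; with a low membership floor
  this population is empty, but with a high floor it can be sizable.
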