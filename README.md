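# phosphodyn

Stage-resolved phosphoproteomic inference for TMT-style time-course and
knockout designs: protein-calibrated phosphosite quantification,
differential regulation screening, fuzzy temporal module clustering, and
kinase–substrate module enrichment — plus a synthetic-data generator with
planted ground truth so the whole chain is testable end to end.

## The problem

Developmental processes such as spermiogenesis (the differentiation of
round spermatids into spermatozoa) are largely transcriptionally silent
and are steered at the level of protein phosphorylation.  A typical
experiment quantifies thousands of phosphosites and their parent proteins
across a handful of ordered stages (e.g. four spermatid steps × four
replicates in one TMT 16-plex run) and asks:

1. which phosphosites change beyond what protein abundance explains,
2. what temporal patterns (modules) those changes follow, and
3. which kinases are plausibly driving each module.

`phosphodyn` implements that inference chain for anyone consuming
MaxQuant-style `proteinGroups` / `Phospho (STY)Sites` tables plus a
kinase–substrate relation (KSR) table such as a GPS 5.0 export.

## The model

**Calibration.** With site intensities x(s, j) and protein intensities
p(g, j) over samples j, both are mean-scaled across samples and the site
is divided by its parent protein:

    r(s, j) = [x(s,j) / mean_j x(s,·)] / [p(g(s),j) / mean_j p(g(s),·)]

Protein zeros are replaced by the smallest non-zero value of the whole
protein dataset before scaling; sites whose protein was not quantified
keep their mean-scaled values (flagged `site-only`).  Sites with
localization probability ≤ 0.75 are removed.

**Screening.** Multi-group mode: classical one-way ANOVA on log2(r + ε)
with Tukey's post hoc test and Benjamini–Hochberg FDR control; the fold
change is FC = max(stage means)/min(stage means) on the raw r scale, and
a site is significantly regulated when P.adjust < 0.05 and FC > 2 (both
strict).  Two-group (knockout) mode: two-tailed Student's t-test with
gates p < 0.05, FC > 1.5 in either direction, and positive summed
intensity in the reference condition.

**Modules.** Significant sites are summarized by z-scored stage-mean
trajectories and clustered with Bezdek fuzzy c-means (Euclidean
distance, seeded k-means++ initialization, multi-restart).  The
fuzzifier m is estimated from the data shape by the standard empirical
rule (m ≈ 2.61 for 1000 features × 4 stages).  A centroid-correlation
merge report makes any cluster-count reduction explicit.

**Kinase enrichment.** For each (kinase, module) pair a 2×2 table counts
the kinase's substrate sites inside the module against the background of
quantified, localization-passing sites that are neither significant nor
assigned to any module.  A two-sided Fisher exact test (exact integer
enumeration) scores the association; the sample odds ratio
OR = (a·d)/(b·c) (Haldane–Anscombe corrected on zero cells) gives its
direction, and a kinase is called hyper-/hyporepresented when OR > 1.2
(or < 1/1.2) with p < 0.05.

**Motifs.** Residue-class fractions (pS/pT/pY), sites-per-protein
histograms, centered ±w sequence windows ("_"-padded at protein ends),
and position frequency / information-content matrices for logo renderers.

## Worked example

Run the full pipeline on the default synthetic experiment (1000 proteins,
2000 sites, four planted temporal modules, four planted module-specific
kinases among 20):

```sh
phosphodyn run --seed 7 --outdir demo_run
```

`demo_run/` then contains `calibrated_sites.tsv`, `differential.tsv`,
`membership.tsv` / `centroids.tsv` / `modules.tsv`, a `merge_report.tsv`,
`kinase_enrichment.tsv`, motif summaries, and a `manifest.json` with all
resolved settings, row-count reconciliation and output hashes.  The top
of the kinase table for that seed:

```
kinase  module  a   b    c   d    odds_ratio  pvalue    class
KIN004  1       19  165  23  995  4.98        2.1e-06   hyperrepresented
KIN003  2       14  165  29  989  2.89        3.3e-03   hyperrepresented
```

KIN004 was planted to drive the module peaking at the last stage; the
cluster whose centroid peaks at step 13–14 recovers it with ~5-fold
substrate over-representation.  On the same run, 734 of 1752 calibrated
sites (39%) pass the significance gates and the four cluster centroids
match the four planted trajectories.

The same chain runs on real tables by pointing the config at your files:

```yaml
inputs:
  proteins: proteinGroups.tsv
  sites: phospho_sites.tsv
  design: design.tsv        # sample <tab> stage
  ksr: gps_export.tsv
  fasta: proteome.fasta
  dialect: maxquant
```

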