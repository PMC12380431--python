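# Methods

## Overview

`spotrank` analyses spot-level spatial gene expression from a three-group
chemogenetic design: a treated group in which dopamine (DA) neurons carry the
excitatory hM3Dq receptor and receive its agonist CNO ("GqCNO"), a receptor
control receiving vehicle ("GqVeh"), and an agonist-only control ("CNO").
The pipeline runs in the order: data generation or loading → region
assignment and DA-disc selection → gene detection filtering → normalization
(with method evaluation) → per-gene dual-contrast scoring → hit calling →
cross-species congruence. Each stage is a pure function of its inputs, and
all randomness flows from a single integer seed.

## Capture-area selection

Visium capture areas are 55 µm discs pooling a handful of cells, so a
"dopamine-neuron disc" must be defined operationally. A disc is selected iff:

- **Marker rule.** At least `min_da_markers` (default 2) of the three DA
  markers (*Th*, *Slc6a3*, *Slc18a2*) have counts at or above
  `da_marker_threshold`. The threshold defaults to 1 count — plain
  detection — because the data's sequencing depth varies and any deeper
  cutoff would need justification the data cannot give; it is a plain
  config value rather than a hidden constant.
- **Soma rule.** The disc carries a soma flag (default required). Whether a
  disc contains a complete DA soma is an imaging judgment; the package
  consumes it as a per-spot boolean column. The synthetic generator plants
  it; users of real data supply it.
- **Glia rule.** No astrocyte/microglia marker (*Gfap*, *Aldh1l1*, *Aif1*,
  *P2ry12*) exceeds its per-gene quantile cutoff (default 0.90, computed
  over all tissue spots). A quantile is used because "high glia expression"
  must be scale-free across sequencing depths; a per-section scope is
  available (`glia_quantile_scope="section"`) since either reading is
  defensible.
- **Candidate rule.** The disc lies in a candidate region (SN or VTA).

Every disc records a pass/fail trace for each rule, so exclusions are
auditable. Selection is monotone: lowering the marker threshold or raising
the glia quantile can only grow the selected set (property-tested).

Region assignment votes each region's markers (count ≥
`region_marker_threshold`, default 10) and takes the strict winner; ties —
including no votes — leave the spot unassigned. Conservative tie-breaking is
deliberate: a mis-assigned control spot corrupts a contrast, an unassigned
spot merely shrinks it.

The gene-detection filter removes genes detected (count > 0) in fewer than
`min_rate` of spots, with an inclusive boundary (a gene at exactly the rate
is kept).

## FCS and SNS scoring

For one gene and one treated-vs-control contrast, with spot-level group
means µ, standard deviations σ (ddof = 1), and a two-sided unpaired t-test
p-value P:

    FCS = log2(µ_T / µ_C) · (−log10 P)
    SNS = ((µ_T − µ_C) / (σ_T + σ_C)) · (−log10 P)

FCS weights the log fold change by significance; SNS does the same for a
standardized mean difference and is defined even when a mean is 0. Both are
invariant under positive rescaling of all measurements and share the sign of
the mean difference. Numerical handling:

- P is clipped into [1e-300, 1] before −log10; P = 0 raised as an error in
  the scalar API.
- FCS is undefined when a group mean is ≤ 0 and no pseudocount is set; such
  genes carry `fcs_defined = False` and no FCS rank. A configurable
  pseudocount restores them.
- A gene constant in both groups with equal means is defined as t = 0,
  P = 1 (score 0, worst rank) rather than an error.

The default t-test pools variances (df = n_T + n_C − 2). This choice is
pinned by the summary-statistic reproduction check: the pooled test
reproduces both published slice-physiology p-values (0.05 and 0.17) from
their mean ± SEM summaries, while Welch gives 0.14 and 0.39. Welch remains
available per flag. Ranks are dense on the absolute score, descending.

**Hit rule.** A gene is a hit iff P < α (default 0.05) in *both* the
GqCNO-vs-GqVeh and GqCNO-vs-CNO-alone contrasts. With `top_k` set, hits must
additionally sit in the top k of both |FCS| and |SNS| rankings of the
vs-vehicle table ("appeared in both scoring metrics"); the default
`top_k="all"` reduces the rule to the dual-contrast threshold. Hits are
ordered by |SNS|, then |FCS|, then symbol — fully deterministic.

The two contrasts share the treated group, so their null p-values are
positively dependent; the dual-contrast false-positive rate is therefore
bounded by α (not α²) and is measured, not assumed, in the tests (empirically
~1% at α = 0.05 on the default study).

General-purpose tests in the same module: summary-statistic t-tests
(SEM converted to SD via SD = SEM·√n), a permutation test on |Δmean|
(exhaustive when C(n, n_a) ≤ 20 000, including the observed labeling in the
numerator and denominator; Monte-Carlo with the (k+1)/(n+1) correction
otherwise), the two-sample KS test, and step-down Šidák (Holm–Šidák)
adjustment.

## Normalization and its evaluation

Five methods are provided, each operating on observation rows (for
segment-level data one row is one library; at spot level, per-spot scaling is
the standard convention — aggregate with `pseudobulk_by_sample` first to
normalize at the sample level):

| method | action |
|---|---|
| quantile | rows share the rank-mean distribution, ties averaged |
| q3 | row scaled so its 75th percentile hits the cross-row mean of raw 75th percentiles |
| background | row divided by its mean negative-probe count (subtraction mode per flag) |
| libsize | row scaled to the cross-row mean total count |
| median | row scaled so its median over detected genes hits the cross-row mean of such medians |

SCTransform is recognised but not provided; requesting it raises an explicit
"unavailable" error and the evaluation report records it as unavailable
rather than silently dropping it.

Evaluation computes, per method, the mean |Pearson r| between M and A over
all row pairs (M = log2 ratio, A = mean log2 intensity, pseudocount 0.5 on
counts; |r| defined as 0 when M or A is constant) and the fraction of row
pairs whose normalized value distributions differ at a two-sample KS test
(p < α, default 0.05; exact p for n ≤ 25, asymptotic otherwise; a pooled
mode compares each row against the rest). Methods are ranked by MA score,
then KS fraction; exact ties (reachable only when everything is exactly 0)
keep the requested order. Pairwise KS is the default because "least
significance across samples" is most directly a statement about pairs.

Tie-averaged quantile normalization is exactly idempotent and makes sorted
row vectors exactly equal only on tie-free data; with heavily tied integer
counts the averaging perturbs the target distribution slightly. The package
keeps tie-averaging (the conventional behaviour) and documents the caveat.

**PCA input.** `pca_on_median_normalized` restricts genes to those expressed
(> 0 in total) in every region group, median-normalizes rows, and runs
centered PCA (full SVD). "Median-normalized input" could also mean per-gene
median centering; that reading is available behind
`per_gene_median_center=True`, with no intent assumed. Identical
observations return a zero embedding with a warning rather than an error.

**Activity scores.** Predicted per-spot activity scores are normalized by
dividing by their tissue section's mean, making each section's mean exactly
1 and removing section-level scale before group comparisons (by KS test).

## Cross-species congruence

Mouse DEGs are matched to a human DEG table by case-folded symbol; matched
genes enter a 2×2 table of change-direction signs. The default test is the
closed-form Pearson chi-square of independence,
χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, no continuity correction (the
intended n ≈ 50 is above small-sample regimes; Yates available). A zero
margin yields statistic 0, p 1 with a warning. Because the published
analysis could equally have tested concordant-vs-discordant counts against
50:50, that goodness-of-fit mode ships behind a flag; independence is the
default with no intent assumed. An optional FDR filter (e.g. adj. p < 0.02)
can be applied to the human side first.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Design.** Groups GqCNO (3 samples), GqVeh (3), CNO alone (2); regions
  SN (10 spots/sample), VTA (15), thalamus (12), CP (40), LSX (10), white
  matter (10) — within the per-region disc ranges such experiments report,
  sized so the DA contrasts see ~30 treated discs.
- **Counts.** Negative binomial per gene (mean 5 counts, size 10 — mildly
  overdispersed relative to Poisson, as spot-level counts are), Poisson per
  config flag. One RNG stream per dataset seed, with sub-streams spawned per
  (sample, region) block so block contents are stable.
- **Markers.** DA markers elevated 8-fold in SN and VTA; each region gets 3
  of its own markers elevated 8-fold at home (canonical symbols where the
  field has them: *Sox6* for SN, *Calb1* for VTA, *Prkcd/Ptpn3/Synpo2* for
  thalamus, *Ppp1r1b* for CP, *Mbp* for white matter, …).
- **Planted DEGs.** 20 genes scaled multiplicatively in every treated-group
  spot, folds cycling through 2, 3, 4 alternating up (f) and down (1/f) —
  all at least 2-fold, the regime the dual-contrast rule is meant to catch.
- **Nuisance structure.** 10% of DA-region spots get 10-fold elevated glia
  markers (contamination); DA-region spots carry the soma flag with
  probability 0.8 (midbrain discs hold roughly 5–10 somata, so most but not
  all discs contain a complete one — the value is a documented guess);
  20 negative probes at mean 1.0 counts everywhere.
- **Auxiliary generators.** `simulate_human_deg_table` plants a found-rate
  and a concordance probability against the mouse truth;
  `simulate_depth_series` makes a 6-sample × 2000-gene matrix whose rows
  differ only by library depth spanning 4-fold (noiseless mode returns the
  expected values, giving exactly proportional rows);
  `simulate_two_group_values` draws seeded Gaussian groups for the scalar
  tests.

What the generator does **not** emulate: spatial autocorrelation beyond
region blocks, cell-type mixtures within a disc, batch/slide effects,
zero-inflation beyond NB, or mean–variance trends across genes. Passing
tests therefore demonstrate the pipeline's correctness and calibration under
its stated model, not robustness to every artefact of real tissue data.

## Problem sizes and determinism

The default study (2000 genes, 776 spots) runs every stage in about a
second, so tests and the acceptance script use it directly; Monte-Carlo
calibrations use 300–1000 replicates, enough for the KS-uniformity checks
they feed. Null-calibration checks of the KS test itself use n = 200 per
group with exact p-values because the KS statistic is discrete (atoms at
k/n) and at much smaller n its p-values fail uniformity checks by
construction.

Reruns with the same config and seed reproduce all numeric artifacts byte
for byte; the run manifest records a canonical-config hash (timestamps
excluded), software version, per-stage counts and surfaced warnings.

## Known limitations

- The per-gene t-test on counts is a normal-theory approximation; at very
  low means or very small disc counts a count model (or the permutation
  test) is preferable.
- FCS is undefined for zero means without a pseudocount; such genes are
  excluded from FCS ranking and flagged, which can drop strongly
  suppressed genes from `top_k`-restricted hit lists.
- The glia exclusion quantile removes a fixed fraction of spots even in
  contamination-free data; it trades sensitivity for purity by design.
- Region assignment assumes region markers are informative at the chosen
  threshold; with heavily overlapping marker panels (e.g. *Prkcd* in both
  thalamus and LSX) markers must be curated per region.
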