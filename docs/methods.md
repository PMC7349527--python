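# Methods

## Growth dose-response model

Hypocotyl growth after a short heat treatment at temperature *x* (°C) is
modeled as `growth(x) = max / (1 + (x/T50)^(-H))` with `max` the unstressed
growth rate (cm·day⁻¹), `T50` the temperature of half-maximal growth and
`H` the signed Hill slope (negative for decreasing curves; stored signed,
displayed as a "negative Hill slope" magnitude). Fits are by nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective)
jointly over all replicates, on the normalized scale (fraction of growth
at the lowest temperature) by default; raw-scale fitting is available.

*Initialization and restarts.* `max` starts at the mean growth at the
lowest temperature, `T50` at the temperature whose mean response is
nearest half-max, `H` at −10; four additional restarts jitter these
(±20%, ±5%, ×0.3–3) and the lowest residual sum of squares wins. Standard
errors come from the Jacobian-based covariance at the optimum
(`inv(JᵀJ)·RSS/dof`). Fitting requires ≥ 4 distinct temperatures and
observations on both sides of half-maximal growth; data entirely on one
side of the transition raise an explicit error rather than extrapolating.

*Derived metrics.* EC*p* is the temperature of fractional growth
**reduction** *p*: `ECp = T50 · (p/(1−p))^(−1/H)`, so EC10 < T50 < EC90
for decreasing curves and the eustress range is (EC10, EC90). The identity
`|H|·log10(EC90/EC10) = log10(81)` is exact and is asserted to 1e-9 for
every fit. Note the published prose can also be read with the opposite
ECp convention (p = growth *remaining*, which merely swaps the EC10/EC90
labels); the reduction convention is this package's documented choice and
leaves the eustress width and all conclusions unchanged.

## Synthetic data generator

The generator defines the study conditions; its defaults mirror the
original design and are not tuned per test.

* **Design**: 4 genotypes × {25, 39, 45} °C × 2 biological replicates;
  growth assay over {25, 40, 42.5, 45, 45.7, 50} °C with 8 replicates and
  Gaussian noise of 5% of `max` (floored at zero growth).
* **Genotypes**: LA2661 (T50 45.6 °C, H −26), LA1994 (45.4, −25),
  Moneymaker (45.0, −13), Red Setter (43.8, −24). The published figures
  give these only graphically, so the defaults encode the stated
  qualitative structure: the two accessions most tolerant, Red Setter
  clearly lowest, Moneymaker intermediate with a much shallower slope
  (widest eustress range), and 39 °C below every genotype's responsive
  zone while 45 °C sits near the tolerant genotypes' T50.
* **Counts**: negative binomial via the gamma–Poisson mixture. Lognormal
  baseline expression weights (log2 sd 1.8); 15% of unplanted genes
  unexpressed (the original dataset found ~25.5k of ~30k genes expressed);
  dispersion φ = 0.05 median with lognormal gene-to-gene scatter (log-sd
  0.3), typical of bulk tag data; library size 2×10⁵ reads per sample —
  deliberately scaled down from the 5–10 M of a real 3′-tag library so
  simulations run in seconds (a documented knob). Expected counts are
  proportional to relative abundance × library size with no
  transcript-length term (one tag per transcript).
* **Planted truth**: per expression class, genes receive a canonical
  (lfc_39v25, lfc_45v25) pair scaled by the effect size (default 2 log2
  units); the 45v39 fold change is the difference by construction, so
  planted triples are always internally consistent. Classes 12 and 14
  (no 25 °C-referenced change but a significant 45-vs-39 shift) cannot be
  realized by sign-consistent truth and arise only from threshold effects
  in noisy data; they are not planted. A fifth of each class's genes are
  planted in only three genotypes to populate concordance level 2.
  Genotype-contrast genes are planted per condition (Red Setter alone, or
  Red Setter + Moneymaker, shifted ±2 log2 at one temperature via
  compensating offsets), half higher and half lower in the focal
  genotype. Upregulated class genes carry the "stress" category with
  probability 0.5 against a uniform 35-bin background, planting a
  category enrichment in the common-up set.
* **Determinism**: one global seed fans out to per-stage substreams
  (`numpy.random.SeedSequence`); regeneration from the serialized truth is
  bit-identical.

What the generator does **not** emulate: read-level sequencing artifacts,
alignment/mapping error, the pooling of stress and recovery RNA before
sequencing, batch effects, and correlated gene–gene expression structure.
Passing tests therefore demonstrate the correctness and calibration of the
procedures under clean NB sampling, not robustness to those real-data
complications.

## TPM and relative abundance

`TPM_gs = count_gs / Σ_g count_gs × 1e6` (no length term). For the
cross-genotype comparison at one temperature, A(x) is the replicate-mean
TPM per genotype (means taken on the TPM scale) and X(x) = A(x)/Σ_i A(x);
genes with Σ_i A = 0 are excluded rather than assigned 0/0. Display values
are min–max rescaled to [0, 1] per table (per temperature and gene set),
feeding the treemap color scale; the polygon layout itself is out of
scope. Category screens run Kruskal–Wallis across genotypes (flag at
p < 0.005) by default — one-way ANOVA is available since the published
figure legends and methods text name different tests — plus Shapiro–Wilk
normality per genotype (0.05) and Tukey all-pairs comparisons (0.05),
via scipy/statsmodels.

## Differential expression

Per gene, a 2-parameter NB GLM (log link, library-size offsets, group
indicator) is fit by vectorized IRLS; the Wald z on the group coefficient
gives a two-sided p and BH adjustment (statsmodels) controls FDR.
Dispersion is estimated by method of moments per gene, a mean–dispersion
trend `φ(μ) = a0 + a1/μ` is fit across genes, and per-gene estimates are
shrunk linearly toward the trend with weight 0.2 on the gene-wise value —
chosen a priori from the ~1 residual degree of freedom available at n = 2
per group, where gene-wise estimates are nearly uninformative. This is a
deliberately simple stand-in for the empirical-Bayes machinery of
dedicated DE packages (no Cox–Reid adjustment, independent filtering or
LFC shrinkage); its null calibration (fraction p < 0.05 ≈ 0.05 on 5,000
null genes) and planted-effect power are verified by test, and one test
cross-checks direction and significance agreement against pydeseq2 on
planted effects. Genes with all-zero counts are reported untested; genes
with one all-zero group are tested with a half-count added to every sample
(the same 0.5 floor backs their fold change). Thresholds: adjusted
p < 0.01 for temperature contrasts, raw p < 0.05 for genotype contrasts
(whether the published genotype contrasts used adjusted p is not stated;
BH is available behind a flag). Power simulations plant signal at a
realistic 5% density (10 of 200 genes) so the FDR context matches real
data rather than a pure global null.

## 15-class scheme and concordance

The (39v25, 45v25, 45v39) status triple (up/down/ns) maps to classes 1–15:
the 39v25 status fixes the block (up → 1–5, down → 6–10, ns → 11–15) and
three anchors pin the numbering (1–3 up at both temperatures, 7 down at
39 °C only, 13 unchanged). The full 27-triple table is a package
convention held in one editable mapping — the published material does not
print it, so subclass numbering beyond the anchors is a documented
convention, not a claim about the original numbering. Classification keys
on significance status only (no fold-change floor). Level 1 requires the
full status triple identical in every genotype (classes that absorb a free
third status would otherwise conflate distinct profiles); level 2 requires
agreement of the 39v25 or the 45v25 statuses without level-1 identity.
Direction tags accumulate level-1 and level-2 members; a gene can carry
both a 39 °C and a 45 °C tag but never counts in both levels.

## PCA gene-contribution selection

Genes are the individuals, replicate-mean expression columns the
variables; columns are centered and unscaled, on raw TPM by default (the
published analysis does not state the scale; log2(TPM+1) is available).
Contribution of gene g to component c = 100·score²/Σ score², summing to
100% per component. A gene is selected when its PC1 **or** PC2
contribution reaches tenfold the equal-share baseline 100/N% (boundary
inclusive), N being the expressed genes of the scope (TPM > 0 in ≥ 1
sample; the original count of 25,478 yields the printed 0.003925% /
0.03925%). Both published scopes are first-class: one PCA per genotype
over temperature means, one per temperature over genotype means, with an
exhaustive (2^k − 1)-cell Venn table across scopes. On the raw-TPM scale
the selection is abundance-weighted: only the most abundant responders
clear the bar, which matches the original observation that the selection
favors the strongest absolute changes.

## Genotype-contrast rules

Rule (i): significant (raw p < 0.05) same-direction change of Red Setter
against **both** tolerant genotypes at a condition ("solely" is read as:
significance is required against exactly those two comparisons, with no
constraint on the intermediate genotype; a stricter reading is behind a
flag). Rule (ii), 25/39 °C only: rule-(i) genes where Moneymaker likewise
differs significantly from both tolerant genotypes in Red Setter's
direction. Rule (iii), 45 °C: with r_G = log2((TPM45+1)/(TPM25+1)) on
replicate-mean TPM, selected iff (r_focal > 0 and r_focal − r_inter > 1)
or (r_focal < 0 and r_inter − r_focal > 1). The published formula prints
a log2 of a TPM *difference*, which is undefined for negative differences;
it is implemented as the log2 ratio with pseudo-count 1 — an
interpretation, flagged here deliberately. The two rule-(i) contrasts
share the focal genotype's samples, so their test statistics correlate
(~0.5); the exact null selection rate of the conjunction at p < 0.05 is
0.0092 for perfectly calibrated tests, far below the nominal 5%.

## Enrichment

Two-sided Fisher's exact test (scipy) per category on the 2×2 set ×
category table against the expressed-gene universe (configurable), flags
at 0.01/0.05, no multiple-testing correction by default (optional BH
column) — both enrichment and depletion are flagged. The merge table
collapsing MapMan-style bins (carbon-fixation bins into "C-fixation",
etc.) is idempotent and rejects conflicting targets; "misc", "not
assigned", "unknown" and "DNA" are hidden from default reports but kept in
the data.

## Platform concordance

ddCt: replicate-averaged ΔCt = Ct_target − Ct_reference per condition,
ΔΔCt against the control condition, relative level 2^(−ΔΔCt); the
reference gene cancels plate offsets. Concordance between two platforms:
per-gene Pearson correlations over matched conditions, summarized by a
Gaussian fitted by least squares to a 10-bin histogram over [−1, 1]; the
one-sided 95% bound is the fitted 5th percentile, mean − 1.6449·sd. A
moment fit (sample mean/sd) is available, and is used automatically when
the histogram fit is degenerate (few genes in one bin). Zero-variance
profiles are excluded with a reason.

## Problem sizes and numerical choices

Test and demonstration runs use 500–2,000 genes at library size 2×10⁵ —
the pipeline's own demo scale; all thresholds are identical to the
full-scale defaults. The end-to-end recovery harness scores only
strong-effect planted genes (every non-zero component of the planted
triple ≥ 2 log2 units, expected baseline count ≥ 200), since
borderline-powered genes are legitimately missed at n = 2 per group.
IRLS runs at most 60 damped iterations (steps clipped to ±5 in natural
log) with means clipped to e^±50; dispersions are clipped to
[1e-8, 10]. The growth grid-search oracle in the tests profiles `max`
analytically (the model is linear in it) over a (0.01 °C × 0.1) grid.
Known limitations: no exact replication of DESeq2 internals; no Voronoi
rendering; classes 12/14 unplantable by design; concordance histograms
with few genes fall back to moments.
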