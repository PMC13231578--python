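# Methods

`pd1rev` re-implements, as a tested and reusable pipeline, the computational
analysis of soluble-PD1 (sPD1) reverse signalling in fibroblast-like
synoviocytes (FLS): a five-condition stimulation design (control, TNF,
TNF+sPD1, and TNF+sPD1 on PD-L1- or PD-L2-knockout cells) measured by bulk
RNA-seq in two disease groups (rheumatoid arthritis, RA, and non-inflammatory
controls, NI), with qPCR validation and public-cohort utilities. Everything
runs on synthetic data with recorded ground truth, so each stage can be
checked by parameter recovery.

## Generative model (simdata)

Counts for gene *g* in sample *s* are negative binomial,

    K_gs ~ NB(mu_gs, phi_g),      Var = mu + phi mu^2
    mu_gs = L_s * 2^(b_g + d_{g,donor(s)} + c_{g,s}) / C,

with baseline log2 abundance `b_g ~ N(4, 1.5)`, per-gene dispersion `phi_g`
lognormal around a median of 0.05 (typical bulk RNA-seq scale), additive
donor effects `d ~ N(0, 0.3)` on the log2 scale (individual variability is
deliberately larger than most treatment effects), library sizes `L_s`
lognormal around 30 million reads (scaled down to 0.3–1 million in tests and
in the acceptance script so that 200–2000-gene studies keep realistic
per-gene depth), and `C = sum_g 2^{b_g}` a fixed normalisation. Normalising
by a *fixed* constant rather than per-sample keeps every planted log2
fold-change exactly recoverable; the compositional distortion this ignores
is small when differential expression is sign-balanced, which the generator
enforces by alternating effect signs.

Condition effects: TNF adds a planted log2FC to every TNF-containing
condition; sPD1 adds a second log2FC to the TNF+sPD1 and knockout
conditions. Each sPD1-responsive gene carries a ligand dependency label
(PD-L1, PD-L2 or both). A knockout removes the matching ligand's share of
the sPD1 effect: all of it for a matched single-ligand gene, half for a
"both" gene (an additive 50/50 split — the simplest testable choice; the
underlying biology provides no quantitative model), none otherwise. TNF
effects are either fixed-magnitude with alternating signs (default) or
drawn `N(0, scale)` (`tnf_lfc_dist="normal"`), which emulates the pervasive
heterogeneous response of a genuine stimulus and matters for bootstrap
stability (below).

qPCR tables put Ct on the exact doubling scale, `Ct = anchor − (signal −
mean baseline) + N(0, noise_sd)`, with technical duplicates; at zero noise
the comparative-Ct method returns planted effects exactly. Single-cell
matrices draw per-cell depths (lognormal, mean 6000 UMI) and multinomial
counts over a profile with a fixed 5% mitochondrial share ("MT-" prefix);
planted low-quality cells fail QC by collapsed depth (150 UMI) or an
inflated (60%) mitochondrial share, half each.

What the generator does *not* emulate: compositional library effects beyond
the fixed-constant normalisation, batch effects, gene–gene correlation,
doublets, zero-inflation beyond NB sampling, or amplification-efficiency
variation in qPCR. Passing recovery tests therefore demonstrate correctness
of the analysis chain under its own model assumptions, not robustness to
every artefact of real data.

## Normalization (normcore)

Genes are filtered at the CPM value of `min_count` (default 10) reads in the
smallest library, kept if reached in at least `min_samples` (default 3, the
size of one condition-by-group cell) samples. TMM factors use the standard
conventions: reference sample with the 75th-percentile count fraction
closest to the mean, two-sided rank trimming of 0.30 on M and 0.05 on A,
inverse delta-method variance weights, factors rescaled to geometric mean 1.
log2-CPM uses a prior count of 0.5 with `2*prior` in the denominator.
Precision weights follow the voom recipe: per-gene OLS residual sqrt
standard deviations are lowess-smoothed (span 0.5) against average log
count, the trend is evaluated at each observation's fitted log count, and
the weight is the predicted standard deviation to the power −4, clamped to
[1e-6, 1e6] (constant extrapolation beyond the trend range).

## Donor-blocked differential expression (dex)

Per group, the design codes control as baseline with one indicator per
condition (a joint two-group fit adds per-group control means and
interaction indicators). Donor is handled as a random effect through a
single consensus intra-donor correlation: per gene, OLS residuals give
unbiased moment estimates of the donor and noise variance components — the
within-block residual cross-products and the residual sum of squares have
expectations linear in the two components with coefficients from the
projection matrices (`M B M` and `M`), so a 2×2 solve removes the
attenuation the residual projection would otherwise cause. The default
pooling averages the components across genes and forms a single ratio; this
is unbiased both under the null and at planted correlations, whereas
pooling per-gene ratios (the `atanh-trim` option, 15% two-sided trim on the
atanh scale) is measurably biased downward because the per-gene numerator
and denominator are coupled. That bias was large enough to spoil type-I
calibration, which is why the component pooling is the default.

Gene-wise estimation is generalized least squares under the
block-exchangeable covariance `D_g C D_g`, `C = (1−rho) I + rho *
same-donor`, `D_g = diag(1/sqrt(w_g))` with voom weights, implemented by a
shared Cholesky whitening and batched linear algebra (with rho = 0 and unit
weights this is exactly OLS, asserted to 1e-10). Residual variances are
shrunk by empirical Bayes: the scaled inverse-chi-square prior `(d0, s0^2)`
is fitted by method of moments on log variances via digamma/trigamma
inversion (Newton), d0 capped at 1e6 to encode infinity, with a degenerate
branch (zero spread shrinks completely to the common value). Moderated t
uses `d_g + d0` degrees of freedom, two-sided p by survival-function
doubling, Benjamini–Hochberg adjustment (statsmodels), DEGs at adjusted
p ≤ 0.05. RA and NI are analysed separately in the primary mode; contrasts
are TNF vs control, TNF+sPD1 vs control, TNF+sPD1 vs TNF (sign convention:
TNF+sPD1 minus TNF), and each knockout vs TNF.

Measured calibration under the full chain (null simulations, 2000 genes,
3 donors × 5 conditions): raw p ≤ 0.05 rate 0.049, BH-adjusted calls ≈ 0,
planted log2FC = 1 recovered with |bias| < 0.02, planted consensus
correlation 0.5 recovered within ±0.05.

## Bootstrap stability (diagnostics)

Within a group, donors are resampled with replacement; every sample of a
drawn donor is carried along, duplicated donors are relabelled as distinct
pseudo-donors (so all-identical resamples stay estimable; a flag can
exclude them), the whole filter-through-contrast chain is rerun on the
resample restricted to the originally kept genes, and the replicate log2FCs
are compared to the originals by Spearman correlation over shared genes
(average ranks on ties). Categories: median > 0.9 stable, < 0.8 unstable,
otherwise intermediate; boundary values fall to intermediate. Default 1000
replicates; the acceptance checks use 200.

An analytic property worth knowing when reading these numbers: because
replicates reuse the original samples, the replicate-vs-original
correlation has an intrinsic overlap floor even for pure noise. With three
donors, a resample {A,A,B} (18 of the 27 ordered draws) gives correlation
`3/sqrt(15) ≈ 0.775` for null genes, {A,A,A} gives `1/sqrt(3) ≈ 0.577` and
{A,B,C} gives 1 — verified by simulation. The *median* under pure noise is
therefore ≈ 0.775, not 0: a median below 0.8 already means the ranking
carries essentially no reproducible signal, and medians above 0.9 require a
pervasive heterogeneous response across most genes, not a few strong
effects. Residual PCA (per-gene removal of donor means, within-donor
residuals summing to zero by projection) and a plain PCA overview
(sklearn, full SVD, variance ratios summing to 1) complete the module.

## sPD1 statistics (pd1sig)

Δlog2FC per gene is (TNF+sPD1 vs control) − (TNF vs control); genes at
Δ ≤ −0.5 are dampened, Δ ≥ +0.5 amplified (boundaries included). By
contrast algebra Δ equals the directly estimated TNF+sPD1 vs TNF
coefficient in the saturated one-group design (asserted to 1e-8).

The responsive-gene caller applies two criteria on unadjusted p-values:
(1) |log2FC| ≥ 0.585 (a 50% change) and p ≤ 0.05 in TNF+sPD1 vs TNF;
(2) |log2FC| < 0.585 and p ≥ 0.5 in a knockout vs TNF. A gene is responsive
if (1) holds and (2) holds for at least one ligand ("and/or" reading;
`require_both` switches to the conjunction). Attribution is the ligand
whose knockout abolishes the response, "both" iff both qualify; direction
follows the criterion-1 sign. Boundary handling is exactly as printed
(≥ 0.585 passes criterion 1, < 0.585 passes criterion 2). Note the rule is
*not* monotone in the fold-change threshold — lowering it loosens
criterion 1 but tightens criterion 2 — and criterion 2's `p ≥ 0.5` demand
on a truly null knockout contrast is passed only about half the time by a
calibrated test. That, plus the structural inability to call
"both"-dependent genes under the additive knockout split (either single
knockout leaves half the effect, 0.75 > 0.585 log2 units), caps measured
sensitivity near 0.34 and precision near 0.7 at the reference conditions
(|log2FC| = 1.5, phi = 0.05, 200 of 2000 genes, 3 donors), while ligand
attribution among correctly called genes is ≈ 0.95. The caller is a filter
designed for specificity of *which ligand*, not a powerful detector.

Average z-score summaries standardise each gene across all included samples
(sample sd, n−1), drop zero-variance genes with a warning, and average
within condition.

## qPCR validation (qpcrval)

Technical duplicates are averaged on the Ct scale (arithmetic mean);
ΔCt = mean Ct(target) − mean Ct(reference, HPRT1-like, required to be free
of condition effects); ΔΔCt is taken against the TNF-alone baseline
(condition means; per-donor gating available); relative expression
2^(−ΔΔCt); amplification efficiency fixed at 2. Genes with mean Ct ≥ 30 in
the TNF gate condition are excluded (boundary exclusionary); the default
gates on the mean across gate-condition samples, `per_donor=True` excludes
a gene if any donor reaches the threshold. Cross-platform agreement is the
Spearman correlation of qPCR and RNA-seq log2FCs over shared gene ×
condition pairs.

## Cohort utilities (cohort)

Cell QC: fewer than 1000 detected genes or mitochondrial fraction strictly
above 25% removes the cell (exactly 25% is retained); genes under 10 total
UMI are dropped after cell filtering. Percent-expressing is the share of
non-zero cells per group. Pseudobulk sums cells per sample and applies the
log2-CPM transform (factors 1, prior 0.5); two-group comparisons use
Mann–Whitney (exact below 8 per group, tie-corrected normal approximation
otherwise). Gene-set scores follow the GSVA recipe: per-gene
Gaussian-kernel CDF across samples (bandwidth = sd/4), per-sample ranking
of the transformed values, a weighted random walk with the symmetric rank
statistic |p/2 − rank| to the power tau = 1 inside the set and a uniform
penalty outside, and the signed-difference score (largest positive plus
largest negative deviation). Scores are invariant to rank-preserving affine
maps per gene. Spearman correlations carry Fisher-z 95% CIs and strength
bands on |rho| at 0.2/0.4/0.6/0.8.

## Thresholds collected in RunConfig

| parameter | default | role |
|---|---|---|
| fc_threshold | 0.585 | responsive criterion fold-change cutoff (50% change) |
| p1 / p2 | 0.05 / 0.5 | responsive criteria, unadjusted p |
| delta_threshold | −0.5 | Δlog2FC dampening cut |
| deg_fdr | 0.05 | BH-adjusted DEG call |
| ct_gate | 30 | qPCR reliability gate (Ct ≥ excluded) |
| qc_min_genes / qc_max_mito | 1000 / 0.25 | single-cell QC |
| min_count / min_samples | 10 / 3 | CPM filter |

## Numerical choices and degenerate inputs

Weights clamped to [1e-6, 1e6]; d0 to 1e6; consensus rho to (−0.99, 0.99);
rank-deficient designs rejected naming aliased columns; zero contrast
vectors rejected; all-zero libraries rejected naming the sample; zero-
variance genes dropped from z-summaries and given a tiny kernel bandwidth
in GSVA; a bootstrap resample leaving a contrast condition unrepresented is
redrawn and counted. Every generator and the bootstrap are deterministic
given their seed; the end-to-end pipeline is a pure function of its config.

## Problem sizes used by tests and the acceptance script

Null calibration uses 150–200 runs of 2000 genes; recovery scenarios 2000
genes with 200 planted responders; dampening 100 two-group simulations of
600 genes; bootstrap 200 replicates on 800 genes; cohort checks 1000 cells
× 2000 genes. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances while a full run of the suite stays
desk-scale.

## Known limitations

No gene-level REML random effects (one shared consensus correlation); no
surrogate-variable or batch modelling; no efficiency-corrected qPCR
quantification; no doublet handling (none simulated); GSVA parameters
follow package conventions and are not calibrated against any external
implementation; synthetic effect sizes are free parameters, not estimates
from any cohort.
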