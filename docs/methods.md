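# Methods

This note documents the statistical models implemented in `allelics`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions that affect results near boundaries.

## Case-control association and conditional analysis

The association model is prospective logistic regression with an additive
allele-dosage coding: logit P(case) = α + β·g + γᵀx, where g ∈ {0, 1, 2}
counts the alternate allele. Each variant is tested with the 1-df
**efficient score test** evaluated at the covariate-only null fit. Writing
p̂ for the null fitted probabilities and W = diag(p̂(1 − p̂)),

U = gᵀ(y − p̂),  V = gᵀWg − gᵀWX (XᵀWX)⁻¹ XᵀWg,  U²/V → χ²₁.

The score test needs only one null fit per scan, is valid under
retrospective (case-control) sampling for the odds-ratio parameter, and is
the standard choice for dense imputed scans. Effect estimates (log OR and
SE) come from the full alternative fit and are reported alongside; when
that fit separates or fails to converge the estimate is flagged unreliable
while the score p-value is still returned, since the score statistic needs
no alternative fit. `fit_beta=False` skips the alternative fits entirely,
which is what large simulation studies use.

Conditional analysis is **individual-level**: the conditioning variants'
dosages are appended to the covariate matrix and every other variant is
re-tested. This is exactly equivalent to a per-variant score test with the
conditioning genotype as a covariate (and the test suite asserts the
equality is exact). Summary-statistic conditioning (GCTA-style
approximation from marginal effects and an LD reference) is deliberately
not implemented — with individual-level data available it is strictly
inferior.

Numerical conventions:

* Null fits use IRLS (statsmodels GLM, binomial family), 100 iterations,
  deviance tolerance 1e-8; non-convergence raises rather than returning a
  silently wrong null.
* Intercept-only nulls use the closed-form MLE p̂ = ȳ.
* Missing genotypes are dropped pairwise per test; no dosage imputation.
* Monomorphic variants and single-class phenotypes raise typed errors.
* p-values are reported unadjusted (no multiple-testing correction), on
  the natural scale, clipped into (0, 1].

QC follows the usual imputed-scan rule: drop variants with minor-allele
frequency below 0.01 or imputation INFO below 0.5. Both thresholds are
**inclusive** (a variant exactly at MAF 0.01 or INFO 0.5 is kept), because
the exclusion rule is phrased as strictly-below; absent INFO (directly
genotyped data) passes.

## Linkage disequilibrium

For two loci with alternate-allele frequencies p_A, p_B and haplotype
frequency p_AB: D = p_AB − p_A p_B, r² = D²/(p_A q_A p_B q_B), and
D′ = |D|/D_max with D_max = min(p_A q_B, q_A p_B) for D > 0 and
min(p_A p_B, q_A q_B) for D < 0 (D′ ≡ 0 at D = 0). r² ≤ D′ always holds
and is asserted property-wise.

With phase known, haplotypes are counted directly. From unphased genotypes
the two-locus haplotype frequencies are estimated by EM starting at
linkage equilibrium; only the double heterozygote carries phase ambiguity,
resolved by expected cis/trans counts each iteration; convergence is
|Δ log-likelihood| < 1e-10 or 1000 iterations. A practical accuracy note:
the phase information lost in double heterozygotes is irreducible, so on
the same 500-individual sample the EM estimate differs from the
phase-known estimate by a median |Δr²| ≈ 0.005 at moderate LD (r² ≈ 0.5).
Only in strong LD (r² ≈ 0.95), where essentially every double heterozygote
is cis, do the two agree to ~1e-3 or better. Tests assert the agreement in
that strong-LD regime and tolerate the irreducible gap elsewhere.

`correlated_set` returns all variants with EM r² strictly above the
threshold (default 0.6) to an index variant, sorted by position, excluding
the index itself.

## Synthetic genotype and phenotype generation

Haplotype pools are **tree-factorised** joint distributions: each LD
target (i, j, r²) becomes an edge storing the child allele's probability
conditional on the parent allele, with the edge solved in closed form from
D = r·√(p_A q_A p_B q_B). Pairwise r² is therefore exact at the population
level (and along paths it is the product of edge correlations, a property
of binary tree-Markov models); all sampling error lives at the sample
level. Infeasible targets — |D| exceeding D_max for the two allele
frequencies — raise an error naming the pair. The LD-target graph must be
a forest; cyclic constraint systems generally have no closed-form (or any)
exact solution and are rejected. This covers the two architectures that
matter here: a star (an index SNP with proxies) and a chain (a tight LD
block with decaying correlation).

Diploid individuals are two independent haplotype draws (Hardy–Weinberg,
no inbreeding); case-control status follows the logistic model above.
Retrospective (GWAS-style) sampling simulates a cohort of
`cohort_multiplier` × (n_cases + n_controls) individuals (default 20×) and
subsamples the requested numbers by status, raising if the cohort cannot
supply them. This reproduces case oversampling without
conditional-likelihood machinery; by standard logistic-regression theory
only the intercept is biased by the design, not the odds ratios.

The **masking preset** plants two causal variants in positive LD
(r² = 0.30 at MAFs 0.19/0.35) with opposite-direction effects (OR 0.8 and
1.4). The marginal slope at the masked variant A is approximately
β_A + β_B·D/(p_A q_A), tuned to nearly cancel, so A looks null in
single-SNP analysis and lights up after conditioning on B. With r² = 0 no
masking is possible; the generator records a warning in the output
metadata rather than failing.

Simulation scales used by the acceptance checks mirror the study designs
they emulate: a 9-SNP chain block (adjacent r² = 0.98, so the furthest
proxy retains r² ≈ 0.85 to the causal variant — all above 0.6, as in a
tight LD block of near-perfect proxies), OR 1.3 at MAF 0.19, 4000 cases +
4000 controls, 100 replicates; and 5000 null replicates of n = 1000 for
calibration.

What the generator does **not** emulate: recombination-map-aware or
coalescent haplotype structure, imputation dosage uncertainty, population
stratification, genotyping error. Passing tests demonstrate the
statistical machinery is correct under the stated model, not robustness to
those real-data complications.

## Label-swap pulldown simulation and binder calling

Each protein carries a latent log₂ intensity (normal, sd 1.5 around the
background scale) and a true allele-oriented binding preference δ: 0 for
background, +effect for planted C-binders, −effect for G-binders. Each
run observes per-channel log₂ intensities μ ± δ/2 plus independent
N(0, sd) channel noise; the forward run carries the C bait in the heavy
isotope channel and the reverse run swaps the labels. Intensities are
log-normal and never exactly zero (zeros in real tables are a reader
concern, handled by floor-imputation at call time).

The caller computes allele-oriented log₂(C/G) per run (floor for
single-channel zeros = half the smallest positive intensity in the run;
both-zero proteins dropped with a logged reason), **median-centres** each
run (the plots in this kind of analysis are centred clouds; the centring
is shift-invariant and makes fences comparable across runs), then flags
Tukey outliers: quartiles by linear interpolation of order statistics
(position (n−1)p + 1, numpy's default), fences at Q1 − k·IQR and
Q3 + k·IQR with k = 1.5, **strict** exceedance (a value exactly on a
fence, or any value when IQR = 0, is not an outlier). Classification
requires concordance: upper in both runs → C-preferential, lower in both →
G-preferential, anything else → non-differential. Under independent run
noise, concordance squares the single-run false-positive rate, which is
why the planted-null simulations show essentially zero concordant calls.
Proteins present in only one run are reported non-differential with a
"single-run" note. No distributional moderation (limma-style shrinkage) is
applied; the IQR rule is the method being reproduced.

## qPCR arithmetic

All quantities assume perfectly efficient amplification — one threshold
cycle per doubling of template — which is the operating assumption of
TaqMan-style relative quantification; standard-curve efficiency
corrections are out of scope and would enter as a base change in the
exponents.

* **ΔΔCt**: replicate Cts are averaged within each (sample, target,
  condition) group *before* differencing (rather than per-replicate ΔCt
  then averaging — with perfect efficiency the two orders give the same
  point estimate when replicates are balanced, and group-mean-first is the
  convention implemented and tested). ΔCt = mean Ct(target) − mean
  Ct(reference); ΔΔCt subtracts the calibrator condition's ΔCt;
  fold = 2^−ΔΔCt. SEMs propagate by the delta method:
  SE(fold) = ln 2 · fold · SE(ΔΔCt). The calibrator's own fold is exactly
  1, and any Ct offset shared by a sample's wells cancels.
* **Allelic discrimination**: ratio C/G = 2^−(Ct_C − Ct_G) on cDNA. The
  reference-gene terms cancel within a sample but reference wells are
  still required when supplied, and per-allele reference-normalised levels
  are reported for cross-sample comparison. The same assay run on genomic
  DNA measures the copy-number ratio; dividing the expression ratio by the
  genomic ratio isolates the per-copy allelic expression difference.
* **Knockdown**: per experiment and allele, knockdown% = 100·(1 −
  treated/scrambled); alleles are compared with a two-sided t-test, paired
  across experiments by default (the replicate structure pairs them;
  an unpaired Welch mode is exposed for designs that do not).
* **Fisher specificity test**: two-sided Fisher's exact test (scipy),
  two-sidedness defined as the sum of margin-consistent tables with
  probability ≤ the observed table's. The three control genes are pooled
  (3/8 hits versus 0/24), which reproduces the published p = 0.011
  (exactly 0.0113); per-gene 0/8 contrasts cannot. The implementation is
  cross-checked against exhaustive integer enumeration for every table
  with total ≤ 40.
* **ChIP**: percent input = 100·2^−(Ct_antibody − Ct_input_adj), with
  Ct_input_adj = mean input Ct − log₂(dilution factor); the dilution
  factor is a config parameter defaulting to 1 (no adjustment) since input
  dilutions vary by protocol. Enrichment is the IP/control percent-input
  ratio; allelic ChIP contrasts use mean(C)/mean(G) with a paired
  two-sided t-test on per-replicate signals.
* **Reporter assays**: per-well activity = (firefly/renilla) scaled by the
  empty-vector mean; C-versus-G contrasts per insert orientation use
  Welch's t-test on replicate activities.
* Degenerate t-test inputs are resolved exactly rather than returning
  NaN: zero-variance differences give p = 1 when the mean difference is
  also zero and p → 0 otherwise.

**Telomere length**: T/S = 2^−(Ct_T − Ct_S) against a single-copy gene in
the same genomic DNA, relative length = T/S ÷ T/S(calibrator condition).
This is the monochrome relative form; absolute calibration against a
standard curve of known telomere lengths is not implemented.

The qPCR simulator draws Ct = offset − log₂(latent amount) + N(0, sd) per
replicate well, splitting allelic templates by expression × copy number on
cDNA and by copy number alone on genomic DNA. It does not model plate
position effects, efficiency differences between assays, or Ct censoring
at high cycle numbers; recovery tests (planted ratios recovered within 10%
at sd 0.1 with triplicates) quantify behaviour under well-behaved noise
only.

## Seeds and determinism

Every stochastic component takes an explicit seed and uses an isolated
`numpy` generator; no analysis code touches global random state. The
pipeline derives all stage seeds from the single config seed, so reruns
are bit-identical.

## Known limitations

* LD-target graphs are restricted to forests; arbitrary pairwise r²
  systems are not representable exactly.
* The EM/phased LD agreement degrades at moderate LD (see above).
* Amplification efficiency is fixed at 2; no standard curves.
* No population-structure correction beyond user-supplied covariates; no
  meta-analysis across studies.
* The chi-square reference for the score test is asymptotic; at n ≈ 200
  its p can differ from the exact permutation p by up to ~0.02 for
  datasets whose observed score sits near a lattice atom.
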