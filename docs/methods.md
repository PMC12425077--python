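# Methods

This note documents the models, numerical choices and simulation scales
behind `edgescan`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Disease and exposure model

Disease status is generated (and analysed) under the logistic model

    logit P(D = 1 | G, E, C) = β₀ + β_G·G + β_E·E + β_GxE·G·E + β_C·C,

with G the alternate-allele dosage at the single causal ("index") variant,
E either the active/inactive indicator (MET-h/wk ≥ 8.75) or the quartile
code 1–4 treated as continuous, and C the adjustment covariates (age, sex,
total energy, three ancestry PCs, and study indicators in pooled fits).
A generative variant allows genotype-specific exposure coefficients
(one log-OR per copy-number stratum), used for stratified-OR recovery
experiments where the three stratified ORs are not log-linear in G.

Exposure is log-normal: log MET = μ + γ_G·G + σZ with σ = 1 fixed; μ is
found by Brent root-finding so the marginal P(MET ≥ 8.75), integrating the
per-allele shift γ_G over Hardy-Weinberg genotype frequencies, equals the
configured active fraction (default 0.76). γ_G is the G–E-dependence knob
that feeds the joint test and the screening statistic; with γ_G = 0 the
calibration reduces to μ = log 8.75 + σ·Φ⁻¹(active fraction).

Genotypes: each SNP's two latent "haplotype" Gaussians are thresholded at
Φ⁻¹(1 − alt frequency), which makes every marginal genotype exactly HWE
regardless of the latent AR(1) correlation (ld_rho within blocks of
block_size SNPs) that induces LD. Imputed SNPs get additive Gaussian noise
with variance 2p(1−p)(1−r²)/r², clipped to [0, 2], so the squared
correlation with the underlying hard call is approximately the configured
imputation R². Covariates are drawn from simple documented distributions
(age ~ N(63, 8²) truncated to [40, 90], sex Bernoulli(1/2), energy
~ N(1900, 700²) truncated positive, PCs standard normal) — they match the
scale of a typical consortium table, not its structure.

Case-control sampling draws a source population 20× the requested totals
(configurable), assigns subjects to studies round-robin, and keeps exact
case/control quotas per study. Because only the index SNP enters the
exposure and disease models, `simulate_study` generates the source
population with that single column and defers the null SNP columns until
after sampling; the result is distributed identically to the literal
three-stage path (also provided and tested) at a fraction of the cost.
All randomness flows from one seed expanded into fixed, named substreams,
so adding a stage never perturbs another stage's draws.

## Quality control

Hardy-Weinberg equilibrium uses the Levene-Haldane exact conditional
distribution of heterozygote counts given allele counts, summing the
probabilities of configurations no more likely than the observed one
(two-sided), in log-space via `gammaln` with a 1 + 1e−12 relative slack for
ties. HWE applies only to directly genotyped SNPs (it is a genotyping-stage
filter; dosages are post-imputation); monomorphic SNPs return p = 1.
Boundary semantics are deliberate: pooled MAF ≤ 0.01 fails, imputation
R² ≥ 0.8 passes. Call-rate and duplicate-concordance filters are accepted
as no-op parameters with a warning — synthetic dosage data are complete.

## Per-SNP tests

Logistic models are fitted by IRLS with step-halving; convergence when the
maximum absolute score falls below 1e−8 or the relative log-likelihood
change below 1e−10, cap 50 iterations; coefficients exceeding 30 in
magnitude are treated as separation and flagged non-converged. Continuous
covariates are centred and scaled internally for conditioning (this leaves
the G, E and G×E inference unchanged). Per-SNP fits warm-start from the
covariate-only fit, which keeps the genome scan at two or three IRLS
iterations per model. Wald tests are the default throughout; the test suite
checks 1-d.f. Wald and likelihood-ratio statistics agree within 5% at the
sample sizes used. SNPs with minor-dosage count below 2 or zero variance
are flagged and excluded from testing rather than fitted.

The γ_G statistic is the Wald chi-square of the exposure coefficient in the
ordinary-least-squares regression of dosage on exposure plus covariates in
the combined case-control sample, vectorised across all SNPs in one solve.
The joint 3-d.f. statistic is the 2-d.f. Wald on (β_G, β_GxE) from the
interaction model plus the γ_G chi-square, combined as independent
chi-squares; the step-1 screening statistic is the marginal D–G chi-square
(from a reduced model without exposure terms) plus the γ_G chi-square
(2 d.f.). Treating the components as independent is standard for these
constructions and is verified empirically: under the global null the
correlation between step-1 and step-2 p-values across SNPs is ~0, and all
three p-values are marginally uniform.

## Two-step weighted testing

Bins are defined by step-1 p-value thresholds in expectation: bin j covers
(B(2^(j−1)−1)/m, B(2^j−1)/m] with B = 5 and m the assumed number of
independent tests (10⁶ by default; for simulations it is set to the number
of simulated independent SNPs, since the binning is defined relative to the
assumed test count). The number of bins is the smallest J with
B(2^J−1) ≥ m; the residual geometric budget α·2⁻ᴶ is left unallocated
(conservative) rather than folded into the last bin. Per-bin thresholds are
α·2⁻ʲ/m_eff_j, with m_eff the smallest eigenvalue count reaching 99.5% of
the variance of the bin's SNP correlation matrix (the simpleM convention;
the cutoff is configurable). m_eff is computed on the combined case-control
sample (exposed as a parameter — computing it on controls only is a
defensible alternative). SNPs with missing step-1 or step-2 p-values are
routed to the final bin and never rejected. The reported two-step p-value
p* = p₂·m_eff_j·2ʲ/m satisfies p* ≤ α/m ⟺ rejection exactly, by
construction. Boundary ties in step-1 p at a bin edge stay in the lower
(more lenient) bin by interval membership; decision tables are ordered by
(step-1 p, chromosome, position) for deterministic output.

## Meta-analysis and follow-up

τ² is DerSimonian-Laird (the conventional pairing with Hartung-Knapp, which
specifies the variance and CI, not τ²). The Hartung-Knapp variance is
Σwᵢ(θᵢ − θ̂)²/((k−1)Σwᵢ) with wᵢ = 1/(SEᵢ² + τ²), CIs via t with k−1 d.f.;
Q and I² use fixed-effect weights. A single study is refused rather than
"pooled". Funnel diagnostics are emitted as the per-study (logOR, SE)
table; outlier exclusion is left to the analyst.

λ is median(χ²)/0.4549 (the χ²₁ median); λ₁₀₀₀ rescales by
(1/n_ca + 1/n_co)/(2/1000). Q-Q tables use expected p = rank/(m+1).

Stratified follow-up rounds dosages to the nearest genotype for model fits
but displays expected case/control counts from dosage-implied genotype
probabilities (P(het) = d, P(ref-hom) = 1 − d for d ≤ 1; P(alt-hom) = d − 1,
P(het) = 2 − d otherwise — exact for hard calls). Adjusted ORs come from
within-stratum logistic fits; crude cross-product ORs with Woolf CIs (and
Haldane-Anscombe 0.5 correction on zero cells, flagged) are emitted
alongside as an arithmetic cross-check.

## Simulation scales and what they show

The validation experiments (`edgescan.experiments`, driven by
`scripts/acceptance.py`) use desk scales chosen so the full suite runs on
one CPU in minutes while keeping Monte Carlo error small relative to the
quantities tested: 200 null scans of 1,000 SNPs × 2,000 subjects for
family-wise error (binomial SE ≈ 1.5% at a 5% rate); 27 studies of
600/900 for meta-analytic recovery of OR 0.85; one 39,000-subject cohort
for stratified-OR recovery at generating ORs 0.80/0.92/1.30 and allele
frequency 0.20.

Passing these experiments shows the machinery is calibrated and unbiased
under its own generative assumptions. It does not establish behaviour under
features the generator deliberately omits: realistic human LD maps and
allele-frequency spectra, ancestry admixture and fine population structure,
exposure measurement error and between-study heterogeneity of exposure
definitions, case-control matching, or missing genotype data. The
effective-test correction in particular is exercised only under block-
exchangeable LD; heavily structured real LD will change m_eff, though not
the error-control argument, which holds for any m_eff ≤ n_j.

## Known limitations

* The quartile exposure enters scan models as continuous 1–4 (1-d.f.
  interaction); categorical Q1-reference coding is available in the
  follow-up tables. Both codings are defensible genome-wide; continuous is
  the default.
* Wald inference throughout; penalised (Firth-type) fits for separated
  strata are not implemented — such fits are flagged non-converged instead.
* Sample-level QC (relatedness, sex checks, call rates) is out of scope;
  the QC module covers SNP-level filters only.
* Rare-variant aggregate tests and alternative screening statistics
  (cocktail/hybrid methods) are out of scope.
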