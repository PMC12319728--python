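# Methods

## 1. Statistical model

Let a gene contain J SNPs with disease-GWAS z-scores `z` (length J,
sample size n) and LD correlation matrix `R` (J × J). Each MRI
modality q contributes K IDPs; Stage 1 estimates a J × K weight matrix
`W(q)` whose column k imputes IDP k from genotypes.

The modality-level null hypothesis is that the tested modality's K₁
imputed IDPs have no effect on the trait once the other modalities'
imputed IDPs and a residual direct genetic effect are held fixed. With
`A1 = W(tested)` and `A2 = [W(other modalities) | 1]` (the column of
ones is the burden term absorbing direct SNP → trait effects), the
score vector and its plug-in null covariance are

```
S      = A1'z − A1'R A2 (A2'R A2)^{-1} A2'z
Cov(S) = A1'R A1 − A1'R A2 (A2'R A2)^{-1} A2'R A1
```

and the statistic is `T = S'S`. Under the null, `T ~ Σ λ_k χ²₁` with
`λ` the eigenvalues of `Cov(S)`. The test is scale-invariant: scaling
`z` or `A1` rescales `T` and `λ` together and leaves p unchanged, so
any common normalization convention of the summaries cancels (verified
to 1e-10 relative in the suite).

For K₁ = 1 the statistic reduces to the squared Gaussian score
`(a'z)² / a'Ra` and the p-value equals the two-sided normal p-value
(asserted in the suite).

### Comparator methods (used in the validation study)

1. **proposed** — the adjusted modality test above.
2. **idp_specific_adjusted** — each tested IDP separately with the
   same adjustment; combined by Bonferroni (min-p × K, capped at 1).
3. **proposed_unadjusted** — modality test with empty `A2`.
4. **uv_iwas** — per-IDP tests with empty `A2`, Bonferroni-combined.

## 2. Stage 1: weights from summary statistics

- **z → marginal coefficient**: `b = z / sqrt(n − 2 + z²)`, the exact
  sample correlation implied by a simple-regression Wald z. Bounded in
  (−1, 1) and sign-preserving (property-tested).
- **Joint weights**: `w = solve(R + ridge·I, b)`. Ridge defaults to
  `0.001 × mean(diag R)` and is applied only when `cond(R) > 1e8`;
  with a singular `R` and no ridge the solver raises a conditioning
  error instructing the caller, rather than returning garbage.
- **Clumping** (per IDP, before weighting): greedy — repeatedly keep
  the smallest-p SNP and drop SNPs within 1 Mb whose r² with it
  exceeds 0.5; output preserves genomic order. Per-IDP kept sets are
  merged (union, position-ordered) into one SNP set per gene so all
  weight matrices share one SNP list; absent SNPs get weight 0.
- **Screening**: gene–IDP association F-test from summaries,
  `R² = b' R^{-1} b` (clipped to [0, 1)), `F = (R²/J)/((1−R²)/(n−J−1))`,
  keep when p < 5e-5. Screened-out IDPs contribute no column; a
  modality with zero surviving columns yields a no-test row, not an
  error.

Clumping and screening are on by default in the file-based pipeline
and off in the simulation experiments, whose generative model gives
every SNP a nonzero effect on every IDP.

## 3. Mixture chi-square p-values

`mixture_chisq_pvalue(T, eigenvalues, method, mc_draws, seed)` with
`method ∈ {auto, davies, liu, monte_carlo}`:

- **davies** — numerical inversion of the characteristic function
  (Imhof's integral). The integrand oscillates with period ≈ 4π/T and
  its envelope decays only like `u^-(K/2+1)`, so naive adaptive
  quadrature fails for small K. Implementation: composite 15-point
  Gauss–Legendre on segments no longer than half an oscillation
  period up to the point where every `arctan` has saturated, plus a
  closed-form integration-by-parts asymptotic tail. Verified against
  an independently coded pairwise-convolution oracle (3e-8 absolute)
  and the exact chi-square for equal eigenvalues (2e-7).
- **liu** — moment-matching to a non-central chi-square; cheap,
  accurate to a few per mille in the body, used as the fallback
  whenever inversion returns p outside (0, 1].
- **monte_carlo** — `p = (1 + #{draws ≥ T}) / (1 + mc_draws)` over
  `mc_draws` (default 1e6) mixture samples; never exactly 0; requires
  a seed.
- **auto** policy: all eigenvalues equal → exact scaled chi-square
  (reported as `chisq_exact`); K > 5 → davies; K ≤ 5 with unequal
  eigenvalues → Monte Carlo (inversion is least reliable exactly
  where Monte Carlo is cheapest).

Eigenvalues below `1e-12 × λ₁` are discarded (numerical noise would
otherwise inflate the mixture dimension); all-zero eigenvalues raise a
degenerate-test signal that callers convert to a no-test result.
Collinear adjustment columns are dropped by rank-revealing pivoted QR
on `R^{1/2}A2` before projection, with the dropped labels logged.

## 4. Generative model of the validation study

Per replicate, with Q = 2 modalities:

```
m_k(q) = Σ_j g_j α_jk(q) + u γ_k(q) + δ_k(q)
y      = μ Σ_j g_j + Σ_qk β_k(q) m_k(q) + θ u + ε          (continuous)
logit P(y=1) = intercept + same linear predictor            (binary)
```

`u` is an unobserved standard-normal confounder feeding both IDPs and
trait. Defaults (the study conditions): n = 2000, J = 58, K = 10,
`α ~ N(0, 0.3²)`, `γ ~ N(0, 1)`, `β(2) ~ N(0, 0.05²)`, μ = θ = 1,
sd(δ) = 5, sd(ε) = 4, intercept −2. Scenarios for the tested
modality's `β(1)`: `null` (all zero), `dense` (all K from `N(0, τ²)`),
`sparse` (only the first).

**Genotypes** are correlated binary 0/1 indicators: a latent
multivariate normal is dichotomized at the allele-frequency quantile;
per-lag latent correlations are solved numerically (root-finding on
bivariate-normal orthant probabilities, with a linearized inverse for
targets < 1e-4) so the *binary* correlations hit the decaying target
`ld_rho^|j−j'|`; the per-lag solutions are assembled into a Toeplitz
matrix and eigenvalue-clipped to the PSD cone. Monomorphic columns
(likely at rare allele frequencies) are redrawn. An optional
`two_haplotype_sum` mode sums two independent draws into 0/1/2
dosages.

**Calibration.** The generative equations use mean-centered raw 0/1
genotypes (`genotype_scale="centered"`) with allele frequency 0.005
and `ld_rho = 0.5`. This choice puts the study in the intended
weak-instrument regime — per-SNP effects of μ = 1 on rare indicators
are individually tiny — and was fixed once, before the validation
suite was written, from a one-dimensional scan targeting a binary
prevalence near 18% and average genotype R² below 0.10. The suite and
`scripts/acceptance.py` verify those outcomes (≈18.5%, ≈0.074); no
parameter was moved afterwards. Standardized-genotype and raw
conventions remain selectable but make per-SNP effects of 1 enormous.

**Summary conversion.** Linear traits and IDPs: exact Wald z from the
sample correlation, `z = r sqrt(n−2)/sqrt(1−r²)`. Binary traits:
per-SNP univariate logistic Wald z, fitted by a Newton–Raphson solver
vectorized across SNPs (cross-checked against statsmodels to 1e-6);
separation or non-convergence yields NaN, and those SNPs are dropped
with a log message. LD is the in-sample genotype correlation matrix.

What the generator emulates: LD decay within one gene, rare-variant
burden architecture, confounded IDP–trait structure, horizontal
pleiotropy through a second modality, direct genetic effects, and the
exact summary-statistics interface of a real analysis. What it does
not: realistic genome-wide LD (one gene at a time, AR-style decay
only), allele-frequency spectra, sample overlap or mismatched GWAS
panels, population stratification, or binary-trait ascertainment.

## 5. Experiment drivers and their defaults

- `run_null_experiment`: empirical rejection rate per method at
  `alpha_levels = (0.05, 0.01)` with Monte-Carlo standard errors.
- `run_power_experiment`: power over a τ grid per scenario; τ = 0 is
  run under the null scenario. The packaged grid {0.1, 0.25, 0.5}
  spans the rising part of the power curve at the default sample
  size.

Observed behavior at the defaults (computed by the suite, 500–1000
reps): the adjusted test's Type-I error is ≈5% for both trait types
while the unadjusted variants reject >50% of nulls; dense-scenario
power of the modality test rises 0.27 → 0.98 over the grid and
dominates the Bonferroni comparator; in the sparse scenario the
comparator overtakes the modality test at the largest τ (0.49 vs
0.39) — concentrating all signal in one IDP is the per-IDP test's
best case, and the omnibus test pays for the 9 null dimensions.

## 6. Numerical and interface decisions

- 1-based, fully inclusive genomic windows (default ±1 Mb around the
  gene body); BED input is converted from 0-based half-open.
- Allele harmonization to the disease table: swapped alleles negate
  z; strand-ambiguous (A/T, C/G) and irreconcilable pairs are
  dropped; output follows reference order; idempotent.
- Bonferroni significance is strict (`p < α/m`), reported both
  globally (α / all performed tests) and per modality.
- Panel missingness: SNPs above the missingness threshold (default
  1%) are dropped; remaining gaps are median-imputed per SNP.
- All drops (SNPs, IDPs, adjustment columns) are logged with reasons;
  stochastic outputs record their seed in the metadata file.
- A numerically indefinite `Cov(S)` (beyond −1e-8 relative) signals a
  degenerate test — it arises when `R` itself is effectively singular,
  e.g. duplicated rare SNPs in a small panel — and is reported as
  no-test rather than silently clipped.

## 7. Limitations

- The burden adjustment absorbs a *uniform* direct effect; direct
  effects with heterogeneous signs across SNPs are only partially
  captured.
- Binary traits are handled by linearization of the summary
  statistics; no summary-level logistic-link variant is defined.
- The plug-in covariance ignores estimation error in the Stage-1
  weights and LD matrix; with small reference panels the test can be
  miscalibrated (visible in the toy fixture example).
- No effect-size or modality-level partial-R² estimation; the output
  is a test.
- Power in sparse-signal regimes is lower than per-IDP testing with
  Bonferroni correction (see §5); the modality test is aimed at
  distributed signals.
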