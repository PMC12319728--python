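# modality-iwas

Summary-statistics test of whether a whole brain-imaging **modality**
(structural, diffusion or functional MRI) carries a genetically
regulated pathway from a gene to a disease trait.

## The problem

Imaging-derived phenotypes (IDPs) — regional volumes, tract FA values,
connectivity edges — mediate part of the genetic influence on
neurological disease. Two-stage designs (TWAS/IWAS) test one
intermediate phenotype at a time: SNPs in a gene predict the IDP, and
the genetically imputed IDP is tested against the trait. Testing each
of many IDPs separately costs a heavy multiplicity correction and
ignores that an MRI modality is the scientifically meaningful unit.
Worse, a gene can affect the trait through *other* modalities or
directly (horizontal pleiotropy), which inflates a naive test.

`modality-iwas` implements a modality-level, variance-component score
test on GWAS summary statistics that:

1. aggregates all K IDPs of a modality into one test,
2. adjusts for the genetically imputed IDPs of the *other* modalities
   (pleiotropic pathways), and
3. adjusts for residual direct genetic effects via a burden column
   (the sum of the gene's genotypes).

Only three inputs are needed, all summary-level: per-IDP GWAS z-scores,
disease GWAS z-scores, and an LD matrix (from a reference panel).

## The method in brief

Stage 1 turns each IDP's GWAS z-scores into joint SNP weights:
marginal coefficients `b = z / sqrt(n - 2 + z^2)` are mapped through
the LD matrix, `w = (R + ridge I)^{-1} b`, after per-IDP LD clumping
(radius 1 Mb, r² > 0.5) and a gene–IDP F-screen (p < 5e-5). Stacking
the weight columns gives the tested modality's matrix `A1` and the
adjustment matrix `A2` (other modalities' columns plus the burden
column of ones).

Stage 2 computes the score vector and its null covariance

```
S      = A1'z − A1'R A2 (A2'R A2)^{-1} A2'z
Cov(S) = A1'R A1 − A1'R A2 (A2'R A2)^{-1} A2'R A1
```

with `z` the disease z-scores. Under the null, `T = S'S` follows a
mixture of 1-df chi-squares weighted by the eigenvalues of `Cov(S)`;
the p-value comes from characteristic-function inversion, Monte Carlo,
or a moment-matching approximation (see `docs/methods.md`).

## Worked example

`examples/01_modality_test_from_summaries.py` simulates one gene under
the null (the tested sMRI modality has no causal effect, but the gene
has direct effects and dMRI-mediated effects on the trait), converts
the data to summary statistics and runs the test:

```
gene TOY_GENE, modality sMRI
  SNPs: 58, tested IDPs: 10
  T = 0.5393
  p  = 0.0155  (davies)
  adjusted for: ['mod2_idp1', 'mod2_idp2', 'mod2_idp3'] ... (11 columns)
```

(a single null replicate; at the 5% level one in twenty such p-values
lands below 0.05, as this one does).
`examples/02_type_one_error.py` shows why the adjustment matters —
200 null replicates:

```
 method        method_label trait_type  alpha  rate    mc_se  n_reps
      1            proposed continuous   0.05 0.045 0.014659     200
      3 proposed_unadjusted continuous   0.05 0.650 0.033727     200
      4             uv_iwas continuous   0.05 0.545 0.035212     200
```

The adjusted modality test (method 1) sits at the nominal 5% while the
unadjusted variants reject more than half the time. The other
examples cover the power comparison (`03_power_curve.py`) and the full
file-based pipeline (`04_file_pipeline.py`).

## Command line

```bash
# toy inputs to experiment with
modality-iwas fixtures --out toy --seed 3

# gene x modality analysis from files
modality-iwas test \
  --disease-gwas toy/disease_gwas.tsv --idp-gwas-dir toy/idp_gwas \
  --panel toy/panel.tsv --genes toy/genes.bed \
  --modality-map toy/modality_map.tsv --out run1

# Type-I error / power experiments
modality-iwas simulate --mode null --reps 200 --seed 1 --out sim1
```

`test` writes `<out>.results.tsv` (one row per gene × modality with T,
p, method used, and both global and modality-specific Bonferroni
calls) plus `<out>.meta.json` recording all parameters and the seed.

## Repository layout

- `src/modality_iwas/` — the library
  (`sumstats_io`, `stage1`, `modality_test`, `workflow`, `simulation`,
  `fixtures`, `cli`)
- `tests/` — unit, property and validation tests
- `examples/` — short narrative scripts
- `scripts/acceptance.py` — recompute the validation numbers
- `docs/methods.md` — model, parameters, numerical choices, limitations
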