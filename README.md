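# roblogit

Standard versus robust logistic regression for predicting a binary disease
phenotype (hypertension) from age and SNP genotypes.

Genetic risk models are usually fitted by maximum likelihood (iteratively
reweighted least squares), whose estimates can lean heavily on a handful of
individuals who depart from the bulk of the cohort — an 85-year-old who
never developed hypertension, or a patient affected at 38.  This package
implements, side by side and behind a common interface:

* **standard logistic regression** by IRLS, with deviance tests, Wald
  odds-ratio confidence intervals, and a Pearson χ² covariate screen;
* **robust logistic regression**: the Mallows-type quasi-likelihood
  estimator for binomial regression, solving

  $$\sum_{i=1}^{n}\Big[\nu(y_i;\mu_i)\,w(x_i)\,\mu_i' \Big] - n\,a(\beta) = 0,$$

  where $\nu(y;\mu)=\psi_c(\varepsilon)/V^{1/2}(\mu)$ with Pearson residual
  $\varepsilon=(y-\mu)/V^{1/2}(\mu)$, $V(\mu)=\mu(1-\mu)$, the Huber score
  $\psi_c$ (identity on $[-c,c]$, capped outside; default $c=1.345$),
  leverage weights $w(x_i)=(1-h_{ii})^{1/2}$ from the hat matrix, and the
  Fisher-consistency correction
  $a(\beta)=\tfrac1n\sum_i E[\nu(y_i;\mu_i)]\,w(x_i)\,\mu_i'$.  Nested
  models are compared with the quasi-deviance $\Lambda_{QM}$, variances are
  sandwich-form;
* **influence diagnostics**: exact leave-one-out Cook's distances
  $D_i=\sum_j(\hat y_j-\hat y_j^{(i)})^2/(q\,\mathrm{MSE})$, outlier
  flagging, and exclusion-impact tables for the age odds ratio;
* **variant scans** ranking each SNP (additive dosage 0/1/2) by minimal
  deviance / minimal quasi-deviance on top of the age baseline, with QQ
  coordinates and pairwise genotypic r²;
* **cross-validated clinical metrics**: leave-one-out probabilities,
  per-cutoff concordance, sensitivity, specificity, clinical net benefit
  $NB(c)=\mathrm{sens}\cdot\pi-(1-\mathrm{spec})(1-\pi)\,c/(1-c)$, AUC, and
  the integrated discrimination improvement (IDI);
* a **synthetic cohort generator** (Hardy–Weinberg genotypes, age-driven
  logistic risk, planted extreme-age outliers, genotype missingness) so the
  whole pipeline is testable without restricted clinical data.

Inputs are VCF (GT field) or dosage TSV genotypes plus a phenotype TSV with
longitudinal measurements; a four-step filter (first complete measurement,
polymorphism, per-individual missingness ≤ 5%, per-variant completeness)
produces the analysis-ready dataset.

## Worked example

The `analysis/` scripts run the full comparison on a simulated cohort of
130 individuals × 500 SNPs (33% target prevalence, age OR 1.085/year, one
causal SNP, four planted extreme-age outliers):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_filter_and_screen.py
python analysis/03_baseline_models.py
python analysis/04_outlier_influence.py
python analysis/05_variant_scan.py
python analysis/06_cross_validation.py
```

Step 02 reports the filter outcome and the covariate screen:

```
retained 127 individuals x 446 variants; removals per criterion: {'c': 3, 'd': 54}
chi-square screen gender: p = 0.91 (excluded)
chi-square screen smoking: p = 0.48 (excluded)
baseline covariates beyond age: none
```

— three individuals exceeded 5% genotype missingness, 54 variants kept a
missing call, and the null gender/smoking covariates are correctly screened
out, leaving the age-only baseline.  Step 04 finds the planted outliers at
the top of the influence ranking:

```
7 individuals exceed the Cook's-distance threshold 0.05
  ind0078: D = 0.144, age = 93.5, status = 0 (planted)
  ind0056: D = 0.112, age = 22.7, status = 1 (planted)
  ...
excess-risk change upon exclusion (standard vs robust):
  ind0056: +15.1% vs +9.3%
```

For the young affected outlier ind0056 (Pearson residual ≈ 4, strongly
truncated by ψ_c) the robust age OR moves far less upon exclusion than the
standard one — the estimator already discounted that observation.  Step 06
prints the cross-validated performance of the age+SNP models, e.g.

```
LOOCV AUC: standard 0.771, robust 0.772; IDI +0.030
odds of hypertension per age quartile: <43.66: 0.19, ..., >=60.3064: 1.67
```

The same pipeline runs from the shell on any VCF + phenotype TSV:

```bash
roblogit run-all --genotypes cohort.vcf --phenotypes phenotypes.tsv --out results/
```

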