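# longrr — genomic random regression for longitudinal phenotypes

High-throughput phenotyping platforms image every plant in a trial every
day, turning a single trait into a 20-point growth trajectory per line.
`longrr` is a Python library for genomic prediction on such data: it models
projected shoot area (PSA) trajectories of a genotyped diversity panel —
under control and water-limited (drought) conditions — with a **random
regression model (RRM)**, and evaluates how well genetic growth curves can
be predicted for new lines, for future days, and under reduced phenotyping
schedules.

It is written for quantitative geneticists and breeders who want a
self-contained, scriptable alternative to Wombat/BLUPF90-style pipelines
for longitudinal genomic prediction experiments.

## The model

The adjusted phenotype of accession *i* on day *t* is

```
y_it = Σ_k φ_k(t) β_k + Σ_k φ_k(t) u_ik + Σ_k φ_k(t) pe_ik + ε_it
```

where φ(t) is a K-dimensional time basis — normalized Legendre polynomials
of the standardized day x ∈ [−1, 1], or B-splines built by the Cox–de Boor
recursion on s equidistant knots (K = s + d − 1) — β is the fixed
population-mean trajectory, u_i and pe_i are the additive-genetic and
permanent-environment regression coefficients of line *i*, and ε has a
separate variance per day.  In matrix form

```
y = Xβ + Zu + Q pe + ε,
Var(u) = G ⊗ Cu,   Var(pe) = I ⊗ Cpe,   Var(ε) = diag(σ²_t),
```

with G = W_sc W_sc′ / p the VanRaden genomic relationship matrix from
centered/standardized SNP dosages, and Cu, Cpe unstructured K×K covariance
functions.  Variance components are estimated by EM-REML on the mixed-model
equations; model fit is compared by −½AIC = logL − p and the matching
−½BIC, where p = 2·K(K+1)/2 + t_max counts the variance parameters.  The
implied genetic covariance between any two days is Φ Cu Φ′, and a line's
genetic value on *any* day in the window — phenotyped or not — is
ĝ_it = φ(t)′ û_i.

Three validation designs are built in:

* **CV1** — predict lines never phenotyped, via
  ĝ_tst = G_tst,trn G_trn,trn⁻¹ ĝ_trn, with a multi-trait GBLUP (one trait
  per day, unstructured Σu, Σε) as baseline;
* **CV2** — walk-forward forecasting: train on days 1..t, forecast each
  line's own days t+1..20 as ĝ_t′ = φ(t′)′ û_i;
* **CV3** — phenotyping-frequency reduction: train on odd days (A), even
  days (B) or every third day (C) of the 1–15 window, forecast days 16–20.

Accuracy is the Pearson correlation between predicted genetic values and
the held-out adjusted phenotypes, per day.

The package also ships the surrounding pipeline — PLINK 1 / CSV genotype
readers, call-rate/MAF quality control, mean imputation, IQR outlier
screening of plant records, per-day BLUE adjustment for experiment and
replicate effects — and a synthetic-data generator that emulates the whole
study (inbred structured panel, two treatments diverging after day 6,
basis-structured genetic and permanent-environment variation, day-specific
noise) with full ground truth for validation.

## A worked example

`examples/06_forecasting_cv.py` simulates a 100-line water-limited trial
whose genetic trajectories are quadratic, fits the linear-Legendre RRM, and
runs all three designs:

```
CV1 (new lines, all days): median accuracy per day quartile: [0.23 0.29 0.35]

CV2 (forecast own future): median accuracy at days 16-20
  trained on days 1.. 5: 0.09
  trained on days 1..10: 0.37
  trained on days 1..15: 0.65

CV3 (thinned phenotyping in days 1-15, forecast 16-20):
  CV3A (odd days  ): median accuracy 0.64
  CV3B (even days ): median accuracy 0.53
  CV3C (keep 1 of 3): median accuracy 0.50
```

Reading the numbers: predicting entirely new lines (CV1) is hardest early
in growth, when genetic variance is still small.  Forecast accuracy for the
last five days rises steeply with the length of the training window (0.09 →
0.65), and phenotyping only every other day (CV3A, 0.64) costs almost
nothing relative to the full window, while keeping just one day in three
(CV3C, 0.50) clearly hurts — the practical message being that imaging
frequency can be halved without losing predictive power.

The other examples walk through each stage: `01` genotypes → GRM, `02`
outlier screening → BLUEs, `03` the basis constructions, `04` an EM-REML
fit with variance-component recovery against ground truth, `05` the
multi-trait baseline and its equivalence with the saturated RRM.

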