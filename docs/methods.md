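# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `longrr`, together with what the synthetic-data
experiments do and do not demonstrate.

## Model and assumptions

The random regression model treats a line's growth curve as a smooth
function: genetic and permanent-environment effects are regressions on a
K-dimensional time basis, so each accession contributes K genetic and K
permanent-environment coefficients rather than one effect per day.
Assumptions: (i) multivariate-Gaussian effects and residuals; (ii) genetic
coefficients covary across lines proportionally to the genomic relationship
matrix G and across coefficients by an unstructured K×K matrix Cu
(Var(u) = G ⊗ Cu, accession-major stacking); (iii) permanent-environment
coefficients are independent across lines (I ⊗ Cpe); (iv) residuals are
independent with a free variance per day (heterogeneous diagonal R); (v)
the fixed effect is a single population mean trajectory on the same basis.
One adjusted record per accession-day enters the model; the permanent
environment is separated from the residual only because pe is
basis-structured (rank K over 20 days) while ε is free per day, and from
the genetic term only through G — see the identifiability remarks below.

### Bases

* **Legendre**: days are mapped to x = −1 + 2(t − t_min)/(t_max − t_min)
  and the design is Φ = MΛ with M the Vandermonde matrix in x and Λ the
  polynomial coefficients scaled to the orthonormal normalization
  P̄_j = sqrt((2j+1)/2) P_j.  K = d + 1.  The normalization affects the
  scale of Cu but not fits or predictions.
* **B-splines**: s equidistant knots on [t_min, t_max], boundary knots
  repeated d extra times, Cox–de Boor recursion with 0/0 := 0; zero-degree
  splines are half-open interval indicators with the last interval closed,
  so the basis is a partition of unity on the whole window including t_max.
  K = s + d − 1.

Both bases refuse to evaluate outside [t_min, t_max]: trajectories
interpolate but never extrapolate beyond the modelled window.  In
forecasting designs Φ is always built on the full window, so rows exist for
days the training data lack.

### Estimation

EM-REML on the mixed-model equations.  Each iteration solves the MME at the
current components (dense Cholesky; LAPACK `potri` for the inverse, which
the conditional-expectation updates need in full), then replaces Cu, Cpe
and σ²_t by their conditional expectations.  These updates are averages of
PSD terms, so positive (semi-)definiteness holds at every iterate without
reparameterization, and the restricted log-likelihood is non-decreasing —
a property the test suite asserts.  Matrices that touch the PD boundary
(degenerate inputs, e.g. duplicated traits) receive a minimal relative
jitter for inversion only; the multi-trait fitter additionally stops at the
last well-conditioned iterate if an update lands on the boundary.

The reported log-likelihood is the error-contrast (restricted) likelihood
including the −log|X′X| normalization, making it invariant to the scaling
of the fixed-effect basis and directly comparable between the RRM and the
multi-trait parameterization of the same model.  Model comparison uses
−½AIC = logL − p and −½BIC = logL − p/2 · ln(n_obs − rank X), with
p = 2·K(K+1)/2 + t_max variance parameters.  The ν = n_obs − rank X
convention for the BIC sample size is one of several in circulation;
−½BIC is therefore checked for formula correctness, not against any
published table.

Starting values: Cu = Cpe = ½·v̄ / ‖φ‖² · I with v̄ the mean within-day
phenotypic variance (the pooled variance would wrongly include the
mean-curve spread across days) and ‖φ‖² the mean squared basis-row norm;
σ²_t starts at half the day-t variance.  Convergence requires both
|ΔlogL| < tol (default 1e-6) and a maximum relative parameter change
< 1e-4, capped at 500 iterations with a warning.  EM is reliable but slow
along the u/pe ridge: at small n the likelihood is nearly flat in that
direction and fits may report `converged=False` while the estimates are
already at the optimum for every practical purpose; the heavy test-suite
studies therefore run with max_iter = 150–200 and tol = 1e-5, problem
sizes chosen as n = 300 × 20 days for recovery and n = 150 × 10 repeats
for the cross-validation studies.

### Genomic relationships

G = W_sc W_sc′/p with per-marker centering and population-SD (divisor n)
scaling, under which mean diag(G) = 1 exactly.  A ridge of 1e-6 is added to
the diagonal (recorded in the object) because downstream designs invert
training-set blocks of G.  QC removes markers with call rate ≤ the
threshold or MAF ≤ the threshold (strict inequalities retained — a literal
reading of the filter definition), and mean imputation stands in for
haplotype-based imputation: it preserves allele frequencies, which is all
the GRM consumes.  PLINK 1 binary (SNP-major) and a simple CSV dialect are
supported natively; dosages count A1 alleles.

### Phenotype adjustment

Outliers are flagged (never silently removed) per treatment-day group by
the k·IQR rule with type-7 quantiles; groups with fewer than 4 records are
skipped with a warning.  BLUEs are per-day ordinary least squares with
intercept, experiment, replicate-within-experiment and accession as fixed
effects; accessions are fixed because a best linear unbiased *estimator* is
only defined for fixed effects.  Rank deficiency is resolved by the
minimum-norm solution and the accession estimates are re-centered to the
group mean, which makes them invariant to the constraint choice whenever
accession contrasts are estimable (connected designs).  Replicate terms are
fitted only where estimable.

## Cross-validation conventions

* CV1 splits lines ceil(n/2)/floor(n/2); both the RRM and the MTM see the
  same splits per repeat, so comparisons are paired.  Predicted values that
  are constant yield an undefined correlation and are reported as missing
  with a warning.
* CV2/CV3 fit and evaluate the *same* random half of the lines: the design
  forecasts a line's own future, not other lines.  Forecast targets are the
  held-out-day BLUEs.  Training windows with fewer days than K are
  rejected.
* Repeat seeds derive from one master seed by fixed offsets, so a plan is
  bit-for-bit reproducible.

## The synthetic-data generator

The generator emulates a drought phenomics experiment on a structured crop
diversity panel; its defaults are the emulated study's conditions: 357
accessions, 35k SNPs, 20 daily records, three experiments with 54
accessions duplicated per experiment, treatments diverging after day 6.

* **Panel**: inbred (selfing-crop) lines — dosages are doubled haploid
  draws, hence {0, 2}; three subpopulations at Balding–Nichols Fst 0.3 with
  Dirichlet(0.3) admixture.  The admixture continuum matters: with discrete
  exchangeable groups the GRM is close to "identity plus low-rank" and the
  genetic vs permanent-environment decomposition (G⊗Cu vs I⊗Cpe) is so
  weakly identified at n = 300 that REML returns the *sum* accurately but
  splits it with ~30–50% noise.  Inbreeding, differentiation and admixture
  together give the relatedness spread that makes the split estimable
  (leading-eigenvalue recovery error ~14% median in the shipped test).
* **Trajectories**: coefficients drawn with Var(vec U) = G ⊗ Cu (sampled as
  chol(Cu)·Z·chol(G)′) and I ⊗ Cpe; records are mean curve + Φu + Φpe +
  experiment effect + day-specific noise, truncated at zero.  Default Cu
  gives a genetic variance fan that widens over growth; Cpe = 0.4·Cu;
  σ(t) = 2 + 1.4t.
* **Mean curves**: exponential (default) and logistic families emulate real
  shoot growth, with the water-limited arm growing at half rate after the
  divergence day; a linear family exists because variance-component
  *recovery* is only well-posed when the fixed curve lies in the span of
  the fitted basis — with a curved mean and a linear basis, the day-specific
  lack of fit is absorbed by the heterogeneous residuals, exactly as it
  would be in a real analysis.
* **What passing tests do not show**: the generator draws effects from the
  model's own distribution.  Real trajectories are not finite basis
  expansions, panels carry linkage disequilibrium and family structure the
  Balding–Nichols draw lacks, and outliers are not merely heavy-tailed
  noise.  Recovery results therefore certify the estimator, not the model's
  adequacy for any particular crop.

Two deliberate consequences for the qualitative experiments: under a
correctly-specified basis, a handful of training days saturates the
information in the K coefficients, so window-length and thinning
comparisons become ties; the shipped qualitative study therefore generates
quadratic-Legendre trajectories and fits the linear model, reproducing the
situation — universal with real growth data — where later time points carry
information the early window cannot supply.  For the same reason the
forecast-horizon ordering (day 16 vs day 20 accuracy) is not asserted: with
a correctly-specified linear basis it is genuinely noise-dominated, and the
degradation seen on real data is a misspecification effect.

## Known limitations

* EM-REML only (no average-information acceleration); hundreds of
  iterations are normal, and the u/pe direction converges slowly.
* The multi-trait baseline with unstructured 20×20 covariances is near
  the identifiability edge at a few hundred lines; it is certified by tests
  at t ≤ 5 days and intended as a baseline, not a production fitter.
* Equal basis order for fixed, genetic and permanent-environment terms;
  unequal orders are not supported.
* No dominance/epistatic relationship matrices, no LD-aware imputation, no
  spatial greenhouse-trend correction.
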