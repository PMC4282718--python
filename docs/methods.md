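# Methods

## The model

`metfa` analyses multi-environment variety trial (MET) data in two stages.
Stage 1 analyses each trial separately and produces, per variety, an
adjusted mean yield and a statistical weight (the reciprocal variance of
that mean).  Stage 2 combines the n variety means y across t environments
(location–year combinations) and m varieties in the weighted linear mixed
model

    y = X tau + Z u + Z_p u_p + eta

where tau holds the t trial means (fixed), u is the mt-vector of
variety-by-environment genetic effects ordered as varieties within
environments, u_p optional iid non-genetic random terms (off by default),
and var(eta) = Sigma is the known diagonal of reciprocal weights from
stage 1.  The genetic effects have var(u) = G_e ⊗ I_m with G_e a t×t
between-environment genetic variance matrix.  Supported structures:

| kind | G_e | free parameters |
|------|-----|-----------------|
| DIAG | diag(σ²_g1..t) | t |
| CS | σ²_g J + σ²_ge I | 2 |
| VC | σ²_g J + Σ_f σ²_f B_f + σ²_r I | 2 + #factors |
| FA(k) | ΛΛ' + diag(ψ) | t(k+1) − k(k−1)/2 |
| US | full symmetric PSD | t(t+1)/2 |

The factor analytic form is the workhorse: u_ij = Σ_r λ_rj f_ri + δ_ij
reads as a latent regression of variety effects on estimated environmental
covariates (loadings λ, in t/ha per unit score), with variety slopes
(scores f, var 1) and environment-specific residuals δ (specific variance
ψ_j).  Goodness of fit is summarised by the percentage of genetic variance
the factors account for, per environment (v_j) and overall (v̄, the
genetic-variance-weighted mean of the v_j).

The FA parameter count here is t(k+1) − k(k−1)/2: all loadings except the
k(k−1)/2 identification zeros, plus t specific variances, including any
pinned on the zero floor.  Published model summaries sometimes count
boundary-fixed parameters differently; this package documents and uses the
formula above.

## Estimation

Variance parameters are estimated by REML.  Because varieties are
independent under G_e ⊗ I_m and Sigma is diagonal, H = Z(G_e ⊗ I_m)Z' +
Sigma is block diagonal by variety, so the residual log-likelihood

    l_R = −½[(n−t) log 2π + log|H| + log|X'H⁻¹X| + y'Py]

is accumulated from per-variety blocks of size t_i (number of trials the
variety was grown in); varieties sharing an incidence pattern are batched.
The constant (n−t)/2·log 2π is included, so values agree with any dense
multivariate-normal implementation.  The gradient with respect to G_e has
the closed form −½(A − S2 − S3) (see `metfa/reml.py`), which each
structure chains to its own parameters.

Optimisation runs on an unconstrained parametrisation — variances on the
log scale with a floor of 1e-8 standing in for boundary zeros, loadings
free with the upper triangle of Λ fixed at 0 for identifiability — in
three phases:

1. **L-BFGS-B pre-phase** from deterministic starts: per-environment
   moment estimates of genetic variance, and for FA/US an
   eigen-decomposition of the moment variances combined with assumed
   common correlations (0.5, 0.8, 0.2) plus one jittered start.  Higher FA
   orders warm-start from the previous order.
2. **Average-information Newton polish**: AI-REML steps with a projected
   active set for floor-pinned parameters and backtracking line search.
   The quasi-Newton phase alone crawls in the flat tail typical of FA REML
   surfaces; AI steps converge in a handful of iterations.
3. **Boundary snap**: near-zero variances are pinned exactly on the 1e-8
   floor whenever that does not lower the log-likelihood by more than
   1e-9 (the log parametrisation is flat there and the optimiser can stall
   a few orders of magnitude above the boundary).

The optimiser target is a relative log-likelihood change below 1e-10 and
gradient below 1e-5 (`FitControl.ftol`, `gtol`), with max_iter 500; a fit
is *declared* converged when the final gradient maximum is below 1e-3 on
the log-likelihood scale, which is well inside statistical noise — the
oracle-equivalence tests confirm agreement with a brute-force dense
optimiser to 1e-4 in log-likelihood.

EBLUPs and prediction error variances (PEV) come from the same per-variety
blocks: for variety i with environment set J,

    f̃_i = Λ_J' H_i⁻¹ (y_i − X_i τ̂),   ũ_i = G[:,J] H_i⁻¹ (y_i − X_i τ̂),

and the PEV blocks include the X A⁻¹X' term carrying the uncertainty of
the estimated trial means.  PEV (and hence all standard errors and
accuracies) conditions on the estimated variance parameters; no
delta-method inflation for their uncertainty is attempted.  Per-variety
diagonal PEV blocks are stored; cross-variety covariance (which enters
only through τ̂) is not retained.

With peripheral random terms the block factorisation fails and a dense
implementation (numerical gradients) is used; this path is intended for
small datasets and is off by default.

## Post-fit tools

- **Order selection** fits FA1, FA2, … (warm-started) and stops at the
  first order whose v̄ reaches the threshold (default 80%).  AIC, BIC and
  the REML likelihood-ratio test against the previous order are reported
  but never decide: likelihood criteria tend to select unnecessarily high
  orders (AIC, REMLRT) or underfit (BIC).  The REMLRT p-value uses the
  plain chi-square reference; with boundary parameters the true null is a
  chi-square mixture, so the p-value is conservative.
- **Rotation**: Λ'Λ is eigen-decomposed and loadings/scores rotated so the
  first factor carries the maximum genetic covariance; column signs are
  fixed so each rotated loading column sums non-negative.  The PEV of
  rotated scores is the orthogonal transform of the fitted score PEV —
  algebraically identical to refitting with the rotated loadings held
  fixed, which is retained as a cross-check (`fa_eblups`).
- **Predictions**: the grower-facing quantity is the regression component
  β̃_ij = Σ_r λ*_rj f̃*_ri, defined for every variety-environment cell
  whether or not the variety was grown there; the residual δ̃ is
  environment-specific and non-repeatable.  ũ = β̃ + δ̃ exactly.
- **Accuracy**: per cell, sqrt(max(0, 1 − PEV(ũ_ij)/Ĝ_e[j,j])) — the
  standard correlation between true and predicted effect for an
  individual; per environment, the mean over varieties grown there.
- **Correlation heatmap ordering**: agglomerative clustering on the
  dissimilarity 1 − ĉ_jj' (zero diagonal), average linkage by default and
  configurable, leaf order of the dendrogram as display order.  The
  dissimilarity is the elementwise complement of the correlation matrix;
  the linkage choice is not canonical and other linkages may order real
  data differently.
- **Regional predictions** are (optionally weighted) means of β̃ over a
  group of environments; their standard errors use the full per-variety
  PEV block of the group, not independent diagonals.  For VC fits,
  `component_blups` provides the historical analogue (variety main effect
  + variety-by-region EBLUP).

## Data rules

Environments are keyed by location + "_" + year; regions (and optional
mega-regions) are attributes.  Trials showing no genetic variance are
dropped: stage-1 variety F-ratio < 1, or diagonal-fit genetic variance on
the zero floor.  Varieties grown in fewer than 4 remaining trials, or
flagged as fillers (an explicit input flag — there is no operational
definition), are then dropped in a single pass; every removal is logged
with its rule.  Weights are carried exactly as supplied, never
re-normalised.  Connectivity (varieties in common between trial pairs) is
diagnosed before FA fitting; a disconnected trial graph aborts the
pipeline with a component report, since FA models cannot be fitted across
fully disconnected subsets (indirect, moving-window connectivity is
acceptable).

## Stage 1 (simplified)

Each trial is analysed as an RCBD with additive fixed replicate and
variety effects by OLS: adjusted variety means (predictions averaged over
replicate levels), weight = 1/Var(adjusted mean) — for a balanced trial
with r replicates and residual mean square s², every weight is r/s² — the
partial F statistic for varieties, and the residual mean square.  Spatial
field-trend modelling and the full precision matrix of the means are out
of scope; only the diagonal weight approximation is carried forward,
consistent with the second stage's diagonal Sigma.

## Synthetic data

The generator emulates the structural features of national testing data
that drive the method, with defaults representing a five-year mega-region
study: 40 locations × 5 years (≈200 trials) in 8 regions, ≈200 distinct
varieties, FA order 5, three replicates.  Trial mean yields are uniform on
0.8–5 t/ha; error variances log-uniform on 0.01–2 (t/ha)² (a 200-fold
spread, which is why the weighted second stage matters); factor-1 loadings
are positive (|N(0.3, 0.12)|, ≈t/ha per unit score), higher factors
N(0, 0.12·0.8^(r−1)); specific variances uniform on 0.005–0.05 (t/ha)².
An optional switch ties factor-1 loadings to trial mean yield.  Variety
turnover follows an entry/retirement process (yearly retention 0.75 by
default, retired varieties never return), which produces the moving-window
connectivity pattern of real programs; the year-one cohort and yearly
intake are sized so the realised variety count is close to the configured
m.  `resimulate_met` redraws effects and noise under a fixed truth for
repeated-sampling studies.

The generator does **not** emulate spatial field trend, frost/disease
events, non-random variety placement within regions, or correlated
stage-1 errors; passing tests therefore demonstrate correctness of the
estimation machinery under the stated generative model, not robustness to
those features of real data.

## Problem sizes in the test-suite and acceptance script

Repeated-sampling checks use desk-scale studies chosen as the smallest
sizes at which the properties are informative: recovery of an FA2 truth at
t = 12, m ≈ 200 (100 replicates in the test suite, 60 in the acceptance
script); FA-versus-diagonal accuracy at t = 8, m = 40 (200 and 100
replicates respectively); oracle equivalence at t ≤ 3, m ≤ 10 where dense
brute-force optimisation is cheap.  The full pipeline example runs 30
trials (6 locations × 5 years) with 120 varieties.

## Known limitations

- PEV, standard errors and accuracies ignore variance-parameter
  uncertainty.
- The unstructured model is only usable when t(t+1)/2 parameters are
  estimable from the connectivity; no automatic check beyond optimizer
  behaviour is made.
- No prediction for environments outside the dataset, no environmental
  covariate interpretation of factors, no automatic mega-region
  discovery, and no spatial stage-1 analysis — all deliberate scope
  boundaries.
- The REMLRT boundary issue (chi-square mixture) is flagged but not
  corrected.
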