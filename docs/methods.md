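# Methods

## The screening model

For each gene *g* in a two-subtype cohort (subtypes c1 and c2), the
hazard of sample *i* is modelled as

    λ_ig(t) = λ0g(t) · exp( β1g·I(i ∈ c2) + β2g·X_ig + β3g·I(i ∈ c2)·X_ig )

where X_ig is log2(FPKM + 1) expression and I(·) the subtype indicator.
The baseline hazard λ0g(t) drops out of the partial likelihood and is
never estimated.  Two null hypotheses classify the gene:

* H0: β2g = 0 — the gene has no prognostic value in subtype c1;
* H0: β2g + β3g = 0 — no prognostic value in subtype c2.

Each contrast is tested per gene with a two-sided Wald statistic
z = wᵀβ̂ / √(wᵀ Σ̂ w) (w = (0,1,0) and (0,1,1) respectively, Σ̂ the
inverse observed information).  The two p-value families are adjusted
with Benjamini–Hochberg **separately** across genes — each contrast is
its own genome-wide screen — and a gene is labelled `c1_specific`,
`c2_specific`, `shared` or `none` by which adjusted p-values fall below
α (default 0.05, strict inequality).  Pooled adjustment across both
families is available behind a flag; in the null simulations below the
two choices give nearly identical calibration, and per-family adjustment
keeps each screen's FDR interpretable on its own.  A likelihood-ratio
version of each contrast (refit under wᵀβ = 0 via a null-space
reparameterisation) is available as a cross-check; Wald is the default
because it needs one fit per gene.  β1g is estimated but never tested.

## Fitting

The log partial likelihood, analytic gradient and observed information
are evaluated with Efron's tie correction by default (Breslow optional;
the two coincide to machine precision on tie-free data, which is a test
invariant).  Newton–Raphson starts at β = 0 with step-halving (up to 30
halvings) so the log-likelihood never decreases; convergence requires a
relative log-likelihood change below 1e-8 within 50 iterations.
Covariate columns are centered internally before exponentiation — the
partial likelihood is invariant to location shifts, so the estimates are
unchanged while exp(η) stays bounded during line search.

Degenerate genes never raise during a screen: expression constant
overall, constant within both subtype strata (interaction inestimable),
outcomes without events, or singular information produce an `unfit`
record; any coefficient escaping |β| > 10 is flagged as a monotone
likelihood (perfect separation of the event ranking).  Unfit genes are
excluded from both adjustment families.

## Data preparation

Features whose raw-FPKM row sum over *all* samples (subtypes combined)
is below 4 are deleted; the boundary is literal, so a sum of exactly 4
is retained.  Retained values are transformed to log2(FPKM + 1).
Samples missing any required clinical field (overall-survival time,
event indicator, subtype; the empty string, `NA`, `NaN` and
`[Not Available]` count as missing) are discarded, and the expression
columns are reordered to match the clinical rows.  A subtype arm with
fewer than 10 samples triggers a warning, not an error — extremely
unbalanced designs (such as 89:6) are analysable and are an explicit
study condition here.  The FPKM-sum filter is applied uniformly to any
dataset and its threshold is a flag.

## The synthetic cohort generator

The generator inverts the screening model so that every downstream stage
can be validated against known truth.  Gene classes are apportioned by
largest remainder (ties broken in the order null, c1_only, c2_only,
shared) and shuffled.  Effect sizes are parameterised by the two
contrasts: a class-`c1_only` gene has (β2, β3) = (b, −b), `c2_only`
(0, c), `shared` (b, c − b), with b = `beta2_effect` and c =
`beta3_effect`; the class invariants (which contrasts are zero) hold by
construction.

Event times are drawn by inverse-CDF sampling from a constant baseline
hazard (exponential; a Weibull shape is a config option), censoring from
an independent exponential with an optional administrative cutoff.
Expression is i.i.d. Normal per gene on the log2 scale and is centered
at its mean inside the linear predictor: a location shift only rescales
λ0, leaving the coefficients and the partial likelihood unchanged while
keeping the event fraction at its configured level.

Defaults emulate the study conditions of the motivating application:
n = 81 + 83 samples (the balanced esophageal design; 89:6 reproduces the
extreme head-and-neck imbalance), baseline rate 0.001/day (median
survival ≈ 690 days) with censor rate 0.0015/day giving ≈ 40% events,
expression mean 3 and SD 1 on the log2(FPKM+1) scale, and unit
log-hazard effects.

Two designs are provided and the distinction matters:

* **matched** (default): each gene receives its own survival
  realisation driven by that gene alone, so every per-gene fit is
  exactly correctly specified.  Calibration, recovery and
  classification studies use this design;
  `screen_genes_matched` pairs gene *g* with outcome row *g*.
* **cohort**: one shared outcome driven by a small set of driver genes
  (default one).  This is the realistic pipeline demonstration; with
  several drivers the per-gene marginal fits are approximations (omitted
  covariates attenuate marginal coefficients), and planted signal genes
  that are not selected as drivers are relabelled null in the returned
  truth, because the truth must describe the simulation actually run.

The generator does **not** model library-size effects, count
overdispersion, gene–gene correlation or competing risks, so passing
tests demonstrate correctness of the estimator and the decision rules
under a correctly specified proportional-hazards world — not robustness
to the full messiness of RNA-seq cohorts.

## Signature evaluation

A multivariate Cox model (same Newton engine, k gene covariates, no
subtype terms) gives each sample the risk score Σ_g coef_g · X_ig.
Samples are split at the **median** training score — ties go to the
low-risk group — and the two groups are compared with Kaplan–Meier
curves and the log-rank test (observed vs hypergeometric-expected events
per distinct event time; χ² with #groups − 1 degrees of freedom).  By
default the model is trained and evaluated on the same cohort,
reproducing the common in-sample convention; this is optimistic, and a
holdout split mode is available when honest error is wanted.

The Kaplan–Meier estimator takes an exact path when the risk sets
telescope (no censoring interleaved with events): the product collapses
to the empirical survival function and is computed as a single division,
making the no-censoring identity S = 1 − ECDF bit-exact; otherwise the
standard cumulative product is used.

Wilcoxon rank-sum comparisons (e.g. expression between subtypes) use
exact enumeration when the combined sample size is ≤ 20 with no ties,
else the normal approximation with tie-corrected variance and continuity
correction.  A cross-validated logistic classifier (AUC) quantifies how
much subtype information a signature carries.

## Study sizes and what the checks show

The bundled acceptance studies run at: null calibration on 1000-gene
all-null cohorts (KS distance of both p-value families from uniform,
rejection rate averaged over 20 replicates); recovery of β2 = 1 over
1000 matched genes (median absolute error, 95% Wald-CI coverage);
CI-width comparison of the minority contrast between the 81:83 and 89:6
designs over 400 genes per design; classification recovery over 50
replicates of 200-gene cohorts (70% null, 10% per signal class,
|effect| = 2); and the dissociation study over 50 replicates of a
10-gene subtype-independent prognostic signature (log-rank power vs
subtype AUC).  On one CPU the full set completes in under a minute.

At 89:6 a substantial fraction of fits for the minority contrast hit
monotone likelihoods (6 samples cannot always order events informatively)
and are reported as unfit; among converged fits the minority-contrast
CIs are several times wider than in the balanced design.  This is the
expected statistical price of extreme imbalance and is surfaced, not
hidden, by the recovery report.

## Known limitations

* Proportional hazards is assumed, never tested; no diagnostics are
  provided.
* The per-gene model contains only subtype, expression and their
  interaction; age/gender/stage adjustment is deliberately absent from
  the default model.
* No penalisation: the multivariate risk model needs events ≳ genes
  (it warns otherwise).
* In-sample risk evaluation overstates discrimination; use the holdout
  mode for unbiased estimates.
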