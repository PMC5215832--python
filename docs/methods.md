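# Methods

## Measurement model and estimation

The core model is a K-class mixture of independent Bernoulli variables
over J binary chronic-condition indicators.  Parameters are the class
proportions π (K−1 free) and the item-response probabilities ρ (K·J free),
giving npar = (K−1) + K·J.  The likelihood is computed on the compressed
table of distinct response patterns; this is exact (persons sharing a
pattern contribute identical terms) and makes each EM iteration
O(S·K·J) with S ≤ min(N, 2^J) — in sparse epidemiological tables S is a
few thousand even at N > 100,000.

Survey weights enter as a pseudo-likelihood.  Weights are rescaled to
mean 1 inside estimation so that log-likelihood magnitudes, convergence
tolerances and information criteria keep their usual N-scale meaning;
all reported descriptive prevalences use the original weights.  Whether
weights should enter the measurement model at all is left to the user
(`use_weights`); both choices are supported because practice varies.

**EM protocol.**  Each random start draws ρ ~ Uniform(0.05, 0.95) i.i.d.
and π from a flat Dirichlet.  Starts use independent child streams of one
master `SeedSequence`, so increasing the number of starts never perturbs
earlier ones and every fit is bit-reproducible from its seed.
Convergence is declared when the relative log-likelihood change falls
below 1e−8 (default) or after 1,000 iterations; the winning start is then
polished at a 100× tighter tolerance.  The default protocol uses 500
starts and requires the best log-likelihood to be replicated by at least
5 starts within 0.01 log-units; if not, the number of starts doubles (at
most twice) and the fit is otherwise returned flagged `replicated=False`
rather than raised.  Tests and the reproduction script use 6–25 starts,
which is ample at their problem sizes; the replication check still
applies.

**Numerical guards.**  All mixture arithmetic is in log space.  ρ is
clamped to [1e−6, 1−1e−6] at every M-step; clamping sets a boundary flag,
which together with non-replication and the S ≥ K requirement forms the
identifiability reporting (no claim is made to reproduce any specific
commercial package's "not well identified" rule).  A class whose total
posterior mass reaches zero raises a degenerate-class error; starts that
degenerate are discarded and simply not counted.  Label switching is
resolved by ordering classes by descending π with lexicographic
tie-breaks on the ρ row.

## Model-selection panel

BIC uses the unweighted person count N (the convention consistent with
the published panel's arithmetic, up to its printed rounding).  L² is the
likelihood-ratio chi-square against the saturated model restricted to
observed patterns — the standard choice for sparse tables.  The
dissimilarity index is computed exactly at any J by summing |p̂ − p| over
observed patterns and charging the model's total mass on never-observed
patterns (where p = 0), then halving; no 2^J enumeration occurs.
NFI = 1 − L²_model/L²_baseline with the one-class model as baseline;
published NFI conventions vary and this definition is documented rather
than asserted to be identical to any particular implementation.

The sweep's default heuristic selects the smallest K with I_d ≤ 0.05,
NFI ≥ 0.80 and a replicated log-likelihood, falling back to the BIC
minimum when no K qualifies.  K = 1 qualifies on I_d alone since NFI
cannot certify its own baseline.  The applied decision in real analyses
also involves substantive interpretability; the package encodes only the
quantitative part and always emits the full panel.

## Classification and three-step corrections

Modal assignment takes the argmax posterior (ties to the lowest class
index — probability-zero for continuous posteriors but reachable in toy
data).  The classification error is E = 1 − weighted mean max-posterior;
the error matrix D is estimated by posterior-weighted cross-tabulation
(the ML three-step convention), not by simulation.

The **ML correction** maximizes Σ w_i log Σ_t P(X=t|z_i; β) D[t, W_i] by
L-BFGS with an analytic gradient; the covariance is the inverse observed
information obtained by central differences of that gradient.  Wald 95%
CIs use z = 1.96; each covariate also gets a joint χ²(K−1) Wald test
across the non-reference equations.  Coefficients larger than 15 in
absolute value trigger a separation error with diagnostics.  With
D = I the objective is exactly the ordinary multinomial logit on the
modal classes; the test suite verifies this reduction against
statsmodels' independent implementation.

The **BCH correction** weights each person into every class by the row of
D^{-1} selected by their modal class; class means are the weighted
averages under these (possibly negative) weights.  SEs and the
covariance of the K means come from a nonparametric bootstrap over
persons (B = 200 by default, seed-controlled).  Equality of means is
tested two ways: a Wald χ²(K−1) on contrasts of the BCH means using the
bootstrap covariance, and a classic weighted one-way ANOVA F on the modal
groups (the naive path), both always reported.  The bootstrap Wald runs
slightly liberal in moderate samples (observed ≈ 7% rejection at nominal
5% with N = 2,000); the type-I-error test bands account for this.  If D
is ill-conditioned (condition number > 1e8) the estimator falls back to
naive modal means and flags the entry.

The split — ML for covariates, BCH for continuous distal outcomes —
follows the three-step literature's recommendation: the ML variant is
efficient for membership regression, while BCH is robust for outcome
means because it never modifies the outcome model.

## Synthetic-data generator

The generator forward-samples the assumed data-generating process and
returns true labels for use as a test oracle.  Defaults encode the
seven-class reference solution for 15 chronic conditions: proportions
(0.59, 0.14, 0.10, 0.07, 0.06, 0.03, 0.02) — printed values whose sum of
1.01 reflects rounding and is renormalized proportionally, with the
adjustment recorded on the config — and the full 7×15 item-probability
matrix.  The default covariate is female gender with marginal 0.51 and
per-class odds ratios (1.0, 0.7, 1.9, 2.8, 1.3, 1.3, 1.3) on class
membership; intercepts of the class logit are solved by fixed-point
iteration so the marginal class mix still matches π.  Covariates can
alternatively be generated class-conditionally from given per-class
probabilities.

Outcome scales emulate the eight SF-12 norm-based dimensions (population
mean 50, SD 10).  **The class-specific outcome means are synthetic
placeholders** chosen only to be directionally plausible (quality of life
degrading from the healthy class to the two complex-multimorbidity
classes, mental scales dipping for the headache–mental class); no
reference values exist for them and none are claimed.  Outcomes are
homoscedastic Normal within class — real scale scores are bounded and
skewed, so outcome-related tests demonstrate estimator correctness under
the model, not distributional robustness.

Other simplifications relative to real survey data: indicators are
exactly conditionally independent given class (no local dependence),
weights are i.i.d. lognormal or constant rather than calibration weights
correlated with demographics, and missingness is injected completely at
random.  Passing tests therefore certify the estimators under the
assumed model, not the substantive findings of any particular survey.

## Problem sizes used in tests and the reproduction script

The reproduction script simulates 200,000 records for the classification
error check, 50,000 (with 25 EM starts plus the replication check) for
the generator-to-fit recovery of the largest class proportion, and
100,000 for the three-step odds-ratio recovery; these sizes give
Monte-Carlo error comfortably inside the stated tolerances
(SE ≈ 0.001 on E, ≈ 0.004 on π̂₁, ≈ 0.16 on the recovered OR) while
keeping the full run to a couple of minutes on one CPU.  Unit tests use
3,000–50,000 records and 6–25 starts on lower-dimensional class
structures for the same reason.

## Known limitations

Binary indicators only (no ordinal/polytomous items); no covariates
inside the measurement model (one-step estimation); no local-dependence
modelling; no bootstrap likelihood-ratio test for K; variance estimation
uses weights but not complex survey design (strata/clusters); the BCH
bootstrap treats D as estimated per resample only through the fixed D —
resampling re-estimates means, not the measurement model.
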