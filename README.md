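# multilca

Latent-class analysis of multimorbidity in population health surveys.

Many people report not one chronic disease but several, and the
combinations are far from random: hypertension travels with diabetes,
migraine with mental disorders, asthma with allergy.  `multilca` segments a
surveyed population into a small number of latent classes with distinct
disease profiles, starting from nothing more than a person-level table of
binary chronic-condition indicators (plus optional survey weights,
socio-demographic covariates and continuous health-related quality-of-life
scales).  It is aimed at epidemiologists and health-services researchers
who want a model-based alternative to disease counts or ad-hoc clustering.

## The model

The measurement model is a finite mixture of Bernoulli distributions
(classical latent class analysis).  With latent class $X \in \{1,\dots,K\}$
and binary indicators $y_1,\dots,y_J$ assumed conditionally independent
given $X$:

$$P(y) = \sum_{k=1}^{K} \pi_k \prod_{j=1}^{J} \rho_{kj}^{y_j} (1-\rho_{kj})^{1-y_j}$$

where $\pi_k$ are class proportions and $\rho_{kj}$ are item-response
probabilities.  Estimation is maximum (pseudo-)likelihood by EM on the
compressed table of distinct response patterns, with many random restarts
and an explicit replication check on the best log-likelihood.  Model
selection reports the full panel familiar from the applied literature:
BIC, AIC, modal classification error $E$, the dissimilarity index $I_d$
(total-variation distance between observed and fitted pattern
distributions) and the normed fit index (NFI) against the one-class
baseline.

Because modal class assignment misclassifies a predictable share of
people, step-3 analyses use bias-adjusted three-step estimators built on
the classification-error matrix $D$ with $D_{ts} = P(W{=}s \mid X{=}t)$:
the **ML correction** for multinomial logistic regression of class
membership on covariates (odds ratios with Wald 95% CIs), and the **BCH
correction** for class-specific means of continuous distal outcomes
(bootstrap SEs, Wald equality tests).

A synthetic-data generator ships with the package.  Its default
configuration is a seven-class model of 15 chronic conditions in an adult
general population — a relatively-healthy majority class (~59%) and six
multimorbidity classes (hypertension; musculoskeletal; headache–mental;
asthma–allergy; complex cardiometabolic; complex respiratory) — so every
stage of the pipeline can be exercised end-to-end without access to any
survey microdata.

## Worked example

```python
import numpy as np
from multilca import (default_config, simulate_population, LatentClassModel,
                      modal_assign, error_matrix, fit_covariates_ml)

cfg = default_config()                      # seven-class reference ground truth
ds, labels = simulate_population(cfg, n=20_000, seed=1)

res = LatentClassModel(ds, n_classes=7).fit(n_starts=25, seed=1)
print(res.summary().iloc[:3, :3].round(3))

tau = res.predict_posterior(ds.indicators)
assign = modal_assign(tau)
D = error_matrix(tau, assign, ds.weights)
cm = fit_covariates_ml(assign, D, ds.covariates, ref_class=1)
print(cm.summary()[cm.summary().covariate == "female"]
      [["class", "odds_ratio", "ci_lower", "ci_upper"]].round(2))
```

Output (seed 1):

```
                        class_1  class_2  class_3
class_proportion          0.605    0.129    0.097
hypertension              0.061    0.624    0.307
ischemic_heart_disease    0.000    0.075    0.033
```

```
    class  odds_ratio  ci_lower  ci_upper
1       2        0.65      0.55      0.77
3       3        1.90      1.56      2.31
5       4        2.63      2.11      3.29
7       5        1.41      1.15      1.72
9       6        1.57      1.19      2.08
11      7        1.56      1.17      2.07
```

The first table is the fitted class profile: 60.5% of the synthetic
population falls in the relatively-healthy class, and the second class
reports hypertension with probability 0.62 — both close to the generator's
ground truth (0.584 after renormalization, and 0.63).  The second table
shows the bias-adjusted odds ratios of being female on membership of each
multimorbidity class versus the healthy reference: women are markedly
over-represented in the headache–mental class (OR ≈ 2.6 here at N=20,000,
generator truth 2.8) and under-represented in the hypertension class
(OR ≈ 0.65, truth 0.7).

There is also a CLI (`multilca simulate | prep | fit | sweep | classify |
threestep | run`) that writes the descriptive, fit-panel, class-profile,
odds-ratio and distal-profile tables plus a reproducibility manifest.

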