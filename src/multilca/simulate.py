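"""Synthetic populations with the structure the analysis assumes.

The generator forward-samples the latent class model: a class label per
person from the class proportions (or from a multinomial logit on
covariates), conditionally independent Bernoulli indicators given the
class, Normal continuous outcomes with class-specific means, optional
lognormal survey weights and optional missingness.  True class labels are
returned alongside so tests can use them as an oracle.

The default configuration is a seven-class model of 15 chronic conditions
in an adult general population: a large relatively-healthy class (~59%)
and six multimorbidity classes dominated respectively by hypertension,
musculoskeletal disorders, headache plus mental disorders, asthma-allergy,
complex cardiometabolic disease and complex respiratory disease.  The
printed reference proportions sum to 1.01 from rounding and are
renormalized (recorded on the config).  The default female-gender effect
on class membership uses the reference odds ratios per class; the
SF-12-like outcome means are synthetic placeholders (norm-based scales,
population mean 50, SD 10), not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IndicatorDataset

__all__ = [
    "SyntheticConfig",
    "CovariateSpec",
    "OutcomeSpec",
    "default_config",
    "simulate_population",
    "inject_missingness",
    "solve_logit_intercepts",
    "DISEASE_NAMES",
    "CLASS_LABELS",
    "REFERENCE_CLASS_PROPORTIONS",
    "REFERENCE_ITEM_PROBS",
    "REFERENCE_FEMALE_ORS",
]

DISEASE_NAMES = [
    "hypertension",
    "ischemic_heart_disease",
    "stroke",
    "diabetes",
    "cancer",
    "copd",
    "asthma",
    "allergy",
    "arthritis",
    "osteoporosis",
    "back_injury",
    "mental_disorders",
    "migraine_headache",
    "tinnitus",
    "cataract",
]

CLASS_LABELS = [
    "Relatively Healthy",
    "Hypertension",
    "Musculoskeletal Disorders",
    "Headache-Mental Disorders",
    "Asthma-Allergy",
    "Complex Cardiometabolic Disorders",
    "Complex Respiratory Disorders",
]

# Seven-class reference solution: class proportions (printed values sum to
# 1.01 and are renormalized at config time) and item-response probabilities,
# rows = classes, columns = the 15 conditions in DISEASE_NAMES order.
REFERENCE_CLASS_PROPORTIONS = np.array([0.59, 0.14, 0.10, 0.07, 0.06, 0.03, 0.02])

REFERENCE_ITEM_PROBS = np.array(
    [
        # hyp   ihd   strk  diab  canc  copd  asth  allg  arth  osteo back  ment  migr  tinn  cata
        [0.05, 0.00, 0.00, 0.01, 0.01, 0.01, 0.02, 0.14, 0.05, 0.01, 0.05, 0.06, 0.09, 0.07, 0.01],
        [0.63, 0.08, 0.05, 0.23, 0.06, 0.06, 0.02, 0.10, 0.33, 0.06, 0.09, 0.06, 0.05, 0.16, 0.12],
        [0.25, 0.02, 0.01, 0.02, 0.06, 0.06, 0.01, 0.19, 0.77, 0.13, 0.37, 0.08, 0.12, 0.21, 0.11],
        [0.13, 0.03, 0.02, 0.02, 0.02, 0.04, 0.08, 0.33, 0.30, 0.02, 0.35, 0.42, 0.65, 0.22, 0.01],
        [0.05, 0.00, 0.00, 0.01, 0.01, 0.01, 0.46, 0.94, 0.08, 0.00, 0.08, 0.13, 0.18, 0.09, 0.00],
        [0.73, 0.30, 0.14, 0.29, 0.09, 0.22, 0.16, 0.34, 0.84, 0.19, 0.60, 0.30, 0.37, 0.34, 0.26],
        [0.38, 0.09, 0.04, 0.12, 0.07, 0.69, 0.91, 0.46, 0.50, 0.15, 0.30, 0.19, 0.21, 0.20, 0.12],
    ]
)

# Reference per-class odds ratios for female gender (vs. male, reference
# class = class 1); marginal share of women ~0.51.
REFERENCE_FEMALE_ORS = np.array([1.0, 0.7, 1.9, 2.8, 1.3, 1.3, 1.3])

# Synthetic SF-12-like scale names and class means.  Norm-based scales
# (population mean 50, SD 10); the class means below are invented,
# plausibility-only values ordered so that quality of life degrades from
# the healthy class to the two complex-multimorbidity classes.
SF12_SCALES = [
    "physical_functioning",
    "role_physical",
    "bodily_pain",
    "general_health",
    "vitality",
    "social_functioning",
    "role_emotional",
    "mental_health",
]

_SYNTHETIC_SCALE_MEANS = {
    # class:            1     2     3     4     5     6     7
    "physical_functioning": [54.0, 46.0, 43.0, 48.0, 53.0, 33.0, 33.5],
    "role_physical": [53.0, 47.0, 44.0, 46.0, 52.0, 34.0, 34.5],
    "bodily_pain": [54.0, 47.0, 41.0, 44.0, 52.0, 35.0, 35.5],
    "general_health": [53.0, 46.0, 44.0, 44.0, 50.0, 33.0, 33.0],
    "vitality": [53.0, 49.0, 47.0, 44.0, 51.0, 40.0, 40.5],
    "social_functioning": [53.0, 50.0, 48.0, 43.0, 51.0, 41.0, 41.0],
    "role_emotional": [52.0, 50.0, 49.0, 42.0, 50.0, 43.0, 43.0],
    "mental_health": [52.0, 51.0, 50.0, 41.0, 50.0, 44.0, 44.0],
}


@dataclass
class CovariateSpec:
    """One generated covariate.

    mode "logit": binary covariate with the given marginal probability and
    per-class odds ratios on class membership (reference class 1); the
    class-model intercepts are solved so the marginal class distribution
    matches the configured proportions.
    mode "class_conditional": sampled from class-specific Bernoulli
    probabilities directly.
    """

    name: str
    mode: str = "logit"  # "logit" | "class_conditional"
    marginal: float = 0.5
    class_odds_ratios: np.ndarray | None = None
    class_probs: np.ndarray | None = None


@dataclass
class OutcomeSpec:
    """A continuous outcome with class-specific Normal means and one SD."""

    name: str
    class_means: np.ndarray
    sd: float = 10.0


@dataclass
class SyntheticConfig:
    """Ground truth for a synthetic population."""

    class_proportions: np.ndarray
    item_probs: np.ndarray
    item_names: list[str]
    class_labels: list[str] | None = None
    covariates: list[CovariateSpec] = field(default_factory=list)
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    weight_mode: str = "constant"  # "constant" | "lognormal"
    weight_sigma: float = 0.3
    missing_rate: float = 0.0
    all_missing_rate: float = 0.0
    pi_renormalized: bool = False

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.item_probs = np.atleast_2d(np.asarray(self.item_probs, dtype=float))
        total = self.class_proportions.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            if not np.isclose(total, 1.0, atol=0.05):
                raise ValueError("class proportions too far from 1 to renormalize")
            self.class_proportions = self.class_proportions / total
            self.pi_renormalized = True
        if np.any(self.item_probs < 0) or np.any(self.item_probs > 1):
            raise ValueError("item probabilities must lie in [0, 1]")
        if self.item_probs.shape[0] != len(self.class_proportions):
            raise ValueError("item_probs rows must match number of classes")
        for spec in self.outcomes:
            if spec.sd <= 0:
                raise ValueError("outcome SDs must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def n_items(self) -> int:
        return self.item_probs.shape[1]

    def implied_item_prevalence(self) -> np.ndarray:
        """Model-implied marginal prevalence per item: sum_k pi_k rho_kj."""
        return self.class_proportions @ self.item_probs


def default_config(include_covariates: bool = True, include_outcomes: bool = True) -> SyntheticConfig:
    """Seven-class, fifteen-condition reference configuration.

    Class proportions and item-response probabilities are the reference
    seven-class solution (proportions renormalized from their printed sum
    of 1.01); the female covariate uses the reference per-class odds
    ratios; outcome class means are synthetic placeholders, not reference
    values.
    """
    covs = (
        [
            CovariateSpec(
                name="female",
                mode="logit",
                marginal=0.51,
                class_odds_ratios=REFERENCE_FEMALE_ORS.copy(),
            )
        ]
        if include_covariates
        else []
    )
    outs = (
        [
            OutcomeSpec(name=scale, class_means=np.asarray(means), sd=10.0)
            for scale, means in _SYNTHETIC_SCALE_MEANS.items()
        ]
        if include_outcomes
        else []
    )
    return SyntheticConfig(
        class_proportions=REFERENCE_CLASS_PROPORTIONS.copy(),
        item_probs=REFERENCE_ITEM_PROBS.copy(),
        item_names=list(DISEASE_NAMES),
        class_labels=list(CLASS_LABELS),
        covariates=covs,
        outcomes=outs,
    )


def solve_logit_intercepts(
    pi: np.ndarray, betas: np.ndarray, cov_values: np.ndarray, cov_probs: np.ndarray
) -> np.ndarray:
    """Intercepts a_k of a class-membership logit so the marginal class
    distribution matches ``pi``.

    The class model is P(X=k | x) = softmax_k(a_k + b_k x) with a_1 = 0,
    b_1 = 0; ``betas`` holds b_k per class, ``cov_values``/``cov_probs``
    the (discrete) covariate distribution.  Solved by a fixed-point
    iteration a_k <- a_k + log(pi_k / pihat_k), which converges quickly
    for well-posed targets.
    """
    k = len(pi)
    a = np.log(pi / pi[0])
    for _ in range(500):
        eta = a[None, :] + np.outer(cov_values, betas)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        marginal = cov_probs @ p
        if np.max(np.abs(marginal - pi)) < 1e-12:
            break
        a = a + np.log(pi / marginal)
        a -= a[0]
    return a


def _draw_classes(
    cfg: SyntheticConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Sample covariates and class labels (1-based)."""
    logit_specs = [c for c in cfg.covariates if c.mode == "logit"]
    cov_frame: dict[str, np.ndarray] = {}
    if logit_specs:
        if len(logit_specs) > 1:
            raise NotImplementedError("one logit-mode covariate is supported")
        spec = logit_specs[0]
        x = (rng.random(n) < spec.marginal).astype(float)
        betas = np.log(np.asarray(spec.class_odds_ratios, dtype=float))
        a = solve_logit_intercepts(
            cfg.class_proportions,
            betas,
            cov_values=np.array([0.0, 1.0]),
            cov_probs=np.array([1 - spec.marginal, spec.marginal]),
        )
        eta = a[None, :] + np.outer(x, betas)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        labels = 1 + (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
        cov_frame[spec.name] = x
    else:
        labels = 1 + rng.choice(cfg.n_classes, size=n, p=cfg.class_proportions)

    for spec in cfg.covariates:
        if spec.mode == "class_conditional":
            probs = np.asarray(spec.class_probs, dtype=float)[labels - 1]
            cov_frame[spec.name] = (rng.random(n) < probs).astype(float)
    frame = pd.DataFrame(cov_frame) if cov_frame else None
    return labels, frame


def simulate_population(
    cfg: SyntheticConfig, n: int, seed: int | None = None
) -> tuple[IndicatorDataset, np.ndarray]:
    """Forward-sample a population of ``n`` persons.

    Returns the dataset and the true 1-based class labels (the test
    oracle).  Covariate-driven class assignment is used when a logit-mode
    covariate is configured, otherwise classes are drawn from the class
    proportions directly.
    """
    rng = np.random.default_rng(seed)
    labels, covariates = _draw_classes(cfg, n, rng)
    rho = cfg.item_probs[labels - 1]
    indicators = (rng.random((n, cfg.n_items)) < rho).astype(float)

    outcomes = None
    if cfg.outcomes:
        outcomes = pd.DataFrame(
            {
                spec.name: np.asarray(spec.class_means, dtype=float)[labels - 1]
                + spec.sd * rng.standard_normal(n)
                for spec in cfg.outcomes
            }
        )

    if cfg.weight_mode == "constant":
        weights = np.ones(n)
    elif cfg.weight_mode == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=cfg.weight_sigma, size=n)
    else:
        raise ValueError(f"unknown weight mode {cfg.weight_mode!r}")

    ds = IndicatorDataset(
        indicators=indicators,
        weights=weights,
        covariates=covariates,
        outcomes=outcomes,
        item_names=list(cfg.item_names),
    )
    if cfg.missing_rate > 0 or cfg.all_missing_rate > 0:
        ds = inject_missingness(
            ds,
            rate=cfg.missing_rate,
            all_missing_rate=cfg.all_missing_rate,
            seed=None if seed is None else seed + 1,
        )
    return ds, labels


def inject_missingness(
    ds: IndicatorDataset,
    rate: float,
    all_missing_rate: float = 0.0,
    seed: int | None = None,
) -> IndicatorDataset:
    """Blank indicator cells independently with probability ``rate`` and,
    additionally, blank every item for a fraction ``all_missing_rate`` of
    persons (those rows are what the missingness rule later drops)."""
    if not (0 <= rate <= 1 and 0 <= all_missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ind = ds.indicators.copy()
    if rate > 0:
        ind[rng.random(ind.shape) < rate] = np.nan
    if all_missing_rate > 0:
        rows = rng.random(ds.n_persons) < all_missing_rate
        ind[rows] = np.nan
    return IndicatorDataset(
        indicators=ind,
        weights=ds.weights.copy(),
        covariates=None if ds.covariates is None else ds.covariates.copy(),
        outcomes=None if ds.outcomes is None else ds.outcomes.copy(),
        item_names=list(ds.item_names),
        person_index=ds.person_index.copy(),
        n_dropped=ds.n_dropped,
    )
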