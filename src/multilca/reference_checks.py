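"""Reference consistency checks built on the seven-class default model.

These functions recompute, from the package's own machinery, quantities
that can be cross-checked against the published seven-class solution:
model-implied marginal prevalences, the expected modal classification
error, generator-to-fit recovery of the largest class proportion, and
three-step recovery of a covariate odds ratio.  They are used by the test
suite and the reproduction script; each takes an explicit seed.
"""

from __future__ import annotations

import numpy as np

from .classify import classification_error, error_matrix, modal_assign
from .model import LCAParams, LatentClassModel, _component_log_probs
from .simulate import default_config, simulate_population
from .threestep import fit_covariates_ml

__all__ = [
    "implied_prevalence_percent",
    "expected_classification_error_pct",
    "refit_largest_class_proportion",
    "recover_female_odds_ratio",
]


def _true_params():
    """Reference measurement parameters and the matching generator config."""
    cfg = default_config(include_covariates=False, include_outcomes=False)
    return LCAParams(cfg.class_proportions, cfg.item_probs), cfg


def implied_prevalence_percent(item: str) -> float:
    """Model-implied marginal prevalence of one condition, in percent,
    rounded to the nearest integer: 100 * sum_k pi_k rho_k,item."""
    cfg = default_config(include_covariates=False, include_outcomes=False)
    j = cfg.item_names.index(item)
    return float(np.round(100.0 * cfg.implied_item_prevalence()[j]))


def true_posteriors(indicators: np.ndarray) -> np.ndarray:
    params, _ = _true_params()
    lp = _component_log_probs(params, indicators)
    tau = np.exp(lp - lp.max(axis=1, keepdims=True))
    return tau / tau.sum(axis=1, keepdims=True)


def expected_classification_error_pct(n: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the seven-class modal classification error,
    in percent: simulate from the reference parameters, compute posteriors
    under those same parameters, average 1 - max posterior."""
    _, cfg = _true_params()
    ds, _ = simulate_population(cfg, n=n, seed=seed)
    tau = true_posteriors(ds.indicators)
    return 100.0 * classification_error(tau)


def refit_largest_class_proportion(
    n: int = 50_000, n_starts: int = 25, seed: int = 0
) -> float:
    """Generator-to-fit loop: simulate from the reference seven-class
    parameters, refit K = 7 by EM with random restarts and the replication
    check, return the largest fitted class proportion."""
    _, cfg = _true_params()
    ds, _ = simulate_population(cfg, n=n, seed=seed)
    res = LatentClassModel(ds, 7).fit(n_starts=n_starts, seed=seed)
    return float(res.params.class_proportions[0])


def recover_female_odds_ratio(
    n: int = 100_000, seed: int = 0, class_index: int = 4
) -> float:
    """Three-step ML recovery of the female odds ratio on membership of
    the headache-mental class (class 4) versus the relatively-healthy
    reference class.  The generator assigns classes via a multinomial
    logit whose female effects are the logs of the reference odds ratios;
    posteriors and modal assignments use the true measurement parameters.
    """
    cfg = default_config(include_outcomes=False)
    ds, _ = simulate_population(cfg, n=n, seed=seed)
    tau = true_posteriors(ds.indicators)
    assign = modal_assign(tau)
    d = error_matrix(tau, assign)
    model = fit_covariates_ml(assign, d, ds.covariates, ref_class=1)
    return model.odds_ratio(class_index, "female")
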