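"""Model-selection panel for latent class sweeps.

For each candidate number of classes K the panel reports: number of free
parameters, log-likelihood, BIC, AIC, modal classification error E, the
dissimilarity index I_d (total-variation distance between observed and
model-implied pattern distributions), the likelihood-ratio chi-square L2
against the saturated model, and the normed fit index NFI relative to the
one-class (independence) baseline.  Conventions:

* npar = (K - 1) + K * J (class proportions plus item probabilities).
* BIC uses the unweighted person count N.
* L2 sums over observed patterns only (the saturated reference for sparse
  tables); I_d additionally charges the model mass on unobserved patterns,
  making it the exact total-variation distance at any J.
* NFI = 1 - L2_model / L2_baseline; an NFI of 0.8 means the model removes
  80% of the baseline's residual association.

The default selection heuristic picks the smallest K whose fit is adequate
(I_d <= 0.05 and NFI >= 0.80) and whose likelihood was replicated across
starts; the full panel is always returned so users can override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PatternTable
from .model import LCAParams, LatentClassModel, LatentClassResults, e_step

__all__ = [
    "FitStatistics",
    "SweepResult",
    "count_parameters",
    "aic",
    "bic",
    "l2_statistic",
    "dissimilarity_index",
    "normed_fit_index",
    "compute_fit_statistics",
    "sweep_models",
]


def count_parameters(n_classes: int, n_items: int) -> int:
    """Free parameters of a K-class model on J binary items: K-1 mixing
    proportions plus K*J item probabilities."""
    if n_classes < 1 or n_items < 1:
        raise ValueError("n_classes and n_items must be >= 1")
    return (n_classes - 1) + n_classes * n_items


def aic(loglik: float, npar: int) -> float:
    return -2.0 * loglik + 2.0 * npar


def bic(loglik: float, npar: int, n_obs: int) -> float:
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + npar * np.log(n_obs)


def _model_pattern_probs(params: LCAParams, pt: PatternTable) -> np.ndarray:
    from .model import _component_log_probs
    from scipy.special import logsumexp

    return np.exp(logsumexp(_component_log_probs(params, pt.patterns), axis=1))


def l2_statistic(params: LCAParams, pt: PatternTable) -> float:
    """Likelihood-ratio chi-square vs. the saturated model, over observed
    patterns: L2 = 2 * sum_s n_s * ln(n_s / e_s), e_s = W * P(pattern_s)."""
    n = pt.counts
    e = pt.total_weight * _model_pattern_probs(params, pt)
    return float(2.0 * np.sum(n * (np.log(n) - np.log(e))))


def dissimilarity_index(params: LCAParams, pt: PatternTable) -> float:
    """Total-variation distance between observed and model-implied pattern
    distributions.  Observed patterns contribute |p_hat - p|; the model's
    mass on never-observed patterns (where p = 0) contributes in full, so
    no 2**J enumeration is needed and the value is exact."""
    p_obs = pt.observed_proportions()
    p_mod = _model_pattern_probs(params, pt)
    unobserved_mass = max(0.0, 1.0 - p_mod.sum())
    return float(0.5 * (np.abs(p_mod - p_obs).sum() + unobserved_mass))


def normed_fit_index(l2_model: float, l2_baseline: float) -> float:
    """NFI = 1 - L2_model / L2_baseline (baseline = one-class model)."""
    if l2_baseline <= 0:
        raise ValueError("baseline L2 must be positive")
    return 1.0 - l2_model / l2_baseline


@dataclass
class FitStatistics:
    """One row of the selection panel."""

    n_classes: int
    npar: int
    loglik: float
    bic: float
    aic: float
    classification_error: float
    dissimilarity: float
    l2: float
    nfi: float | None
    replicated: bool
    boundary_flag: bool
    converged: bool

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "npar": self.npar,
            "loglik": self.loglik,
            "bic": self.bic,
            "aic": self.aic,
            "classification_error": self.classification_error,
            "dissimilarity": self.dissimilarity,
            "l2": self.l2,
            "nfi": self.nfi,
            "replicated": self.replicated,
            "boundary_flag": self.boundary_flag,
            "converged": self.converged,
        }


def compute_fit_statistics(
    results: LatentClassResults,
    n_obs: int | None = None,
    l2_baseline: float | None = None,
) -> FitStatistics:
    """Assemble the panel row for one fitted model.

    ``n_obs`` defaults to the raw person count behind the pattern table;
    ``l2_baseline`` (the one-class L2) enables the NFI column.
    """
    from .classify import classification_error as _ce

    pt = results.model.pattern_table
    n_obs = pt.n_raw if n_obs is None else n_obs
    k, j = results.n_classes, pt.n_items
    npar = count_parameters(k, j)
    tau, _ = e_step(results.params, pt)
    l2 = l2_statistic(results.params, pt)
    return FitStatistics(
        n_classes=k,
        npar=npar,
        loglik=results.loglik,
        bic=bic(results.loglik, npar, n_obs),
        aic=aic(results.loglik, npar),
        classification_error=_ce(tau, pt.counts),
        dissimilarity=dissimilarity_index(results.params, pt),
        l2=l2,
        nfi=None if l2_baseline is None else normed_fit_index(l2, l2_baseline),
        replicated=results.replicated,
        boundary_flag=results.boundary_flag,
        converged=results.converged,
    )


@dataclass
class SweepResult:
    """Fit-statistics panel for K = 1..K_max plus the heuristic choice."""

    statistics: list[FitStatistics]
    fits: list[LatentClassResults | None]
    selected_k: int
    rationale: str
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.statistics])


def sweep_models(
    data,
    k_max: int,
    id_threshold: float = 0.05,
    nfi_threshold: float = 0.80,
    n_obs: int | None = None,
    **fit_kwargs,
) -> SweepResult:
    """Fit models for K = 1..k_max and apply the selection heuristic.

    Selection: the smallest K with I_d <= ``id_threshold``, NFI >=
    ``nfi_threshold`` and a replicated log-likelihood; when no K qualifies,
    fall back to the BIC minimum.  Identifiability problems (more classes
    than distinct patterns) are recorded as flags, not raised.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    seed = fit_kwargs.pop("seed", None)
    stats: list[FitStatistics] = []
    fits: list[LatentClassResults | None] = []
    flags: dict = {}
    l2_baseline = None
    for k in range(1, k_max + 1):
        try:
            model = LatentClassModel(data, n_classes=k)
        except ValueError as exc:
            flags[k] = str(exc)
            fits.append(None)
            continue
        res = model.fit(seed=None if seed is None else seed + k, **fit_kwargs)
        row = compute_fit_statistics(res, n_obs=n_obs, l2_baseline=l2_baseline)
        if k == 1:
            l2_baseline = row.l2
            row.nfi = 0.0 if l2_baseline > 0 else None
        stats.append(row)
        fits.append(res)

    # NFI is relative to the one-class baseline, so it cannot certify the
    # baseline itself; K = 1 qualifies on the dissimilarity criterion alone.
    adequate = [
        s
        for s in stats
        if s.dissimilarity <= id_threshold
        and s.replicated
        and (s.n_classes == 1 or (s.nfi is not None and s.nfi >= nfi_threshold))
    ]
    if adequate:
        selected = min(a.n_classes for a in adequate)
        rationale = (
            f"smallest K with dissimilarity <= {id_threshold}, "
            f"NFI >= {nfi_threshold} and a replicated log-likelihood"
        )
    elif stats:
        selected = min(stats, key=lambda s: s.bic).n_classes
        rationale = "no K met the adequacy thresholds; BIC minimum reported"
    else:
        raise ValueError("no model could be fitted")
    return SweepResult(
        statistics=stats, fits=fits, selected_k=selected, rationale=rationale, flags=flags
    )
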