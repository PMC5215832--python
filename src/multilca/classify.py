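"""Posterior classification and the classification-error machinery that
feeds the bias-adjusted three-step analyses.

Modal assignment puts each person in the class with the largest posterior
membership probability.  Because assignment is probabilistic, a share of
persons land in the wrong class; the expected share is the classification
error E = 1 - weighted mean of the maximum posterior.  The K x K
classification-error matrix D, with D[t, s] = P(assigned s | true t)
estimated by posterior-weighted cross-tabulation, is the correction kernel
used by the ML and BCH three-step estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Assignment", "modal_assign", "classification_error", "error_matrix"]


@dataclass
class Assignment:
    """Modal class per person (1-based) and the winning posterior."""

    modal_class: np.ndarray
    max_posterior: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.modal_class.max())


def _check_tau(tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2:
        raise ValueError("posterior matrix must be 2-D")
    if np.any(tau < 0) or not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must be probabilities summing to 1")
    return tau


def modal_assign(tau: np.ndarray) -> Assignment:
    """Assign each row to its highest-posterior class; ties go to the
    lowest class index (argmax convention, documented and deterministic)."""
    tau = _check_tau(tau)
    idx = np.argmax(tau, axis=1)
    return Assignment(modal_class=idx + 1, max_posterior=tau[np.arange(len(tau)), idx])


def classification_error(tau: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Expected modal misclassification rate E = 1 - weighted mean max-posterior."""
    tau = _check_tau(tau)
    w = np.ones(len(tau)) if weights is None else np.asarray(weights, dtype=float)
    top = tau.max(axis=1)
    return float(1.0 - (w * top).sum() / w.sum())


def error_matrix(
    tau: np.ndarray,
    assignment: Assignment,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate D[t, s] = P(W = s | X = t) by posterior-weighted
    cross-tabulation of true class t against assigned class s:

        D[t, s] = sum_i w_i tau_it 1{W_i = s} / sum_i w_i tau_it

    Rows index the latent (true) class, columns the assigned class; each
    row sums to 1.
    """
    tau = _check_tau(tau)
    n, k = tau.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wv = w[:, None] * tau  # (N, K) posterior-weighted mass per true class
    mass = wv.sum(axis=0)
    if np.any(mass <= 0):
        empty = np.flatnonzero(mass <= 0) + 1
        raise ValueError(f"class(es) {empty.tolist()} carry zero posterior mass")
    d = np.zeros((k, k))
    for s in range(k):
        d[:, s] = wv[assignment.modal_class == s + 1].sum(axis=0)
    return d / mass[:, None]
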