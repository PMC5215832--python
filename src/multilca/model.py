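"""Bernoulli-mixture latent class model estimated by EM.

The measurement model assumes an unobserved class variable X with K
categories; given X = k, the J binary indicators are independent Bernoulli
variables with class-specific probabilities rho_kj ("item-response
probabilities").  The marginal probability of a response pattern y is

    P(y) = sum_k pi_k * prod_j rho_kj**y_j * (1 - rho_kj)**(1 - y_j)

with class proportions pi.  Estimation maximizes the (pseudo-)log-likelihood
sum_s c_s log P(y_s) over the distinct observed patterns, where c_s is the
(weighted) pattern count, by expectation-maximization with many random
starts.  A solution is only trusted when the best log-likelihood is
replicated by several independent starts; otherwise the fit is flagged.

`LatentClassModel` / `LatentClassResults` follow the familiar model/results
split: construct the model from data, call ``fit``, and interrogate the
results object (parameters, posteriors, diagnostics, ``summary()``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IndicatorDataset, PatternTable, compress_patterns

__all__ = [
    "LCAParams",
    "LatentClassModel",
    "LatentClassResults",
    "mixture_pattern_probability",
    "log_likelihood",
    "e_step",
    "m_step",
    "canonicalize_params",
]

_RHO_CLAMP = 1e-6


@dataclass
class LCAParams:
    """Parameters of a K-class Bernoulli mixture.

    class_proportions : (K,) probabilities summing to 1.
    item_probs        : (K, J) class-conditional indicator probabilities.
    """

    class_proportions: np.ndarray
    item_probs: np.ndarray

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.item_probs = np.atleast_2d(np.asarray(self.item_probs, dtype=float))
        k = self.class_proportions.shape[0]
        if self.item_probs.shape[0] != k:
            raise ValueError("item_probs must have one row per class")
        if np.any(self.class_proportions < 0) or not np.isclose(
            self.class_proportions.sum(), 1.0
        ):
            raise ValueError("class proportions must be nonnegative and sum to 1")
        if np.any(self.item_probs < 0) or np.any(self.item_probs > 1):
            raise ValueError("item probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.class_proportions.shape[0]

    @property
    def n_items(self) -> int:
        return self.item_probs.shape[1]

    def to_dict(self) -> dict:
        return {
            "class_proportions": self.class_proportions.tolist(),
            "item_probs": self.item_probs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAParams":
        return cls(np.asarray(d["class_proportions"]), np.asarray(d["item_probs"]))


def _component_log_probs(params: LCAParams, patterns: np.ndarray) -> np.ndarray:
    """(S, K) matrix of log(pi_k) + log P(pattern_s | class k), in log space."""
    rho = np.clip(params.item_probs, _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    y = np.asarray(patterns, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    # log P(y|k) = y . log(rho/(1-rho)) + sum_j log(1-rho)
    logit = np.log(rho) - np.log1p(-rho)
    base = np.log1p(-rho).sum(axis=1)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.class_proportions)
    return y @ logit.T + base + logpi


def mixture_pattern_probability(params: LCAParams, pattern: np.ndarray) -> float:
    """Marginal probability of one response pattern under the mixture."""
    pattern = np.asarray(pattern)
    if pattern.shape[-1] != params.n_items:
        raise ValueError("pattern length must equal the number of items")
    from scipy.special import logsumexp

    return float(np.exp(logsumexp(_component_log_probs(params, pattern), axis=1)[0]))


def log_likelihood(params: LCAParams, pt: PatternTable) -> float:
    """Weighted log-likelihood over a pattern table; identical to the
    person-level sum because patterns collapse identical terms."""
    from scipy.special import logsumexp

    lp = logsumexp(_component_log_probs(params, pt.patterns), axis=1)
    return float(pt.counts @ lp)


def e_step(params: LCAParams, pt: PatternTable) -> tuple[np.ndarray, float]:
    """Posterior class memberships per pattern (Bayes rule) and the
    log-likelihood, both computed in log space."""
    from scipy.special import logsumexp

    lp = _component_log_probs(params, pt.patterns)
    norm = logsumexp(lp, axis=1, keepdims=True)
    tau = np.exp(lp - norm)
    return tau, float(pt.counts @ norm[:, 0])


def m_step(
    tau: np.ndarray, pt: PatternTable, clamp: float = _RHO_CLAMP
) -> tuple[LCAParams, bool]:
    """Weighted maximization step.

    pi_k  = sum_s c_s tau_sk / sum_s c_s
    rho_kj = sum_s c_s tau_sk y_sj / sum_s c_s tau_sk

    Item probabilities are clamped away from the 0/1 boundary; the returned
    flag records whether clamping occurred (a boundary solution is a symptom
    of weak identification).
    """
    c = pt.counts
    mass = c @ tau  # (K,)
    if np.any(mass <= 0):
        raise ValueError("a class received zero posterior mass (degenerate class)")
    pi = mass / c.sum()
    rho = (tau * c[:, None]).T @ pt.patterns / mass[:, None]
    hit = bool(np.any(rho < clamp) or np.any(rho > 1 - clamp))
    rho = np.clip(rho, clamp, 1 - clamp)
    return LCAParams(pi / pi.sum(), rho), hit


def canonicalize_params(
    params: LCAParams, tau: np.ndarray | None = None
) -> tuple[LCAParams, np.ndarray]:
    """Resolve label switching: order classes by descending proportion,
    breaking ties lexicographically on the item-probability row.  Returns
    the reordered parameters and the permutation applied."""
    keys = [tuple(row) for row in params.item_probs]
    order = sorted(
        range(params.n_classes),
        key=lambda k: (-params.class_proportions[k], keys[k]),
    )
    order = np.asarray(order)
    new = LCAParams(params.class_proportions[order], params.item_probs[order])
    return new, order


class LatentClassModel:
    """Latent class model for binary indicators.

    Parameters
    ----------
    data
        An :class:`IndicatorDataset`, a :class:`PatternTable`, a DataFrame
        or an (N, J) binary array.
    n_classes
        Number of latent classes K.
    use_weights
        Whether survey weights enter the pseudo-likelihood (normalized to
        mean 1 internally).  Ignored when `data` is already a PatternTable.
    """

    def __init__(self, data, n_classes: int, use_weights: bool = True):
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.n_classes = int(n_classes)
        if isinstance(data, PatternTable):
            self.pattern_table = data
        else:
            if isinstance(data, pd.DataFrame):
                data = IndicatorDataset(
                    data.to_numpy(dtype=float), item_names=list(data.columns)
                )
            elif isinstance(data, np.ndarray):
                data = IndicatorDataset(data)
            if use_weights:
                norm = IndicatorDataset(
                    data.indicators,
                    data.normalized_weights(),
                    item_names=list(data.item_names),
                )
                self.pattern_table = compress_patterns(norm)
            else:
                self.pattern_table = compress_patterns(data, use_weights=False)
        if self.n_classes > self.pattern_table.n_patterns:
            raise ValueError(
                f"cannot identify {self.n_classes} classes from "
                f"{self.pattern_table.n_patterns} distinct patterns"
            )

    def _one_class_fit(self) -> LCAParams:
        pt = self.pattern_table
        rho = (pt.counts @ pt.patterns) / pt.total_weight
        return LCAParams(np.ones(1), np.clip(rho[None, :], _RHO_CLAMP, 1 - _RHO_CLAMP))

    def _random_start(self, rng: np.random.Generator) -> LCAParams:
        k, j = self.n_classes, self.pattern_table.n_items
        rho = rng.uniform(0.05, 0.95, size=(k, j))
        pi = rng.dirichlet(np.ones(k))
        return LCAParams(pi, rho)

    def _run_em(
        self, params: LCAParams, tol: float, max_iter: int
    ) -> tuple[LCAParams, float, int, bool, bool]:
        pt = self.pattern_table
        ll_prev = -np.inf
        boundary = False
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            tau, ll = e_step(params, pt)
            params, hit = m_step(tau, pt)
            boundary = boundary or hit
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
                converged = True
                break
            ll_prev = ll
        _, ll = e_step(params, pt)
        return params, ll, n_iter, converged, boundary

    def fit(
        self,
        n_starts: int = 500,
        tol: float = 1e-8,
        max_iter: int = 1000,
        replication_tol: float = 0.01,
        min_replications: int = 5,
        seed: int | None = None,
        max_start_doublings: int = 2,
    ) -> "LatentClassResults":
        """Estimate by EM over random restarts.

        Each start draws item probabilities Uniform(0.05, 0.95) and class
        proportions from a flat Dirichlet, using an independent substream of
        the master seed (so enlarging ``n_starts`` never perturbs earlier
        starts).  If fewer than ``min_replications`` starts reach the best
        log-likelihood within ``replication_tol``, the number of starts is
        doubled (at most ``max_start_doublings`` times); a fit that still
        fails the replication check is returned flagged, not raised.
        """
        if self.n_classes == 1:
            params = self._one_class_fit()
            ll = log_likelihood(params, self.pattern_table)
            return LatentClassResults(
                model=self,
                params=params,
                loglik=ll,
                n_iterations=0,
                converged=True,
                n_starts_used=1,
                ll_replications=1,
                replicated=True,
                boundary_flag=False,
                seed=seed,
                options={"n_starts": n_starts, "tol": tol, "max_iter": max_iter},
            )

        sseq = np.random.SeedSequence(seed)
        results: list[tuple[float, LCAParams, int, bool, bool]] = []

        def run_start(idx: int) -> None:
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence(entropy=sseq.entropy, spawn_key=(idx,)))
            )
            start = self._random_start(rng)
            try:
                p, ll, it, conv, bnd = self._run_em(start, tol, max_iter)
            except ValueError:
                return  # degenerate start; simply not counted
            results.append((ll, p, it, conv, bnd))

        total = n_starts
        for idx in range(total):
            run_start(idx)
        doublings = 0
        while True:
            if not results:
                raise RuntimeError("all EM starts degenerated")
            best_ll = max(r[0] for r in results)
            n_rep = sum(1 for r in results if best_ll - r[0] <= replication_tol)
            if n_rep >= min_replications or doublings >= max_start_doublings:
                break
            for idx in range(total, 2 * total):
                run_start(idx)
            total *= 2
            doublings += 1

        ll, params, n_iter, converged, boundary = max(results, key=lambda r: r[0])
        # polish the winner to a tighter tolerance
        params, ll, extra_it, converged, bnd2 = self._run_em(
            params, tol * 1e-2, max_iter
        )
        params, _ = canonicalize_params(params)
        return LatentClassResults(
            model=self,
            params=params,
            loglik=ll,
            n_iterations=n_iter + extra_it,
            converged=converged,
            n_starts_used=total,
            ll_replications=n_rep,
            replicated=n_rep >= min_replications,
            boundary_flag=boundary or bnd2,
            seed=seed,
            options={
                "n_starts": n_starts,
                "tol": tol,
                "max_iter": max_iter,
                "replication_tol": replication_tol,
                "min_replications": min_replications,
            },
        )


@dataclass
class LatentClassResults:
    """Fitted latent class model: canonical parameters plus diagnostics."""

    model: LatentClassModel
    params: LCAParams
    loglik: float
    n_iterations: int
    converged: bool
    n_starts_used: int
    ll_replications: int
    replicated: bool
    boundary_flag: bool
    seed: int | None
    options: dict = field(default_factory=dict)

    @property
    def llf(self) -> float:
        return self.loglik

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    def posterior_patterns(self) -> np.ndarray:
        """(S, K) posterior memberships for the distinct patterns."""
        tau, _ = e_step(self.params, self.model.pattern_table)
        return tau

    def predict_posterior(self, indicators: np.ndarray) -> np.ndarray:
        """(N, K) posterior memberships for arbitrary binary rows."""
        from scipy.special import logsumexp

        lp = _component_log_probs(self.params, np.asarray(indicators, dtype=float))
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def predict_pattern_probability(self, patterns: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        return np.exp(logsumexp(_component_log_probs(self.params, patterns), axis=1))

    def summary(self) -> pd.DataFrame:
        """Class proportions and item-response probabilities as a table
        (items in rows, classes in columns, proportions in the first row)."""
        names = self.model.pattern_table.item_names or [
            f"item_{j + 1}" for j in range(self.params.n_items)
        ]
        cols = [f"class_{k + 1}" for k in range(self.n_classes)]
        body = pd.DataFrame(self.params.item_probs.T, index=names, columns=cols)
        head = pd.DataFrame(
            [self.params.class_proportions], index=["class_proportion"], columns=cols
        )
        return pd.concat([head, body])

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "ll_replications": self.ll_replications,
            "replicated": self.replicated,
            "boundary_flag": self.boundary_flag,
            "seed": self.seed,
            "options": self.options,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source, model: LatentClassModel | None = None) -> "LatentClassResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            model=model,
            params=LCAParams.from_dict(payload["params"]),
            loglik=payload["loglik"],
            n_iterations=payload["n_iterations"],
            converged=payload["converged"],
            n_starts_used=payload["n_starts_used"],
            ll_replications=payload["ll_replications"],
            replicated=payload["replicated"],
            boundary_flag=payload["boundary_flag"],
            seed=payload["seed"],
            options=payload.get("options", {}),
        )
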