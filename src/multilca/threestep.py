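"""Bias-adjusted three-step analyses of latent class membership.

After a latent class model is fitted (step 1) and persons are modally
assigned (step 2), relating the assigned class W to external variables
naively ignores that W misclassifies a known share of people, which
attenuates associations.  Both estimators here correct for that using the
classification-error matrix D with D[t, s] = P(W = s | X = t):

* **ML correction** (covariates): the assigned class is treated as an
  indicator of the true class with known error rates, and the multinomial
  logistic regression of X on covariates z is estimated by maximizing

      sum_i w_i log sum_t P(X = t | z_i; beta) * D[t, W_i].

  With D = I this is exactly the ordinary multinomial logit on W.

* **BCH correction** (continuous distal outcomes): each person contributes
  to every class with signed weights u_i = e_{W_i}' D^{-1}; the weighted
  outcome means per class are then unbiased for the true class-specific
  means.  Standard errors come from a nonparametric bootstrap.

Equality of class-specific outcome means is tested with a Wald chi-square
on K-1 contrasts (BCH path) and, alongside, a classic one-way ANOVA F-test
on the modal groups (naive path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .classify import Assignment

__all__ = [
    "CovariateModel",
    "DistalProfileEntry",
    "DistalProfile",
    "fit_covariates_ml",
    "bch_distal_means",
    "anova_equality_test",
]


class SeparationError(RuntimeError):
    """Raised when a covariate perfectly separates classes (unbounded beta)."""


# ---------------------------------------------------------------------------
# ML-corrected multinomial logistic regression of class membership
# ---------------------------------------------------------------------------


@dataclass
class CovariateModel:
    """Results of the ML-corrected step-3 multinomial logit.

    Coefficients are (K-1) x P against the reference class; odds ratios are
    exp(beta) with Wald 95% CIs; the per-covariate Wald statistic tests the
    covariate's K-1 coefficients jointly against zero.
    """

    coefficients: np.ndarray  # (K-1, P)
    standard_errors: np.ndarray
    cov_params: np.ndarray  # ((K-1)*P, (K-1)*P), row-major over classes
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    wald_statistics: dict
    wald_pvalues: dict
    ref_class: int
    class_indices: list
    covariate_names: list
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for e, t in enumerate(self.class_indices):
            for p, name in enumerate(self.covariate_names):
                rows.append(
                    {
                        "class": t,
                        "covariate": name,
                        "coef": self.coefficients[e, p],
                        "se": self.standard_errors[e, p],
                        "odds_ratio": self.odds_ratios[e, p],
                        "ci_lower": self.ci_lower[e, p],
                        "ci_upper": self.ci_upper[e, p],
                        "wald_p": self.wald_pvalues.get(name),
                    }
                )
        return pd.DataFrame(rows)

    def odds_ratio(self, class_index: int, covariate: str) -> float:
        e = self.class_indices.index(class_index)
        p = self.covariate_names.index(covariate)
        return float(self.odds_ratios[e, p])


def _design_matrix(covariates, add_intercept: bool) -> tuple[np.ndarray, list]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        z = covariates.to_numpy(dtype=float)
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        names = [f"x{p + 1}" for p in range(z.shape[1])]
    if add_intercept:
        z = np.column_stack([np.ones(len(z)), z])
        names = ["intercept"] + names
    return z, names


def _ml_nll_grad(
    beta_flat: np.ndarray,
    z: np.ndarray,
    d_obs: np.ndarray,
    w: np.ndarray,
    k: int,
    ref0: int,
) -> tuple[float, np.ndarray]:
    n, p = z.shape
    beta = beta_flat.reshape(k - 1, p)
    eta = np.zeros((n, k))
    free = [t for t in range(k) if t != ref0]
    eta[:, free] = z @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    prob = expeta / expeta.sum(axis=1, keepdims=True)
    lik = np.einsum("nk,nk->n", prob, d_obs)
    lik = np.maximum(lik, 1e-300)
    nll = -float(w @ np.log(lik))
    # d log L_i / d eta_t = p_t d_t / L_i - p_t
    g_eta = prob * d_obs / lik[:, None] - prob
    grad = -(z.T @ (w[:, None] * g_eta[:, free])).T  # (K-1, P)
    return nll, grad.ravel()


def fit_covariates_ml(
    assignment: Assignment,
    error_mat: np.ndarray,
    covariates,
    ref_class: int = 1,
    weights: np.ndarray | None = None,
    add_intercept: bool = True,
    max_iter: int = 500,
    separation_bound: float = 15.0,
) -> CovariateModel:
    """Fit the ML-corrected multinomial logit of latent class on covariates.

    Parameters
    ----------
    assignment
        Modal assignments from step 2 (classes 1..K).
    error_mat
        K x K classification-error matrix D (rows: true class; columns:
        assigned class).  Pass the identity to recover the ordinary
        multinomial logit on the modal classes.
    covariates
        DataFrame or array of person-level covariates; an intercept column
        is added unless ``add_intercept=False``.
    ref_class
        1-based reference class (implied odds ratio 1).
    """
    d = np.asarray(error_mat, dtype=float)
    k = d.shape[0]
    if d.shape != (k, k) or not np.allclose(d.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("error matrix must be square and row-stochastic")
    if not 1 <= ref_class <= k:
        raise ValueError("ref_class out of range")
    z, names = _design_matrix(covariates, add_intercept)
    n, p = z.shape
    w_assigned = np.asarray(assignment.modal_class, dtype=int)
    if len(w_assigned) != n:
        raise ValueError("assignment and covariates must align")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.mean()
    d_obs = d[:, w_assigned - 1].T  # (N, K): D[t, W_i] for every t
    ref0 = ref_class - 1

    x0 = np.zeros((k - 1) * p)
    res = optimize.minimize(
        _ml_nll_grad,
        x0,
        args=(z, d_obs, w, k, ref0),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x.reshape(k - 1, p)
    if np.any(np.abs(beta) > separation_bound):
        raise SeparationError(
            "coefficient magnitude exceeds the separation bound; a covariate "
            "may perfectly predict class membership"
        )

    # observed-information covariance via central differences of the gradient
    m = (k - 1) * p
    h = 1e-5 * np.maximum(1.0, np.abs(res.x))
    hess = np.empty((m, m))
    for a in range(m):
        xp = res.x.copy()
        xm = res.x.copy()
        xp[a] += h[a]
        xm[a] -= h[a]
        _, gp = _ml_nll_grad(xp, z, d_obs, w, k, ref0)
        _, gm = _ml_nll_grad(xm, z, d_obs, w, k, ref0)
        hess[a] = (gp - gm) / (2 * h[a])
    hess = 0.5 * (hess + hess.T)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(k - 1, p)

    zcrit = 1.96
    or_ = np.exp(beta)
    ci_lo = np.exp(beta - zcrit * se)
    ci_hi = np.exp(beta + zcrit * se)

    free_classes = [t + 1 for t in range(k) if t != ref0]
    wald_stats: dict = {}
    wald_p: dict = {}
    for pi, name in enumerate(names):
        idx = [e * p + pi for e in range(k - 1)]
        b = res.x[idx]
        v = cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.pinv(v) @ b)
        wald_stats[name] = stat
        wald_p[name] = float(stats.chi2.sf(stat, df=k - 1))

    return CovariateModel(
        coefficients=beta,
        standard_errors=se,
        cov_params=cov,
        odds_ratios=or_,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        wald_statistics=wald_stats,
        wald_pvalues=wald_p,
        ref_class=ref_class,
        class_indices=free_classes,
        covariate_names=names,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# BCH-corrected distal outcome means
# ---------------------------------------------------------------------------


@dataclass
class DistalProfileEntry:
    """Class-specific means of one continuous outcome with SEs, the mean
    covariance (bootstrap for BCH), and equality-test results."""

    outcome: str
    means: np.ndarray  # (K,)
    standard_errors: np.ndarray
    cov_means: np.ndarray  # (K, K)
    naive_means: np.ndarray
    wald_statistic: float
    wald_df: int
    wald_pvalue: float
    anova_f: float
    anova_pvalue: float
    method: str  # "bch" or "naive-fallback"
    n_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            **{f"class_{t + 1}_mean": float(m) for t, m in enumerate(self.means)},
            "wald_statistic": self.wald_statistic,
            "wald_pvalue": self.wald_pvalue,
            "anova_f": self.anova_f,
            "anova_pvalue": self.anova_pvalue,
            "method": self.method,
        }


@dataclass
class DistalProfile:
    """Distal-outcome profile across several scales."""

    entries: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.entries])

    def mean_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            {e.outcome: e.means for e in self.entries}
        ).T.rename(columns=lambda c: f"class_{c + 1}")


def _bch_class_means(
    u: np.ndarray, y: np.ndarray, w: np.ndarray
) -> np.ndarray:
    num = (w[:, None] * u * y[:, None]).sum(axis=0)
    den = (w[:, None] * u).sum(axis=0)
    return num / den


def _weighted_group_means(
    labels: np.ndarray, y: np.ndarray, w: np.ndarray, k: int
) -> np.ndarray:
    out = np.empty(k)
    for t in range(k):
        sel = labels == t + 1
        out[t] = (w[sel] * y[sel]).sum() / w[sel].sum() if sel.any() else np.nan
    return out


def bch_distal_means(
    assignment: Assignment,
    error_mat: np.ndarray,
    outcome: np.ndarray | pd.Series,
    weights: np.ndarray | None = None,
    outcome_name: str = "outcome",
    n_boot: int = 200,
    seed: int | None = None,
    cond_threshold: float = 1e8,
) -> DistalProfileEntry:
    """BCH-corrected class-specific means of a continuous distal outcome.

    Each person gets the signed class weights u_i = e_{W_i}' D^{-1}; the
    class-t mean is the u-weighted outcome average.  SEs and the covariance
    of the K means come from a nonparametric bootstrap over persons
    (``n_boot`` resamples).  If D is ill-conditioned the naive modal means
    are returned instead, flagged via ``method='naive-fallback'``.
    """
    d = np.asarray(error_mat, dtype=float)
    k = d.shape[0]
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    labels = np.asarray(assignment.modal_class, dtype=int)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    naive = _weighted_group_means(labels, y, w, k)

    fallback = np.linalg.cond(d) > cond_threshold
    if fallback:
        warnings.warn(
            "classification-error matrix is ill-conditioned; falling back to "
            "naive modal means",
            RuntimeWarning,
        )
        u = np.eye(k)[labels - 1]
        means = naive.copy()
    else:
        dinv = np.linalg.inv(d)
        u = dinv[labels - 1]  # row selected by assigned class
        means = _bch_class_means(u, y, w)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _bch_class_means(u[idx], y[idx], w[idx])
    se = boots.std(axis=0, ddof=1)
    cov = np.cov(boots.T) if n_boot > 1 else np.zeros((k, k))

    wald, df, wald_p = _wald_equality(means, cov, k)
    f_stat, f_p = _naive_anova(labels, y, w, k)

    return DistalProfileEntry(
        outcome=outcome_name,
        means=means,
        standard_errors=se,
        cov_means=cov,
        naive_means=naive,
        wald_statistic=wald,
        wald_df=df,
        wald_pvalue=wald_p,
        anova_f=f_stat,
        anova_pvalue=f_p,
        method="naive-fallback" if fallback else "bch",
        n_boot=n_boot,
    )


def _wald_equality(means: np.ndarray, cov: np.ndarray, k: int) -> tuple[float, int, float]:
    if k < 2:
        raise ValueError("equality test requires at least two classes")
    c = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])  # contrasts vs class 1
    diff = c @ means
    v = c @ cov @ c.T
    if np.allclose(diff, 0.0):
        return 0.0, k - 1, 1.0
    if np.linalg.matrix_rank(v) < k - 1:
        raise ValueError("singular contrast covariance in equality test")
    stat = float(diff @ np.linalg.solve(v, diff))
    return stat, k - 1, float(stats.chi2.sf(stat, df=k - 1))


def _naive_anova(
    labels: np.ndarray, y: np.ndarray, w: np.ndarray, k: int
) -> tuple[float, float]:
    """Weighted one-way ANOVA F on the modal groups."""
    grand = (w * y).sum() / w.sum()
    ss_between = 0.0
    ss_within = 0.0
    groups = 0
    for t in range(k):
        sel = labels == t + 1
        if not sel.any():
            continue
        groups += 1
        wt = w[sel]
        mt = (wt * y[sel]).sum() / wt.sum()
        ss_between += wt.sum() * (mt - grand) ** 2
        ss_within += (wt * (y[sel] - mt) ** 2).sum()
    df1 = groups - 1
    df2 = w.sum() - groups
    if df1 < 1 or ss_within <= 0:
        return 0.0, 1.0
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def anova_equality_test(entry: DistalProfileEntry) -> dict:
    """Equality-of-means tests for one outcome: the Wald chi-square on the
    BCH-corrected means and the classic one-way F on modal groups."""
    wald, df, p = _wald_equality(entry.means, entry.cov_means, len(entry.means))
    return {
        "wald_statistic": wald,
        "wald_df": df,
        "wald_pvalue": p,
        "anova_f": entry.anova_f,
        "anova_pvalue": entry.anova_pvalue,
    }
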