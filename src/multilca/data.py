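"""Person-level indicator data: loading, validation, missingness handling,
pattern compression, and simple morbidity summaries.

The central object is :class:`IndicatorDataset`, a person-level table of
binary chronic-condition indicators with optional survey weights, covariate
columns and continuous outcome columns.  Estimation works on the compressed
:class:`PatternTable` of distinct response patterns, which makes the exact
likelihood cheap even for very large samples (with J items at most 2**J
patterns can occur, and in sparse epidemiological tables far fewer do).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorDataset",
    "PatternTable",
    "PersonSummary",
    "load_indicator_table",
    "apply_missingness_rule",
    "compress_patterns",
    "summarize_persons",
]


@dataclass
class IndicatorDataset:
    """Person-level binary indicators plus optional weights/covariates/outcomes.

    Parameters
    ----------
    indicators
        N x J array of values in {0, 1, NaN}; NaN marks a missing answer.
    weights
        Length-N positive survey weights; defaults to all ones.
    covariates
        Optional DataFrame of covariate columns aligned with persons.
    outcomes
        Optional DataFrame of continuous outcome columns aligned with persons.
    item_names
        Names of the J indicator columns.
    """

    indicators: np.ndarray
    weights: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    outcomes: pd.DataFrame | None = None
    item_names: list[str] | None = None
    person_index: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=float)
        if self.indicators.ndim != 2:
            raise ValueError("indicators must be a 2-D array")
        n, j = self.indicators.shape
        if n < 1:
            raise ValueError("need at least one person")
        if j < 2:
            raise ValueError("need at least two indicator items")
        valid = np.isnan(self.indicators) | np.isin(self.indicators, (0.0, 1.0))
        if not valid.all():
            bad = np.unique(self.indicators[~valid])
            raise ValueError(f"indicator values must be 0, 1 or missing; found {bad}")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights must be length N")
            if not np.all(self.weights > 0):
                raise ValueError("weights must be strictly positive")
        if self.item_names is None:
            self.item_names = [f"item_{k + 1}" for k in range(j)]
        elif len(self.item_names) != j:
            raise ValueError("item_names must have one entry per indicator column")
        if self.person_index is None:
            self.person_index = np.arange(n)
        for df, what in ((self.covariates, "covariates"), (self.outcomes, "outcomes")):
            if df is not None and len(df) != n:
                raise ValueError(f"{what} must have one row per person")

    @property
    def n_persons(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_items(self) -> int:
        return self.indicators.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.indicators).any())

    def normalized_weights(self) -> np.ndarray:
        """Weights rescaled to mean 1 (used inside estimation for stability;
        reported prevalences always use the original weights)."""
        return self.weights / self.weights.mean()

    def summary_dict(self) -> dict:
        """JSON-ready summary: sizes, drop count, weighted item prevalences."""
        out = {
            "n_persons": int(self.n_persons),
            "n_items": int(self.n_items),
            "n_dropped": int(self.n_dropped),
            "total_weight": self.total_weight,
            "has_missing": self.has_missing,
        }
        if not self.has_missing:
            w = self.weights
            prev = (w[:, None] * self.indicators).sum(axis=0) / w.sum()
            out["weighted_prevalence"] = {
                name: float(p) for name, p in zip(self.item_names, prev)
            }
        return out


@dataclass
class PatternTable:
    """Distinct observed response patterns with weighted and raw counts."""

    patterns: np.ndarray  # S x J, int {0,1}
    counts: np.ndarray  # length S, summed weights
    raw_counts: np.ndarray  # length S, person counts
    total_weight: float
    n_raw: int
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=int)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D")
        s = self.patterns.shape[0]
        if self.counts.shape != (s,) or self.raw_counts.shape != (s,):
            raise ValueError("counts and raw_counts must align with patterns")
        if int(self.raw_counts.sum()) != self.n_raw:
            raise ValueError("raw_counts must sum to n_raw")
        if not np.isclose(self.counts.sum(), self.total_weight):
            raise ValueError("counts must sum to total_weight")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_items(self) -> int:
        return self.patterns.shape[1]

    def observed_proportions(self) -> np.ndarray:
        return self.counts / self.total_weight


@dataclass
class PersonSummary:
    """Per-person condition counts and multimorbidity flags plus weighted
    aggregates (multimorbidity = two or more chronic conditions)."""

    condition_count: np.ndarray
    multimorbid: np.ndarray
    multimorbidity_prevalence: float
    mean_condition_count: float


def _parse_schema(schema: Mapping | str) -> dict:
    if isinstance(schema, str):
        with open(schema) as fh:
            if schema.endswith((".yaml", ".yml")):
                import yaml

                schema = yaml.safe_load(fh)
            else:
                schema = json.load(fh)
    out = {
        "indicators": list(schema["indicators"]),
        "weight": schema.get("weight"),
        "covariates": list(schema.get("covariates") or []),
        "outcomes": list(schema.get("outcomes") or []),
    }
    if len(out["indicators"]) < 2:
        raise ValueError("schema must declare at least two indicator columns")
    return out


def load_indicator_table(path, schema: Mapping | str) -> IndicatorDataset:
    """Read a person-level CSV into an :class:`IndicatorDataset`.

    ``schema`` declares which columns are indicators, which column (if any)
    holds the survey weight, and which columns are covariates / continuous
    outcomes.  Indicator cells must be 0, 1 or blank; anything else is an
    error (fail-fast rather than silent coercion).
    """
    spec = _parse_schema(schema)
    df = pd.read_csv(path)
    declared = (
        spec["indicators"]
        + ([spec["weight"]] if spec["weight"] else [])
        + spec["covariates"]
        + spec["outcomes"]
    )
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns declared in schema but absent from CSV: {missing_cols}")

    sub = df[spec["indicators"]]
    blank = pd.isna(sub).to_numpy()
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    parsed = numeric.to_numpy(dtype=float)
    ok = blank | np.isin(parsed, (0.0, 1.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"non-binary indicator value {sub.iloc[r, c]!r} in column "
            f"{spec['indicators'][c]!r}, row {r}"
        )
    parsed[blank] = np.nan

    weights = None
    if spec["weight"]:
        weights = df[spec["weight"]].to_numpy(dtype=float)
        if np.isnan(weights).any() or (weights <= 0).any():
            raise ValueError("weights must be present and strictly positive")
    covariates = df[spec["covariates"]].copy() if spec["covariates"] else None
    outcomes = df[spec["outcomes"]].astype(float) if spec["outcomes"] else None
    return IndicatorDataset(
        indicators=parsed,
        weights=weights,
        covariates=covariates,
        outcomes=outcomes,
        item_names=spec["indicators"],
    )


def apply_missingness_rule(ds: IndicatorDataset) -> IndicatorDataset:
    """Resolve missing indicators: a skipped item counts as disconfirmed (0)
    for anyone who answered at least one item; persons with every item
    missing are dropped.  Idempotent; the number of dropped persons is
    recorded on the returned dataset."""
    miss = np.isnan(ds.indicators)
    keep = ~miss.all(axis=1)
    n_dropped = int((~keep).sum())
    ind = np.nan_to_num(ds.indicators[keep], nan=0.0)
    return IndicatorDataset(
        indicators=ind,
        weights=ds.weights[keep],
        covariates=None if ds.covariates is None else ds.covariates.loc[keep].reset_index(drop=True),
        outcomes=None if ds.outcomes is None else ds.outcomes.loc[keep].reset_index(drop=True),
        item_names=list(ds.item_names),
        person_index=ds.person_index[keep],
        n_dropped=ds.n_dropped + n_dropped,
    )


def compress_patterns(ds: IndicatorDataset, use_weights: bool = True) -> PatternTable:
    """Collapse persons onto distinct response patterns.

    The mixture log-likelihood computed on the returned table equals the
    person-level sum exactly, because persons sharing a pattern contribute
    identical per-person terms.
    """
    if ds.has_missing:
        raise ValueError("resolve missing indicators before compressing patterns")
    ind = ds.indicators.astype(int)
    patterns, inverse = np.unique(ind, axis=0, return_inverse=True)
    w = ds.weights if use_weights else np.ones(ds.n_persons)
    counts = np.bincount(inverse, weights=w, minlength=len(patterns))
    raw = np.bincount(inverse, minlength=len(patterns))
    return PatternTable(
        patterns=patterns,
        counts=counts,
        raw_counts=raw,
        total_weight=float(w.sum()),
        n_raw=ds.n_persons,
        item_names=list(ds.item_names),
    )


def summarize_persons(ds: IndicatorDataset) -> PersonSummary:
    """Condition counts, multimorbidity flags (count >= 2) and their
    weighted aggregates."""
    if ds.has_missing:
        raise ValueError("resolve missing indicators before summarizing")
    counts = ds.indicators.sum(axis=1).astype(int)
    multi = counts >= 2
    w = ds.weights
    return PersonSummary(
        condition_count=counts,
        multimorbid=multi,
        multimorbidity_prevalence=float((w * multi).sum() / w.sum()),
        mean_condition_count=float((w * counts).sum() / w.sum()),
    )
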