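"""End-to-end orchestration of the three analysis steps.

``run_pipeline`` takes a person-level CSV (or generates a synthetic
population), applies the missingness rule, sweeps latent class models,
fits the selected model, classifies persons, runs the bias-adjusted
three-step covariate and distal-outcome analyses, and writes a bundle of
report tables: descriptive prevalences, the fit-statistics panel, class
profiles, the odds-ratio table, the distal-outcome profile, and a JSON
manifest from which the run can be reproduced exactly.
"""

from __future__ import annotations

import json
import sys
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    IndicatorDataset,
    apply_missingness_rule,
    load_indicator_table,
    summarize_persons,
)
from .classify import classification_error, error_matrix, modal_assign
from .model import LatentClassModel
from .selection import sweep_models
from .simulate import default_config, simulate_population
from .threestep import bch_distal_means, fit_covariates_ml, DistalProfile

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run (serialized into the manifest)."""

    output_dir: str
    input_csv: str | None = None
    schema: dict | str | None = None
    synthetic_n: int | None = None
    k_max: int = 9
    fixed_k: int | None = None
    n_starts: int = 50
    tol: float = 1e-8
    max_iter: int = 1000
    seed: int = 0
    use_weights: bool = True
    ref_class: int = 1
    n_boot: int = 200
    covariate_columns: list = field(default_factory=list)
    outcome_columns: list = field(default_factory=list)
    make_plot: bool = True

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["multilca_version"] = __version__
        return d


def _log(msg: str) -> None:
    print(f"[multilca] {msg}", file=sys.stderr)


def _load_or_simulate(cfg: RunConfig) -> IndicatorDataset:
    if cfg.input_csv is not None:
        if cfg.schema is None:
            raise ValueError("a schema is required to read an input CSV")
        return load_indicator_table(cfg.input_csv, cfg.schema)
    n = cfg.synthetic_n or 50_000
    syn = default_config()
    ds, _ = simulate_population(syn, n=n, seed=cfg.seed)
    return ds


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of written file paths.

    Stage failures are reported with the stage name; tables written before
    the failure are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "load"
        ds = _load_or_simulate(cfg)
        _log(f"loaded {ds.n_persons} persons x {ds.n_items} items")

        stage = "prepare"
        ds = apply_missingness_rule(ds)
        summary = summarize_persons(ds)
        w = ds.weights
        prev = (w[:, None] * ds.indicators).sum(axis=0) / w.sum()
        desc = pd.DataFrame(
            {"item": ds.item_names, "weighted_prevalence": prev}
        )
        desc.loc[len(desc)] = ["multimorbidity_2plus", summary.multimorbidity_prevalence]
        desc.loc[len(desc)] = ["mean_condition_count", summary.mean_condition_count]
        path = out / "descriptives.csv"
        desc.to_csv(path, index=False)
        written["descriptives"] = str(path)

        stage = "sweep"
        if cfg.fixed_k is None:
            sweep = sweep_models(
                ds,
                k_max=cfg.k_max,
                n_starts=cfg.n_starts,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                seed=cfg.seed,
            )
            frame = sweep.to_frame()
            frame.attrs["selected_k"] = sweep.selected_k
            path = out / "sweep.csv"
            frame.to_csv(path, index=False)
            written["sweep"] = str(path)
            selected_k = sweep.selected_k
            res = sweep.fits[selected_k - 1]
            _log(f"selected K={selected_k}: {sweep.rationale}")
        else:
            selected_k = cfg.fixed_k
            res = LatentClassModel(ds, selected_k, use_weights=cfg.use_weights).fit(
                n_starts=cfg.n_starts,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                seed=cfg.seed,
            )

        stage = "classify"
        tau = res.predict_posterior(ds.indicators)
        assign = modal_assign(tau)
        err = classification_error(tau, ds.weights)
        d_mat = error_matrix(tau, assign, ds.weights)

        stage = "profiles"
        profile = res.summary()
        counts = ds.indicators.sum(axis=1)
        multi_pct = np.empty(selected_k)
        mean_count = np.empty(selected_k)
        for t in range(selected_k):
            sel = assign.modal_class == t + 1
            wt = ds.weights[sel]
            if wt.sum() > 0:
                multi_pct[t] = (wt * (counts[sel] >= 2)).sum() / wt.sum()
                mean_count[t] = (wt * counts[sel]).sum() / wt.sum()
            else:
                multi_pct[t] = np.nan
                mean_count[t] = np.nan
        profile.loc["multimorbidity_modal_pct"] = multi_pct
        profile.loc["mean_condition_count_modal"] = mean_count
        top_class = np.argmax(res.params.item_probs, axis=0) + 1
        profile["highest_probability_class"] = (
            [""] + [int(c) for c in top_class] + ["", ""]
        )
        path = out / "class_profiles.csv"
        profile.to_csv(path)
        written["class_profiles"] = str(path)

        stage = "threestep-covariates"
        cov_cols = cfg.covariate_columns or (
            list(ds.covariates.columns) if ds.covariates is not None else []
        )
        if cov_cols and ds.covariates is not None:
            cov_model = fit_covariates_ml(
                assign,
                d_mat,
                ds.covariates[cov_cols],
                ref_class=cfg.ref_class,
                weights=ds.weights if cfg.use_weights else None,
            )
            path = out / "odds_ratios.csv"
            cov_model.summary().to_csv(path, index=False)
            written["odds_ratios"] = str(path)

        stage = "threestep-distal"
        out_cols = cfg.outcome_columns or (
            list(ds.outcomes.columns) if ds.outcomes is not None else []
        )
        if out_cols and ds.outcomes is not None:
            entries = []
            for i, col in enumerate(out_cols):
                entries.append(
                    bch_distal_means(
                        assign,
                        d_mat,
                        ds.outcomes[col],
                        weights=ds.weights if cfg.use_weights else None,
                        outcome_name=col,
                        n_boot=cfg.n_boot,
                        seed=cfg.seed + 1000 + i,
                    )
                )
            dp = DistalProfile(entries)
            path = out / "distal_profiles.csv"
            dp.to_frame().to_csv(path, index=False)
            written["distal_profiles"] = str(path)
            if cfg.make_plot:
                written["distal_plot"] = _plot_profile(dp, out / "distal_profiles.png")

        stage = "manifest"
        manifest = cfg.to_manifest()
        manifest.update(
            {
                "n_persons": int(ds.n_persons),
                "n_dropped": int(ds.n_dropped),
                "selected_k": int(selected_k),
                "loglik": res.loglik,
                "classification_error": err,
                "replicated": res.replicated,
                "outputs": written,
            }
        )
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        written["manifest"] = str(path)
        return written
    except Exception as exc:
        _log(f"stage '{stage}' failed: {exc}")
        traceback.print_exc(file=sys.stderr)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _plot_profile(profile: DistalProfile, path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = profile.mean_matrix()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for cls in mat.columns:
        ax.plot(mat.index, mat[cls], marker="o", label=cls)
    ax.set_ylabel("class-specific mean")
    ax.set_xlabel("outcome scale")
    ax.tick_params(axis="x", rotation=45)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return str(path)
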