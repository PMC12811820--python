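"""Design-grid enumeration, LOO / out-of-bag evaluation and model ranking.

Accuracy metrics follow the reference definitions: the residual is
predicted age minus Age_best, the deviance its absolute value, the MAE
the median deviance, and all headline metrics are computed only over
high-confidence (CR 4-5) samples inside the training subset.  Metrics
are also broken out by Age_best bins 0-9, 10-24 and 25+ years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from epiage.clocks import (
    ClockConfig,
    TrainedClock,
    TuningSettings,
    train,
)
from epiage.site_selection import select_sites_enr, select_sites_rfr

AGE_BIN_EDGES = (0.0, 10.0, 25.0)
AGE_BIN_LABELS = ("0-9", "10-24", "25+")


def age_bin(age_best) -> np.ndarray:
    """Assign samples to Age_best bins 0-9 / 10-24 / 25+."""
    age_best = np.asarray(age_best, dtype=float)
    idx = np.digitize(age_best, AGE_BIN_EDGES[1:])
    return np.array(AGE_BIN_LABELS)[idx]


def subset_mask(cr: pd.Series, subset: str) -> pd.Series:
    if subset == "All":
        return pd.Series(True, index=cr.index)
    if subset == "CR3+":
        return cr >= 3
    if subset == "CR4+":
        return cr >= 4
    raise ValueError(f"unknown sample subset {subset!r}")


def cr_weights(cr: pd.Series) -> pd.Series:
    """Training weights: the raw CR integer of each sample."""
    return cr.astype(float)


@dataclass
class EvaluationMetrics:
    config: ClockConfig
    per_sample: pd.DataFrame  # sample_id, age_best, cr, predicted, residual, ...
    mae_overall: float
    mae_by_bin: dict
    mean_residual_by_bin: dict
    mean_residual_overall: float
    correlation: float
    n_eval: int
    extra: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        row = {
            "method": self.config.method,
            "training_samples": self.config.training_samples,
            "weighted": self.config.weighted,
            "age_transform": "log" if self.config.log_age else "none",
            "site_selection": self.config.site_selection,
            "site_selection_samples": self.config.site_selection_samples or "",
            "correlation": self.correlation,
            "mae_overall": self.mae_overall,
            "mean_residual_overall": self.mean_residual_overall,
            "n_eval": self.n_eval,
        }
        for label in AGE_BIN_LABELS:
            row[f"mae_{label}"] = self.mae_by_bin.get(label, np.nan)
            row[f"mean_residual_{label}"] = self.mean_residual_by_bin.get(
                label, np.nan
            )
        return row


def compute_metrics(
    config: ClockConfig, per_sample: pd.DataFrame
) -> EvaluationMetrics:
    """Summaries over the CR4+ evaluation rows of a per-sample table.

    ``per_sample`` needs columns sample_id, age_best, cr, predicted and
    a boolean ``evaluated`` marking rows entering the headline metrics.
    """
    per_sample = per_sample.copy()
    per_sample["residual"] = per_sample["predicted"] - per_sample["age_best"]
    per_sample["deviance"] = per_sample["residual"].abs()
    per_sample["age_bin"] = age_bin(per_sample["age_best"])
    ev = per_sample[per_sample["evaluated"]]
    if ev.empty:
        raise ValueError("no evaluation (CR4+) samples")
    mae_by_bin, resid_by_bin = {}, {}
    for label in AGE_BIN_LABELS:
        rows = ev[ev["age_bin"] == label]
        if len(rows):
            mae_by_bin[label] = float(rows["deviance"].median())
            resid_by_bin[label] = float(rows["residual"].mean())
    if ev["age_best"].nunique() > 1 and ev["predicted"].nunique() > 1:
        corr = float(stats.pearsonr(ev["age_best"], ev["predicted"])[0])
    else:
        corr = np.nan
    return EvaluationMetrics(
        config=config,
        per_sample=per_sample,
        mae_overall=float(ev["deviance"].median()),
        mae_by_bin=mae_by_bin,
        mean_residual_by_bin=resid_by_bin,
        mean_residual_overall=float(ev["residual"].mean()),
        correlation=corr,
        n_eval=len(ev),
    )


def enumerate_configs(grid_spec: dict | None = None) -> list[ClockConfig]:
    """Cartesian product of the design grid, in stable order.

    ``grid_spec`` keys (all optional): methods, transforms (bools),
    site_selections (list of (method, samples) with samples None for
    'all'), training_samples, weighted (bools), exclude (list of dicts
    matched against config fields).
    """
    grid_spec = grid_spec or {}
    methods = list(grid_spec.get("methods", ("ENR", "RFR", "SVM", "GAM")))
    transforms = list(grid_spec.get("transforms", (False, True)))
    default_sel = [("all", None)] + [
        (m, s) for m in ("ENR", "RFR") for s in ("All", "CR3+", "CR4+")
    ]
    site_selections = list(grid_spec.get("site_selections", default_sel))
    training = list(grid_spec.get("training_samples", ("All", "CR3+", "CR4+")))
    weighted = list(grid_spec.get("weighted", (False, True)))
    exclude = grid_spec.get("exclude", [])
    for axis, name in [
        (methods, "methods"),
        (transforms, "transforms"),
        (site_selections, "site_selections"),
        (training, "training_samples"),
        (weighted, "weighted"),
    ]:
        if not axis:
            raise ValueError(f"empty grid axis {name!r}")

    configs = []
    for method, transform, (sel, sel_samples), train_sub, w in itertools.product(
        methods, transforms, site_selections, training, weighted
    ):
        config = ClockConfig(
            method=method,
            log_age=bool(transform),
            site_selection=sel,
            site_selection_samples=sel_samples,
            training_samples=train_sub,
            weighted=bool(w),
        )
        if any(
            all(getattr(config, k) == v for k, v in rule.items())
            for rule in exclude
        ):
            continue
        configs.append(config)
    return configs


def _resolve_sites(
    config: ClockConfig,
    X: pd.DataFrame,
    ages: pd.Series,
    cr: pd.Series,
    settings: TuningSettings,
    seed,
    selection_reps: int,
    cache: dict | None = None,
) -> list:
    """Run (or fetch cached) site selection for a config."""
    if config.site_selection == "all":
        return list(X.columns)
    key = (config.site_selection, config.site_selection_samples, config.weighted)
    if cache is not None and key in cache:
        return cache[key]
    mask = subset_mask(cr, config.site_selection_samples)
    Xs, ys = X.loc[mask], ages.loc[mask]
    w = cr_weights(cr.loc[mask]).to_numpy() if config.weighted else None
    if config.site_selection == "ENR":
        res = select_sites_enr(
            Xs, ys, sample_weight=w, n_reps=selection_reps,
            settings=settings, seed=seed,
        )
    else:
        res = select_sites_rfr(
            Xs, ys, sample_weight=w, n_perm=selection_reps,
            settings=settings, seed=seed,
        )
    sites = res.selected or list(X.columns)  # fall back if nothing selected
    if cache is not None:
        cache[key] = sites
    return sites


def evaluate_loo(
    config: ClockConfig,
    X: pd.DataFrame,
    ages: pd.Series,
    cr: pd.Series,
    settings: TuningSettings | None = None,
    seed=None,
    sites=None,
    refit_counter: list | None = None,
) -> tuple[EvaluationMetrics, TrainedClock]:
    """Leave-one-out evaluation for non-RFR methods.

    Hyperparameters are tuned once on the full training subset, then each
    LOO fold refits coefficients with them held fixed.  Samples outside
    the training subset are predicted by the full-data fit and carried in
    the per-sample table with ``evaluated=False``.
    """
    if config.method == "RFR":
        raise ValueError("use evaluate_oob for RFR configs")
    settings = settings or TuningSettings()
    mask = subset_mask(cr, config.training_samples)
    train_ids = list(X.index[mask])
    if len(train_ids) < 3:
        raise ValueError(f"only {len(train_ids)} training samples; need >= 3")
    weights = cr_weights(cr) if config.weighted else None
    Xt = X.loc[train_ids]
    yt = ages.loc[train_ids]
    wt = weights.loc[train_ids].to_numpy() if weights is not None else None

    rng = np.random.default_rng(seed)
    clock = train(
        config, Xt, yt, sample_weight=wt, settings=settings,
        seed=int(rng.integers(0, 2**31 - 1)), sites=sites,
    )

    loo_pred = pd.Series(index=train_ids, dtype=float)
    for sid in train_ids:
        rest = [s for s in train_ids if s != sid]
        w_rest = (
            weights.loc[rest].to_numpy() if weights is not None else None
        )
        fold = clock.refit(
            X.loc[rest], ages.loc[rest], sample_weight=w_rest,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if refit_counter is not None:
            refit_counter.append(sid)
        loo_pred[sid] = fold.predict(X.loc[[sid]])[0]

    rows = pd.DataFrame(
        {
            "sample_id": train_ids,
            "age_best": ages.loc[train_ids].to_numpy(),
            "cr": cr.loc[train_ids].to_numpy(),
            "predicted": loo_pred.to_numpy(),
            "in_training": True,
        }
    )
    outside = [s for s in X.index if s not in set(train_ids)]
    if outside:
        rows = pd.concat(
            [
                rows,
                pd.DataFrame(
                    {
                        "sample_id": outside,
                        "age_best": ages.loc[outside].to_numpy(),
                        "cr": cr.loc[outside].to_numpy(),
                        "predicted": clock.predict(X.loc[outside]),
                        "in_training": False,
                    }
                ),
            ],
            ignore_index=True,
        )
    rows["evaluated"] = rows["in_training"] & (rows["cr"] >= 4)
    return compute_metrics(config, rows), clock


def evaluate_oob(
    config: ClockConfig,
    X: pd.DataFrame,
    ages: pd.Series,
    cr: pd.Series,
    settings: TuningSettings | None = None,
    seed=None,
    sites=None,
) -> tuple[EvaluationMetrics, TrainedClock]:
    """Out-of-bag evaluation for RFR configs from a single forest fit."""
    if config.method != "RFR":
        raise ValueError("evaluate_oob only applies to RFR configs")
    settings = settings or TuningSettings()
    mask = subset_mask(cr, config.training_samples)
    train_ids = list(X.index[mask])
    if len(train_ids) < 3:
        raise ValueError(f"only {len(train_ids)} training samples; need >= 3")
    weights = cr_weights(cr) if config.weighted else None
    wt = weights.loc[train_ids].to_numpy() if weights is not None else None
    rng = np.random.default_rng(seed)
    clock = train(
        config, X.loc[train_ids], ages.loc[train_ids], sample_weight=wt,
        settings=settings, seed=int(rng.integers(0, 2**31 - 1)), sites=sites,
    )
    oob = clock.backend.oob_prediction_
    if np.isnan(oob).any():
        raise RuntimeError(
            "some samples never out-of-bag; increase the number of trees"
        )
    if config.log_age:
        oob = np.exp(oob)
    oob = np.clip(oob, *clock.clamp)

    rows = pd.DataFrame(
        {
            "sample_id": train_ids,
            "age_best": ages.loc[train_ids].to_numpy(),
            "cr": cr.loc[train_ids].to_numpy(),
            "predicted": oob,
            "in_training": True,
        }
    )
    outside = [s for s in X.index if s not in set(train_ids)]
    if outside:
        rows = pd.concat(
            [
                rows,
                pd.DataFrame(
                    {
                        "sample_id": outside,
                        "age_best": ages.loc[outside].to_numpy(),
                        "cr": cr.loc[outside].to_numpy(),
                        "predicted": clock.predict(X.loc[outside]),
                        "in_training": False,
                    }
                ),
            ],
            ignore_index=True,
        )
    rows["evaluated"] = rows["in_training"] & (rows["cr"] >= 4)
    return compute_metrics(config, rows), clock


def evaluate_config(
    config: ClockConfig,
    X: pd.DataFrame,
    ages: pd.Series,
    cr: pd.Series,
    settings: TuningSettings | None = None,
    seed=None,
    selection_reps: int = 1000,
    selection_cache: dict | None = None,
) -> tuple[EvaluationMetrics, TrainedClock]:
    """Site selection plus the appropriate evaluation for one config."""
    settings = settings or TuningSettings()
    sites = _resolve_sites(
        config, X, ages, cr, settings, seed, selection_reps, selection_cache
    )
    if config.method == "RFR":
        metrics, clock = evaluate_oob(
            config, X, ages, cr, settings=settings, seed=seed, sites=sites
        )
    else:
        metrics, clock = evaluate_loo(
            config, X, ages, cr, settings=settings, seed=seed, sites=sites
        )
    metrics.extra["n_sites"] = len(sites)
    return metrics, clock


def rank_models(results: list[EvaluationMetrics]) -> pd.DataFrame:
    """Rank by overall MAE ascending, ties by correlation descending,
    then original config order."""
    if not results:
        raise ValueError("no results to rank")
    table = pd.DataFrame([r.summary_row() for r in results])
    table["config_order"] = np.arange(len(table))
    table = table.sort_values(
        by=["mae_overall", "correlation", "config_order"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.drop(columns="config_order")


def run_search(
    X: pd.DataFrame,
    ages: pd.Series,
    cr: pd.Series,
    grid_spec: dict | None = None,
    settings: TuningSettings | None = None,
    seed=None,
    selection_reps: int = 1000,
) -> tuple[pd.DataFrame, list[EvaluationMetrics]]:
    """Evaluate every config in the grid and return the ranked table."""
    settings = settings or TuningSettings()
    configs = enumerate_configs(grid_spec)
    cache: dict = {}
    results = []
    rng = np.random.default_rng(seed)
    for config in configs:
        metrics, _ = evaluate_config(
            config,
            X,
            ages,
            cr,
            settings=settings,
            seed=int(rng.integers(0, 2**31 - 1)),
            selection_reps=selection_reps,
            selection_cache=cache,
        )
        results.append(metrics)
    return rank_models(results), results
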