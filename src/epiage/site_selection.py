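"""Stepwise CpG-site selection before clock training.

Two procedures: elastic-net inclusion frequency over replicate
cross-validated fits, and random-forest permutation importance with a
response-permutation null for per-site p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from epiage.clocks import TuningSettings, _standardise, tune_enr_alpha
from epiage.forest import RandomForest


@dataclass
class SiteSelectionResult:
    method: str  # "ENR" or "RFR"
    scores: pd.Series  # inclusion frequency (ENR) or importance (RFR)
    pvalues: pd.Series | None
    selected: list
    threshold: float
    sample_subset: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"site_id": self.scores.index, "score": self.scores.values})
        if self.pvalues is not None:
            out["p_value"] = self.pvalues.values
        out["selected"] = out["site_id"].isin(self.selected)
        return out


def select_sites_enr(
    X: pd.DataFrame,
    y,
    sample_weight=None,
    n_reps: int = 1000,
    freq_threshold: float = 0.5,
    l1_ratio=None,
    settings: TuningSettings | None = None,
    seed=None,
) -> SiteSelectionResult:
    """Sites with nonzero elastic-net coefficients in >= ``freq_threshold``
    of ``n_reps`` replicate cross-validated fits.

    Each replicate redraws its CV folds; the penalty within a replicate
    is the fold-CV deviance minimiser.  The mixing parameter is tuned
    once on this data set unless ``l1_ratio`` is supplied.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0 <= freq_threshold <= 1:
        raise ValueError("freq_threshold must be in [0, 1]")
    settings = settings or TuningSettings()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if l1_ratio is None:
        l1_ratio = tune_enr_alpha(
            X.to_numpy(dtype=float),
            y,
            sample_weight,
            alpha_range=settings.enr_alpha_range,
            n_reps=settings.enr_tune_reps,
            settings=settings,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    Xs, _, _ = _standardise(X.to_numpy(dtype=float))
    counts = np.zeros(X.shape[1])
    for _ in range(n_reps):
        kf = KFold(
            n_splits=settings.cv_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        cv = ElasticNetCV(
            l1_ratio=l1_ratio,
            alphas=settings.enr_n_lambdas,
            cv=kf,
            max_iter=5_000,
        )
        cv.fit(Xs, y, sample_weight=sample_weight)
        counts += cv.coef_ != 0
    freq = pd.Series(counts / n_reps, index=X.columns, name="frequency")
    # a site that never entered any replicate model is never selected,
    # even at a vacuous threshold of zero
    selected = list(freq.index[(freq >= freq_threshold) & (freq > 0)])
    if not selected:
        warnings.warn("elastic-net selection returned no sites", stacklevel=2)
    return SiteSelectionResult(
        method="ENR",
        scores=freq,
        pvalues=None,
        selected=selected,
        threshold=freq_threshold,
    )


def select_sites_rfr(
    X: pd.DataFrame,
    y,
    sample_weight=None,
    n_perm: int = 1000,
    p_threshold: float = 0.05,
    settings: TuningSettings | None = None,
    seed=None,
) -> SiteSelectionResult:
    """Sites whose permutation importance beats a response-permutation null.

    A forest is fitted and per-site importance taken as the percent
    increase in out-of-bag MSE under within-tree permutation.  The null
    distribution per site comes from ``n_perm`` refits on permuted
    responses; p = (1 + #null >= observed) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    settings = settings or TuningSettings()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)

    def one_fit(response):
        forest = RandomForest(
            n_trees=settings.rf_n_trees,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(Xv, response, sample_weight=sample_weight)
        return forest.permutation_importance(rng=int(rng.integers(0, 2**31 - 1)))

    observed = one_fit(y)
    null = np.empty((n_perm, X.shape[1]))
    for i in range(n_perm):
        null[i] = one_fit(rng.permutation(y))
    pvals = (1 + (null >= observed).sum(axis=0)) / (n_perm + 1)
    importance = pd.Series(observed, index=X.columns, name="importance")
    pvalues = pd.Series(pvals, index=X.columns, name="p_value")
    selected = list(pvalues.index[pvalues < p_threshold])
    return SiteSelectionResult(
        method="RFR",
        scores=importance,
        pvalues=pvalues,
        selected=selected,
        threshold=p_threshold,
    )
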