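"""Clock training backends and the shared train / predict contract.

Four regression methods sit behind one interface: elastic-net (ENR),
random-forest (RFR), support-vector (SVM) and generalised additive
models (GAM).  Each backend tunes its own hyperparameters on first fit
and can then be re-fitted with those hyperparameters held fixed, which
is what leave-one-out evaluation and the resampling engine rely on.
Predictions are back-transformed (when trained on log age) and clamped
to [0, 80] years.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from epiage.forest import RandomForest

METHODS = ("ENR", "RFR", "SVM", "GAM")
SITE_SELECTIONS = ("all", "ENR", "RFR")
SAMPLE_SUBSETS = ("All", "CR3+", "CR4+")

CLAMP_BOUNDS = (0.0, 80.0)

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class TuningSettings:
    """Hyperparameter-search settings, overridable for desk-scale runs."""

    cv_folds: int = 10
    # elastic net
    enr_alpha_range: tuple = (1e-4, 0.5)
    enr_tune_reps: int = 1000
    enr_n_lambdas: int = 100
    enr_alpha_xatol: float = 1e-3
    # random forest
    rf_n_trees: int = 10_000
    rf_sampsize_step: int = 1
    rf_mtry_step: int = 1
    # SVM (log10-space grids)
    svm_log_cost: tuple = (-4.0, 5.0)
    svm_log_gamma: tuple = (-5.0, 4.0)
    svm_log_step: float = 0.1
    # GAM
    gam_k: int = 3
    gam_max_k: int = 10
    gam_penalty: float = 1.0

    @classmethod
    def desk(cls) -> "TuningSettings":
        """Reduced settings for tests and small studies."""
        return cls(
            cv_folds=5,
            enr_tune_reps=8,
            enr_n_lambdas=30,
            enr_alpha_xatol=0.02,
            rf_n_trees=200,
            rf_sampsize_step=5,
            rf_mtry_step=5,
            svm_log_cost=(-2.0, 4.0),
            svm_log_gamma=(-4.0, 1.0),
            svm_log_step=1.0,
        )


@dataclass(frozen=True)
class ClockConfig:
    """One point in the model-design grid."""

    method: str = "ENR"
    log_age: bool = False
    site_selection: str = "all"
    site_selection_samples: str | None = None
    training_samples: str = "All"
    weighted: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.site_selection not in SITE_SELECTIONS:
            raise ValueError(f"unknown site_selection {self.site_selection!r}")
        if self.site_selection == "all":
            if self.site_selection_samples is not None:
                raise ValueError("site_selection 'all' takes no sample subset")
        elif self.site_selection_samples not in SAMPLE_SUBSETS:
            raise ValueError(
                f"unknown site_selection_samples {self.site_selection_samples!r}"
            )
        if self.training_samples not in SAMPLE_SUBSETS:
            raise ValueError(f"unknown training_samples {self.training_samples!r}")

    def label(self) -> str:
        sel = self.site_selection
        if self.site_selection_samples:
            sel += f"[{self.site_selection_samples}]"
        return (
            f"{self.method}|{'log' if self.log_age else 'none'}|{sel}"
            f"|{self.training_samples}|{'w' if self.weighted else 'u'}"
        )


class ClockFitError(RuntimeError):
    pass


def _standardise(X):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std, mean, std


def _cv_mae(X, y, l1_ratio, sample_weight, n_folds, n_lambdas, seed):
    """One replicate: pick the CV-deviance-minimising penalty, then the
    median absolute error of cross-validated predictions at that penalty."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=n_lambdas, cv=kf, max_iter=5_000
    )
    cv.fit(X, y, sample_weight=sample_weight)
    lam = cv.alpha_
    pred = np.empty_like(y, dtype=float)
    for train, test in kf.split(X):
        est = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5_000)
        w = None if sample_weight is None else sample_weight[train]
        est.fit(X[train], y[train], sample_weight=w)
        pred[test] = est.predict(X[test])
    return float(np.median(np.abs(pred - y))), lam


def tune_enr_alpha(
    X,
    y,
    sample_weight=None,
    alpha_range=(1e-4, 0.5),
    n_reps=50,
    settings: TuningSettings | None = None,
    seed=None,
):
    """Choose the elastic-net mixing parameter alpha (l1_ratio).

    For each candidate alpha, ``n_reps`` replicate 10-fold CV fits are
    run; each records the MAE at its deviance-minimising penalty, and the
    median MAE over replicates is minimised with a bounded scalar
    optimiser.  Replicates share fold seeds across alphas (common random
    numbers) so the objective is deterministic under ``seed``.
    """
    settings = settings or TuningSettings()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lo, hi = alpha_range
    if lo == hi:
        return float(lo)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < settings.cv_folds:
        raise ClockFitError(
            f"{len(y)} samples but {settings.cv_folds} CV folds requested"
        )
    Xs, _, _ = _standardise(X)
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)

    def objective(alpha):
        maes = [
            _cv_mae(
                Xs,
                y,
                alpha,
                sample_weight,
                settings.cv_folds,
                settings.enr_n_lambdas,
                int(s),
            )[0]
            for s in rep_seeds
        ]
        return float(np.median(maes))

    res = optimize.minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": settings.enr_alpha_xatol},
    )
    return float(res.x)


class ENRBackend:
    """Elastic-net regression with internal standardisation."""

    def __init__(self, settings: TuningSettings, l1_ratio=None, lambda_=None):
        self.settings = settings
        self.l1_ratio = l1_ratio
        self.lambda_ = lambda_

    @property
    def hyperparams(self):
        return {"l1_ratio": self.l1_ratio, "lambda": self.lambda_}

    def fit(self, X, y, sample_weight=None, seed=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        Xs, self.mean_, self.std_ = _standardise(X)
        rng = np.random.default_rng(seed)
        if self.l1_ratio is None:
            self.l1_ratio = tune_enr_alpha(
                X,
                y,
                sample_weight,
                alpha_range=self.settings.enr_alpha_range,
                n_reps=self.settings.enr_tune_reps,
                settings=self.settings,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        if self.lambda_ is None:
            kf = KFold(
                n_splits=self.settings.cv_folds,
                shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            cv = ElasticNetCV(
                l1_ratio=self.l1_ratio,
                alphas=self.settings.enr_n_lambdas,
                cv=kf,
                max_iter=5_000,
            )
            cv.fit(Xs, y, sample_weight=sample_weight)
            self.lambda_ = float(cv.alpha_)
        self.model_ = ElasticNet(
            alpha=self.lambda_, l1_ratio=self.l1_ratio, max_iter=10_000
        )
        self.model_.fit(Xs, y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.std_
        return self.model_.predict(Xs)

    def clone_tuned(self):
        return ENRBackend(self.settings, self.l1_ratio, self.lambda_)


def tune_svm(X, y, settings: TuningSettings, seed=None):
    """10-fold CV grid search for (cost, gamma) of an RBF-kernel SVR.

    The grid is stepped in log10 space (``svm_log_step``) over the
    configured cost and gamma ranges; the pair with the lowest CV mean
    squared error wins.
    """
    lo_c, hi_c = settings.svm_log_cost
    lo_g, hi_g = settings.svm_log_gamma
    step = settings.svm_log_step
    costs = 10.0 ** np.arange(lo_c, hi_c + step / 2, step)
    gammas = 10.0 ** np.arange(lo_g, hi_g + step / 2, step)
    n_folds = min(settings.cv_folds, len(y))
    if n_folds < 2:
        raise ClockFitError("need at least 2 samples to tune SVM")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best = (np.inf, None, None)
    for c in costs:
        for g in gammas:
            sse = 0.0
            for train, test in splits:
                est = SVR(kernel="rbf", C=c, gamma=g)
                est.fit(X[train], y[train])
                sse += float(np.sum((est.predict(X[test]) - y[test]) ** 2))
            mse = sse / len(y)
            if mse < best[0]:
                best = (mse, float(c), float(g))
    return best[1], best[2]


class SVMBackend:
    """RBF-kernel support-vector regression (sample weights unsupported)."""

    def __init__(self, settings: TuningSettings, cost=None, gamma=None):
        self.settings = settings
        self.cost = cost
        self.gamma = gamma

    @property
    def hyperparams(self):
        return {"cost": self.cost, "gamma": self.gamma}

    def fit(self, X, y, sample_weight=None, seed=None):
        # SVM fitting has no weighting mechanism; weights are ignored here
        # (they may still have shaped upstream site selection).
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        Xs, self.mean_, self.std_ = _standardise(X)
        if self.cost is None or self.gamma is None:
            rng = np.random.default_rng(seed)
            self.cost, self.gamma = tune_svm(
                Xs, y, self.settings, seed=int(rng.integers(0, 2**31 - 1))
            )
        self.model_ = SVR(kernel="rbf", C=self.cost, gamma=self.gamma)
        self.model_.fit(Xs, y)
        return self

    def predict(self, X):
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.std_
        return self.model_.predict(Xs)

    def clone_tuned(self):
        return SVMBackend(self.settings, self.cost, self.gamma)


def tune_rf_grid(X, y, sample_weight, settings: TuningSettings, seed=None):
    """Out-of-bag MSE over the (sampsize, mtry) grid, median-smoothed.

    sampsize spans 0.3n..0.7n and mtry 0.1s..0.5s (integer steps per the
    settings).  The selected point is the argmin of the error surface
    after a 3x3 median filter — a deterministic surrogate for choosing
    by visual inspection of the raw surface.
    """
    n, s = X.shape
    ss_vals = np.arange(
        max(2, int(round(0.3 * n))),
        max(2, int(round(0.7 * n))) + 1,
        settings.rf_sampsize_step,
    )
    mtry_vals = np.arange(
        max(1, int(round(0.1 * s))),
        max(1, int(round(0.5 * s))) + 1,
        settings.rf_mtry_step,
    )
    rng = np.random.default_rng(seed)
    errs = np.empty((len(ss_vals), len(mtry_vals)))
    for i, ss in enumerate(ss_vals):
        for j, mt in enumerate(mtry_vals):
            forest = RandomForest(
                n_trees=settings.rf_n_trees,
                sampsize=int(ss),
                mtry=int(mt),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            forest.fit(X, y, sample_weight=sample_weight)
            errs[i, j] = forest.oob_mse()
    smoothed = ndimage.median_filter(errs, size=3, mode="nearest")
    i, j = np.unravel_index(np.argmin(smoothed), smoothed.shape)
    return int(ss_vals[i]), int(mtry_vals[j]), errs, smoothed


class RFRBackend:
    """Random-forest regression; stores out-of-bag predictions after fit."""

    def __init__(self, settings: TuningSettings, sampsize=None, mtry=None):
        self.settings = settings
        self.sampsize = sampsize
        self.mtry = mtry

    @property
    def hyperparams(self):
        return {"sampsize": self.sampsize, "mtry": self.mtry}

    def fit(self, X, y, sample_weight=None, seed=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(seed)
        if self.sampsize is None or self.mtry is None:
            self.sampsize, self.mtry, _, _ = tune_rf_grid(
                X,
                y,
                sample_weight,
                self.settings,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        self.model_ = RandomForest(
            n_trees=self.settings.rf_n_trees,
            sampsize=self.sampsize,
            mtry=self.mtry,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        self.model_.fit(X, y, sample_weight=sample_weight)
        self.oob_prediction_ = self.model_.oob_prediction()
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def clone_tuned(self):
        return RFRBackend(self.settings, self.sampsize, self.mtry)


class GAMBackend:
    """Additive model: one penalised B-spline smooth per site.

    The basis comes from statsmodels' ``BSplines``; coefficients are
    estimated by a direct penalised (weighted) least-squares solve with a
    ridge penalty on the standardised spline coefficients, which stays
    well-posed when the basis has more columns than samples.  The
    per-site basis dimension starts at ``gam_k`` and is incremented if a
    solve fails.
    """

    def __init__(self, settings: TuningSettings, k=None):
        self.settings = settings
        self.k = k

    @property
    def hyperparams(self):
        return {"k": self.k}

    def _fit_once(self, X, y, sample_weight, k):
        from statsmodels.gam.api import BSplines

        n, s = X.shape
        degree = min(2, k - 1)
        bs = BSplines(X, df=[k] * s, degree=[degree] * s)
        basis = np.asarray(bs.basis, dtype=float)
        scale = basis.std(axis=0)
        scale[scale == 0] = 1.0
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        w = w / w.mean()
        b0 = float(np.average(y, weights=w))
        bc = basis / scale
        lam = self.settings.gam_penalty
        lhs = (bc * w[:, None]).T @ bc + lam * np.eye(bc.shape[1])
        rhs = (bc * w[:, None]).T @ (y - b0)
        coef = np.linalg.solve(lhs, rhs)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError("non-finite GAM coefficients")
        return bs, (b0, coef / scale)

    def fit(self, X, y, sample_weight=None, seed=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.col_min_ = X.min(axis=0)
        self.col_max_ = X.max(axis=0)
        k = self.k or self.settings.gam_k
        last_error = None
        while k <= self.settings.gam_max_k:
            try:
                self.smoother_, (self.intercept_, self.coef_) = self._fit_once(
                    X, y, sample_weight, k
                )
                self.k = k
                return self
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_error = exc
                k += 1
        raise ClockFitError(f"GAM failed up to k={k - 1}: {last_error}")

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        # B-spline bases are only defined on the training range
        X = np.clip(X, self.col_min_, self.col_max_)
        basis = np.asarray(self.smoother_.transform(X), dtype=float)
        if basis.ndim == 1:
            basis = basis.reshape(len(X), -1)
        return self.intercept_ + basis @ self.coef_

    def clone_tuned(self):
        return GAMBackend(self.settings, self.k)


_BACKENDS = {
    "ENR": ENRBackend,
    "RFR": RFRBackend,
    "SVM": SVMBackend,
    "GAM": GAMBackend,
}


@dataclass
class TrainedClock:
    """A fitted clock: config, selected sites, backend and transform."""

    config: ClockConfig
    sites: list
    backend: object
    clamp: tuple = CLAMP_BOUNDS
    training_samples: list = field(default_factory=list)

    @property
    def hyperparams(self):
        return self.backend.hyperparams

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [s for s in self.sites if s not in X.columns]
        if missing:
            raise KeyError(f"methylation matrix lacks clock sites: {missing}")
        return X[self.sites].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict ages: back-transform if trained on log age, then clamp."""
        raw = self.backend.predict(self._matrix(X))
        if self.config.log_age:
            raw = np.exp(raw)
        return np.clip(raw, *self.clamp)

    def refit(self, X: pd.DataFrame, ages, sample_weight=None, seed=None):
        """Refit with hyperparameters held fixed (LOO folds, resampling)."""
        backend = self.backend.clone_tuned()
        y = transform_ages(ages, self.config.log_age)
        backend.fit(self._matrix(X), y, sample_weight=sample_weight, seed=seed)
        return TrainedClock(
            config=self.config,
            sites=self.sites,
            backend=backend,
            clamp=self.clamp,
            training_samples=list(X.index),
        )

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump({"version": ARCHIVE_VERSION, "clock": self}, fh)

    @staticmethod
    def load(path) -> "TrainedClock":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"unsupported clock archive version {payload.get('version')!r}"
            )
        return payload["clock"]


def transform_ages(ages, log_age: bool) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if log_age:
        if (ages <= 0).any():
            raise ValueError("log transform requires strictly positive ages")
        return np.log(ages)
    return ages


def train(
    config: ClockConfig,
    X: pd.DataFrame,
    ages,
    sample_weight=None,
    settings: TuningSettings | None = None,
    seed=None,
    sites=None,
) -> TrainedClock:
    """Tune and fit a clock of ``config.method`` on a methylation matrix.

    ``X`` is a samples x sites frame (already restricted to the training
    sample subset); ``sites`` optionally restricts the columns used.
    Weights are ignored by the SVM backend, which has no mechanism.
    """
    settings = settings or TuningSettings()
    sites = list(sites) if sites is not None else list(X.columns)
    if not sites:
        raise ClockFitError("no sites to train on")
    if config.weighted and sample_weight is None:
        raise ValueError("config.weighted=True but no sample weights given")
    if not config.weighted:
        sample_weight = None
    backend = _BACKENDS[config.method](settings)
    y = transform_ages(ages, config.log_age)
    if not np.isfinite(X[sites].to_numpy(dtype=float)).all():
        raise ValueError("methylation matrix contains non-finite values")
    try:
        backend.fit(
            X[sites].to_numpy(dtype=float), y, sample_weight=sample_weight, seed=seed
        )
    except ClockFitError:
        raise
    except Exception as exc:  # surface which configuration failed
        raise ClockFitError(f"fit failed for {config.label()}: {exc}") from exc
    return TrainedClock(
        config=config,
        sites=sites,
        backend=backend,
        training_samples=list(X.index),
    )


def with_settings(settings: TuningSettings, **overrides) -> TuningSettings:
    return replace(settings, **overrides)
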