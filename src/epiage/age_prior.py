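"""Confidence-weighted skew-normal age probability distributions.

Each catalogue age record (Age_best, Age_min, Age_max, CR) becomes a
mixture of a skew-normal — fitted so its mode equals Age_best and its
0.025 / 0.975 quantiles equal Age_min / Age_max — and a uniform over
(Age_min, Age_max).  The mixture weight on the skew-normal component is
set by the confidence rating CR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import skewnorm, uniform

#: Skew-normal mixture weight by confidence rating (no weight defined for CR 1).
CR_WEIGHTS = {2: 0.2, 3: 0.55, 4: 0.75, 5: 1.0}

FIT_TOL = 1e-3  # years / probability, on each of the three constraints


class SkewNormalFitError(RuntimeError):
    """Raised when the constrained skew-normal fit does not converge."""


def mixture_weight(cr: int) -> float:
    """Weight on the skew-normal component for confidence rating ``cr``."""
    try:
        return CR_WEIGHTS[int(cr)]
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"no mixture weight defined for confidence rating {cr!r}; "
            f"supported ratings: {sorted(CR_WEIGHTS)}"
        ) from exc


def skew_normal_mode(shape: float, loc: float = 0.0, scale: float = 1.0) -> float:
    """Numerical mode of a skew-normal distribution."""
    res = optimize.minimize_scalar(
        lambda z: -skewnorm.pdf(z, shape),
        bounds=(-1.0, 1.0),  # standard skew-normal mode lies in (-0.8, 0.8)
        method="bounded",
        options={"xatol": 1e-12},
    )
    return loc + scale * res.x


def _constraint_residuals(params, age_best, age_min, age_max):
    loc, log_scale, shape = params
    scale = np.exp(log_scale)
    mode = skew_normal_mode(shape, loc, scale)
    return np.array(
        [
            mode - age_best,
            skewnorm.cdf(age_min, shape, loc, scale) - 0.025,
            skewnorm.cdf(age_max, shape, loc, scale) - 0.975,
        ]
    )


def _standard_geometry(shape: float) -> tuple[float, float, float]:
    """(mode, 0.025 quantile, 0.975 quantile) of a standard skew-normal."""
    return (
        skew_normal_mode(shape),
        skewnorm.ppf(0.025, shape),
        skewnorm.ppf(0.975, shape),
    )


_SHAPE_BRACKET = 5000.0  # beyond this the skew-normal is numerically half-normal


def fit_skew_normal(
    age_best: float,
    age_min: float,
    age_max: float,
    max_restarts: int = 20,
) -> tuple[float, float, float]:
    """Fit (location, scale, shape) so that mode = Age_best and the 0.025 /
    0.975 quantiles equal Age_min / Age_max, each within 1e-3.

    For a candidate shape, the two quantile constraints fix location and
    scale in closed form, so the fit reduces to a 1-D root solve on the
    shape for the mode constraint (the relative mode position is monotone
    in the shape).  A jittered multi-start least-squares over all three
    parameters is kept as a fallback.  Deterministic for fixed inputs.
    A mode sitting exactly on Age_min or Age_max is nudged inward by
    1e-6 x range since an extreme quantile cannot be the mode.
    """
    if age_min >= age_max:
        raise ValueError(f"Age_min={age_min} must be < Age_max={age_max}")
    if not age_min <= age_best <= age_max:
        raise ValueError("Age_best must lie within [Age_min, Age_max]")
    span = age_max - age_min
    if age_best <= age_min:
        age_best = age_min + 1e-6 * span
    elif age_best >= age_max:
        age_best = age_max - 1e-6 * span
    r_target = (age_best - age_min) / span

    def mode_position(shape):
        m0, z_lo, z_hi = _standard_geometry(shape)
        return (m0 - z_lo) / (z_hi - z_lo)

    lo_val = mode_position(_SHAPE_BRACKET) - r_target
    hi_val = mode_position(-_SHAPE_BRACKET) - r_target
    if lo_val * hi_val <= 0:
        shape = optimize.brentq(
            lambda a: mode_position(a) - r_target,
            -_SHAPE_BRACKET,
            _SHAPE_BRACKET,
            xtol=1e-13,
        )
        m0, z_lo, z_hi = _standard_geometry(shape)
        scale = span / (z_hi - z_lo)
        loc = age_min - scale * z_lo
        resid = np.abs(
            _constraint_residuals(
                [loc, np.log(scale), shape], age_best, age_min, age_max
            )
        )
        if resid.max() < FIT_TOL:
            return float(loc), float(scale), float(shape)

    # fallback: jittered multi-start least-squares over all three parameters
    x0 = np.array([age_best, np.log(span / 3.92), 0.0])
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = x0.copy()
        if attempt:
            start += rng.normal(scale=[0.3 * span, 0.3, 1.5])
        sol = optimize.least_squares(
            _constraint_residuals,
            start,
            args=(age_best, age_min, age_max),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=400,
        )
        resid = np.abs(sol.fun)
        if best is None or resid.max() < best[0]:
            best = (resid.max(), sol.x)
        if resid.max() < FIT_TOL:
            loc, log_scale, shape = sol.x
            return float(loc), float(np.exp(log_scale)), float(shape)
    raise SkewNormalFitError(
        f"skew-normal fit failed for (best={age_best}, min={age_min}, "
        f"max={age_max}); worst constraint violation {best[0]:.3g}"
    )


@dataclass
class AgePrior:
    """Confidence-weighted skew-normal / uniform mixture for one sample."""

    location: float
    scale: float
    shape: float
    weight: float  # mixture weight on the skew-normal component
    age_min: float
    age_max: float

    def pdf(self, age):
        """Mixture density w * SkewNormal + (1 - w) * Uniform(min, max)."""
        age = np.asarray(age, dtype=float)
        sn = skewnorm.pdf(age, self.shape, self.location, self.scale)
        un = uniform.pdf(age, self.age_min, self.age_max - self.age_min)
        out = self.weight * sn + (1.0 - self.weight) * un
        return out if out.ndim else out.item()

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ages: pick a component per draw, reject negatives."""
        out = np.empty(size)
        pending = np.arange(size)
        while pending.size:
            use_sn = rng.random(pending.size) < self.weight
            draws = np.where(
                use_sn,
                skewnorm.rvs(
                    self.shape,
                    self.location,
                    self.scale,
                    size=pending.size,
                    random_state=rng,
                ),
                rng.uniform(self.age_min, self.age_max, size=pending.size),
            )
            out[pending] = draws
            pending = pending[draws < 0]
        return out


def fit_prior(age_best, age_min, age_max, cr) -> AgePrior:
    loc, scale, shape = fit_skew_normal(age_best, age_min, age_max)
    return AgePrior(
        location=loc,
        scale=scale,
        shape=shape,
        weight=mixture_weight(cr),
        age_min=float(age_min),
        age_max=float(age_max),
    )


AGE_TABLE_COLUMNS = [
    "sample_id",
    "individual_id",
    "collection_date",
    "age_best",
    "age_min",
    "age_max",
    "cr",
]


def validate_age_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in AGE_TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"age table missing columns: {missing}")
    records = records.copy()
    for col in ("age_best", "age_min", "age_max"):
        records[col] = pd.to_numeric(records[col])
    records["cr"] = pd.to_numeric(records["cr"]).astype(int)
    bad = records[
        (records["age_min"] > records["age_best"])
        | (records["age_best"] > records["age_max"])
        | (records["age_min"] < 0)
    ]
    if len(bad):
        raise ValueError(
            f"age records violate Age_min <= Age_best <= Age_max:\n"
            f"{bad[['sample_id', 'age_best', 'age_min', 'age_max']]}"
        )
    if records["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in age table")
    return records


def read_age_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return validate_age_table(pd.read_csv(path, sep=sep))


def fit_priors(records: pd.DataFrame) -> dict[str, AgePrior]:
    """Fit one AgePrior per row of a validated age table."""
    records = validate_age_table(records)
    priors = {}
    for row in records.itertuples():
        try:
            priors[row.sample_id] = fit_prior(
                row.age_best, row.age_min, row.age_max, row.cr
            )
        except (SkewNormalFitError, ValueError) as exc:
            raise SkewNormalFitError(
                f"prior fit failed for sample {row.sample_id}: {exc}"
            ) from exc
    return priors


def priors_to_frame(priors: dict[str, AgePrior]) -> pd.DataFrame:
    """Serialise fitted priors to a flat table (inverse of priors_from_frame)."""
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "location": p.location,
                "scale": p.scale,
                "shape": p.shape,
                "weight": p.weight,
                "age_min": p.age_min,
                "age_max": p.age_max,
            }
            for sid, p in priors.items()
        ]
    )


def priors_from_frame(frame: pd.DataFrame) -> dict[str, AgePrior]:
    return {
        row.sample_id: AgePrior(
            location=row.location,
            scale=row.scale,
            shape=row.shape,
            weight=row.weight,
            age_min=row.age_min,
            age_max=row.age_max,
        )
        for row in frame.itertuples()
    }
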