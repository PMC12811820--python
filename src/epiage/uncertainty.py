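"""Resampling-based uncertainty propagation for clock predictions.

Each replicate draws an age for every training sample from its
confidence-weighted age prior and redraws every methylation count from
Binomial(K_m, n_m / K_m), pushes the redrawn proportions through the
same conversion-efficiency correction and logit as the point pipeline,
refits the clock (hyperparameters held fixed) and predicts every sample.
Per-sample draws are summarised as a 95% highest-density interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit as _logit

from epiage.age_prior import AgePrior
from epiage.clocks import TrainedClock
from epiage.methyl import DegenerateLocusError, MethylationMatrix
from epiage.search import cr_weights, subset_mask

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.05


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted draws.

    Ties in width are broken toward the lower (leftmost) window.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws for an HDI")
    if not np.isfinite(draws).all():
        raise ValueError("non-finite draws")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    s = np.sort(draws)
    n = s.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) window on ties
    return float(s[i]), float(s[i + k - 1])


@dataclass
class PredictionDistribution:
    sample_id: str
    draws: np.ndarray
    hdi_lower: float
    hdi_upper: float
    median: float
    mode: float
    age_best: float | None = None

    @property
    def age_best_in_hdi(self) -> bool | None:
        if self.age_best is None:
            return None
        return bool(self.hdi_lower <= self.age_best <= self.hdi_upper)


@dataclass
class PairOrdinality:
    individual_id: str
    earlier_sample: str
    later_sample: str
    true_gap_years: float
    differences: np.ndarray  # later - earlier, per replicate
    proportion_correct: float
    correct: bool


def _draw_mode(draws: np.ndarray, n_bins: int = 40) -> float:
    lo, hi = draws.min(), draws.max()
    if hi - lo < 1e-12:
        return float(lo)
    counts, edges = np.histogram(draws, bins=n_bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def resample_methylation(
    matrix: MethylationMatrix,
    rng: np.random.Generator,
    locus_fallback: pd.Series | None = None,
) -> pd.DataFrame:
    """One binomial redraw of the whole methylation matrix, logit scale.

    Counts n* ~ Binomial(K_m, n_m / K_m) replace n_m; the proportions are
    re-corrected with each sample's fixed conversion efficiency and the
    half-lowest-per-locus substitution applied within the redrawn matrix.
    ``locus_fallback`` supplies half-replacement values for loci whose
    redrawn matrix has no positive corrected cell.
    """
    counts = matrix.counts
    k = counts["K_m"].to_numpy()
    p = counts["n_m"].to_numpy() / k
    n_star = rng.binomial(k, p)
    p_star = n_star / k
    p_v = (
        counts["sample_id"]
        .map(matrix.sample_qc["conversion_efficiency"])
        .to_numpy()
    )
    raw = 1.0 - (1.0 - p_star) / p_v

    locus = counts["locus"].to_numpy()
    out = raw.copy()
    pos = raw > 0
    locus_min = (
        pd.Series(raw[pos]).groupby(pd.Series(locus[pos])).min()
        if pos.any()
        else pd.Series(dtype=float)
    )
    low = ~pos
    if low.any():
        repl = pd.Series(locus[low]).map(locus_min)
        if repl.isna().any():
            if locus_fallback is None:
                raise DegenerateLocusError(
                    "replicate produced a locus with no positive corrected value"
                )
            repl = repl.fillna(pd.Series(locus[low]).map(locus_fallback))
        out[low] = 0.5 * repl.to_numpy()
    below = raw < 1
    high = ~below
    if high.any():
        gap = 1.0 - raw[below & pos]
        locus_gap = pd.Series(gap).groupby(pd.Series(locus[below & pos])).min()
        repl = pd.Series(locus[high]).map(locus_gap)
        if repl.isna().any():
            raise DegenerateLocusError(
                "replicate produced a locus with every corrected value at one"
            )
        out[high] = 1.0 - 0.5 * repl.to_numpy()

    frame = counts[["sample_id", "site_id"]].copy()
    frame["m"] = _logit(out)
    wide = frame.pivot(index="sample_id", columns="site_id", values="m")
    return wide.loc[matrix.sample_ids, matrix.site_ids]


def resample_replicate(
    matrix: MethylationMatrix,
    priors: dict[str, AgePrior],
    rng: np.random.Generator,
    locus_fallback: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Draw one replicate: ages from the priors, methylation from Eq. 3."""
    ages = pd.Series(
        {sid: priors[sid].sample(rng, 1)[0] for sid in matrix.sample_ids},
        name="age",
    )
    m_star = resample_methylation(matrix, rng, locus_fallback=locus_fallback)
    return ages, m_star


@dataclass
class ResamplingResult:
    distributions: dict[str, PredictionDistribution]
    draws: pd.DataFrame  # samples x replicates
    n_requested: int
    n_failed: int
    extra: dict = field(default_factory=dict)


def _point_locus_fallback(matrix: MethylationMatrix) -> pd.Series:
    """Per-locus minimum positive corrected value from the point estimates."""
    p_hat_long = matrix.p_hat.stack()
    locus = p_hat_long.index.get_level_values(1).map(matrix.site_locus)
    pos = p_hat_long[p_hat_long > 0]
    return pos.groupby(locus[p_hat_long > 0]).min()


def run_resampling(
    matrix: MethylationMatrix,
    priors: dict[str, AgePrior],
    clock: TrainedClock,
    cr: pd.Series,
    n_reps: int = 1000,
    seed=None,
) -> ResamplingResult:
    """Propagate age and methylation uncertainty through replicate refits.

    For each of ``n_reps`` replicates a fresh model is fitted on the
    replicate's drawn ages and methylation (training subset and weighting
    from the clock's config), and every sample is predicted and clamped.
    Failed replicate fits are dropped with a warning; more than 5%
    failures aborts the run.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    sample_ids = matrix.sample_ids
    missing = [s for s in sample_ids if s not in priors]
    if missing:
        raise ValueError(f"no age prior for samples: {missing}")
    mask = subset_mask(cr.loc[sample_ids], clock.config.training_samples)
    train_ids = list(pd.Index(sample_ids)[mask.to_numpy()])
    weights = cr_weights(cr) if clock.config.weighted else None
    fallback = _point_locus_fallback(matrix)

    draws = np.full((len(sample_ids), n_reps), np.nan)
    n_failed = 0
    for r in range(n_reps):
        ages_r, m_r = resample_replicate(
            matrix, priors, rng, locus_fallback=fallback
        )
        try:
            w = weights.loc[train_ids].to_numpy() if weights is not None else None
            fit = clock.refit(
                m_r.loc[train_ids],
                ages_r.loc[train_ids],
                sample_weight=w,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            draws[:, r] = fit.predict(m_r)
        except Exception as exc:  # noqa: BLE001 - replicate-level isolation
            n_failed += 1
            logger.warning("replicate %d failed: %s", r, exc)
    if n_failed > MAX_FAILURE_FRACTION * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} replicate fits failed (> "
            f"{MAX_FAILURE_FRACTION:.0%} allowed)"
        )
    ok = ~np.isnan(draws).all(axis=0)
    draws = draws[:, ok]

    draw_frame = pd.DataFrame(draws, index=sample_ids)
    distributions = {}
    for sid in sample_ids:
        d = draw_frame.loc[sid].to_numpy()
        lo, hi = hdi(d, 0.95)
        distributions[sid] = PredictionDistribution(
            sample_id=sid,
            draws=d,
            hdi_lower=lo,
            hdi_upper=hi,
            median=float(np.median(d)),
            mode=_draw_mode(d),
        )
    return ResamplingResult(
        distributions=distributions,
        draws=draw_frame,
        n_requested=n_reps,
        n_failed=n_failed,
    )


def attach_age_best(
    distributions: dict[str, PredictionDistribution], age_best: pd.Series
) -> None:
    for sid, dist in distributions.items():
        if sid in age_best.index:
            dist.age_best = float(age_best.loc[sid])


def hdi_coverage(
    distributions: dict[str, PredictionDistribution],
    age_best: pd.Series,
    sample_ids=None,
) -> float:
    """Fraction of samples whose Age_best lies inside their 95% HDI."""
    ids = list(sample_ids) if sample_ids is not None else list(distributions)
    hits = 0
    for sid in ids:
        dist = distributions[sid]
        hits += dist.hdi_lower <= age_best.loc[sid] <= dist.hdi_upper
    return hits / len(ids)


def build_pair_registry(age_records: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal pairs: same individual sampled on different dates."""
    records = age_records.copy()
    records["collection_date"] = pd.to_datetime(records["collection_date"])
    pairs = []
    for ind, rows in records.groupby("individual_id"):
        rows = rows.sort_values("collection_date")
        if len(rows) < 2 or rows["collection_date"].nunique() < 2:
            continue
        first, last = rows.iloc[0], rows.iloc[-1]
        gap = (last["collection_date"] - first["collection_date"]).days / 365.25
        pairs.append(
            {
                "individual_id": ind,
                "earlier_sample": first["sample_id"],
                "later_sample": last["sample_id"],
                "true_gap_years": gap,
            }
        )
    return pd.DataFrame(
        pairs,
        columns=[
            "individual_id",
            "earlier_sample",
            "later_sample",
            "true_gap_years",
        ],
    )


def pair_ordinality(
    draws: pd.DataFrame, pair_registry: pd.DataFrame
) -> list[PairOrdinality]:
    """Per-pair replicate age differences and ordinality correctness.

    The difference is the later sample's prediction minus the earlier
    sample's, replicate by replicate; ties count as incorrect.
    """
    results = []
    for row in pair_registry.itertuples():
        if row.true_gap_years <= 0:
            raise ValueError(
                f"pair for {row.individual_id} has non-positive true age gap"
            )
        early = draws.loc[row.earlier_sample].to_numpy()
        late = draws.loc[row.later_sample].to_numpy()
        if early.shape != late.shape:
            raise ValueError("mismatched replicate counts within a pair")
        diff = late - early
        prop = float(np.mean(diff > 0))
        results.append(
            PairOrdinality(
                individual_id=row.individual_id,
                earlier_sample=row.earlier_sample,
                later_sample=row.later_sample,
                true_gap_years=float(row.true_gap_years),
                differences=diff,
                proportion_correct=prop,
                correct=prop > 0.5,
            )
        )
    return results


def distributions_to_frame(
    distributions: dict[str, PredictionDistribution],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "median": d.median,
                "mode": d.mode,
                "hdi_lower": d.hdi_lower,
                "hdi_upper": d.hdi_upper,
                "age_best": d.age_best,
                "age_best_in_hdi": d.age_best_in_hdi,
            }
            for d in distributions.values()
        ]
    )
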