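"""Synthetic cohort generator.

Produces per-site nucleotide count tables and catalogue-style age records
with the statistical structure the clock framework assumes: clock CpG
sites whose logit-scale methylation is linear in true age, uninformative
CpG sites, non-CpG cytosine control sites that carry the bisulfite
conversion-failure signal, injected sequencing errors, and age records
degraded from true ages with confidence-rating-dependent noise and range
widths (lower CR and older age -> wider plausible-age ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from epiage.methyl import CPG, NONCPG_C, TABLE_COLUMNS

#: per-CR scale of the Age_best noise (years) and base half-width of the
#: plausible-age range; both widen as CR drops.
CR_NOISE_SD = {2: 4.0, 3: 2.0, 4: 1.0, 5: 0.5}
CR_BASE_HALF_WIDTH = {2: 6.0, 3: 4.0, 4: 2.5, 5: 1.5}


@dataclass
class SynthSpec:
    """Parameters of a synthetic cohort (defaults mirror the reference data:
    89 samples over 8 loci, 47 clock sites among ~184 CpG sites, read
    depths 1000-7000, conversion efficiency 0.993-0.997, ages 3-40)."""

    n_individuals: int = 76
    n_pairs: int = 13
    pair_gap_range: tuple = (2.0, 13.0)
    n_loci: int = 8
    sites_per_locus: int = 23
    n_clock_sites: int = 47
    n_control_per_locus: int = 30
    slope_range: tuple = (0.04, 0.09)
    intercept_range: tuple = (-2.0, 0.5)
    null_level_range: tuple = (-3.0, 1.0)
    #: per-sample, per-site biological scatter on the logit scale; real
    #: amplicon data shows site-age correlations well below 1
    site_noise_sd: float = 0.3
    depth_range: tuple = (1000, 7000)
    conversion_range: tuple = (0.993, 0.997)
    error_rate: float = 0.0002
    age_range: tuple = (3.0, 40.0)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.n_loci * self.sites_per_locus

    def validate(self):
        if self.n_clock_sites > self.n_sites:
            raise ValueError("n_clock_sites exceeds total CpG sites")
        if self.depth_range[0] <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        lo, hi = self.age_range
        if lo < 0 or hi <= lo:
            raise ValueError("invalid age_range")
        # methylation must stay comfortably inside (0, 1) across the age span
        extreme = max(
            abs(self.intercept_range[0]), abs(self.intercept_range[1])
        ) + self.slope_range[1] * 0.5 * (hi - lo)
        if extreme > 12:
            raise ValueError("slopes/intercepts push methylation to 0 or 1")
        return self


@dataclass
class SiteTruth:
    """Generating parameters per CpG site, for test oracles."""

    table: pd.DataFrame  # site_id, locus, is_clock, intercept, slope

    @property
    def clock_sites(self):
        return list(self.table.loc[self.table["is_clock"], "site_id"])

    @property
    def null_sites(self):
        return list(self.table.loc[~self.table["is_clock"], "site_id"])


def _assign_cr(age: float, rng: np.random.Generator) -> int:
    """Older animals are harder to age: CR drifts down with age."""
    p5 = np.clip(0.45 - 0.012 * age, 0.02, None)
    p4 = np.clip(0.40 - 0.004 * age, 0.05, None)
    p3 = 0.35
    p2 = 0.05 + 0.010 * age
    p = np.array([p2, p3, p4, p5])
    return int(rng.choice([2, 3, 4, 5], p=p / p.sum()))


def degrade_ages(
    true_ages: pd.Series,
    rng: np.random.Generator,
    collection_dates: pd.Series | None = None,
    individual_ids: pd.Series | None = None,
    cr: pd.Series | None = None,
    noise_sd: dict | None = None,
    base_half_width: dict | None = None,
) -> pd.DataFrame:
    """Degrade true ages into catalogue records (Age_best, range, CR).

    The range [Age_min, Age_max] always contains the true age (it is a
    100%-confidence bound) and Age_min <= Age_best <= Age_max; ranges
    widen as CR decreases and age increases.  ``noise_sd`` and
    ``base_half_width`` override the per-CR defaults.
    """
    if (true_ages < 0).any():
        raise ValueError("true ages must be >= 0")
    noise_sd = noise_sd or CR_NOISE_SD
    base_half_width = base_half_width or CR_BASE_HALF_WIDTH
    records = []
    for sid, age in true_ages.items():
        rating = int(cr.loc[sid]) if cr is not None else _assign_cr(age, rng)
        sd = noise_sd[rating]
        half = base_half_width[rating] * (1.0 + age / 25.0)
        best = age + (rng.normal(scale=sd) if sd > 0 else 0.0)
        lo = min(age, best) - half * rng.uniform(0.7, 1.3)
        hi = max(age, best) + half * rng.uniform(0.7, 1.3)
        lo = max(0.0, lo)
        best = float(np.clip(best, lo + 1e-3, hi - 1e-3))
        records.append(
            {
                "sample_id": sid,
                "individual_id": (
                    individual_ids.loc[sid] if individual_ids is not None else sid
                ),
                "collection_date": (
                    collection_dates.loc[sid]
                    if collection_dates is not None
                    else "2020-01-01"
                ),
                "age_best": round(best, 2),
                "age_min": round(lo, 2),
                "age_max": round(hi, 2),
                "cr": rating,
            }
        )
    return pd.DataFrame(records)


def generate_cohort(
    spec: SynthSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SiteTruth]:
    """Generate (count table, true ages, age records, site truth).

    Read-level model per CpG site: a read is a sequencing error (A or G)
    with probability ``error_rate``; otherwise it reports C if the
    genome copy is methylated (probability p) or, if unmethylated, fails
    bisulfite conversion with probability 1 - P_v (also reporting C) and
    otherwise reports T.  The conversion-efficiency correction therefore
    recovers p exactly in expectation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- individuals, resampled pairs, true ages -----------------------
    age_lo, age_hi = spec.age_range
    individuals = [f"I{i:03d}" for i in range(spec.n_individuals)]
    first_ages = rng.uniform(age_lo, age_hi, size=spec.n_individuals)
    base_year = 2005.0
    sample_rows = []
    for ind, age in zip(individuals, first_ages):
        sample_rows.append((ind, age, base_year))
    if spec.n_pairs > spec.n_individuals:
        raise ValueError("more pairs than individuals")
    paired = rng.choice(spec.n_individuals, size=spec.n_pairs, replace=False)
    for idx in paired:
        gap = rng.uniform(*spec.pair_gap_range)
        ind = individuals[idx]
        sample_rows.append((ind, first_ages[idx] + gap, base_year + gap))

    sample_ids, true_ages, individual_ids, dates = [], {}, {}, {}
    for k, (ind, age, year) in enumerate(sample_rows):
        sid = f"S{k:03d}"
        sample_ids.append(sid)
        true_ages[sid] = age
        individual_ids[sid] = ind
        frac = year % 1.0
        dates[sid] = f"{int(year)}-{int(1 + frac * 12):02d}-15"
    true_ages = pd.Series(true_ages, name="true_age")

    # --- site parameters ----------------------------------------------
    loci = [f"L{i}" for i in range(spec.n_loci)]
    site_meta = []
    for li, locus in enumerate(loci):
        for p in range(spec.sites_per_locus):
            site_meta.append((locus, p * 10))  # CpG positions spaced 10 bp
    clock_idx = rng.choice(len(site_meta), size=spec.n_clock_sites, replace=False)
    is_clock = np.zeros(len(site_meta), dtype=bool)
    is_clock[clock_idx] = True
    slopes = np.zeros(len(site_meta))
    intercepts = np.zeros(len(site_meta))
    mid_age = 0.5 * (age_lo + age_hi)
    for j in range(len(site_meta)):
        if is_clock[j]:
            slope = rng.uniform(*spec.slope_range) * rng.choice([-1.0, 1.0])
            centre = rng.uniform(*spec.intercept_range)
            slopes[j] = slope
            # anchor the mid-age methylation so extremes stay in (0, 1)
            intercepts[j] = centre - slope * mid_age
        else:
            slopes[j] = 0.0
            intercepts[j] = rng.uniform(*spec.null_level_range)
    truth_table = pd.DataFrame(
        {
            "site_id": [f"{l}_{p}" for l, p in site_meta],
            "locus": [l for l, _ in site_meta],
            "position": [p for _, p in site_meta],
            "is_clock": is_clock,
            "intercept": intercepts,
            "slope": slopes,
        }
    )

    # --- read counts (vectorised over samples x sites) -----------------
    n_samp = len(sample_ids)
    ages_vec = true_ages.to_numpy()
    p_v_vec = rng.uniform(*spec.conversion_range, size=n_samp)

    def _read_counts(depth, p_c):
        """Split depths into (A, C, G, T) with errors injected first."""
        n_err = rng.binomial(depth, spec.error_rate)
        n_a = rng.binomial(n_err, 0.5)
        n_good = depth - n_err
        n_c = rng.binomial(n_good, p_c)
        return n_a, n_c, n_err - n_a, n_good - n_c

    # CpG sites: methylated or conversion-failed copies both read as C
    n_cpg = len(site_meta)
    depth = rng.integers(
        spec.depth_range[0], spec.depth_range[1] + 1, size=(n_samp, n_cpg)
    )
    eta = intercepts[None, :] + slopes[None, :] * ages_vec[:, None]
    if spec.site_noise_sd > 0:
        eta = eta + rng.normal(scale=spec.site_noise_sd, size=eta.shape)
    p_meth = expit(eta)
    p_c = p_meth + (1.0 - p_meth) * (1.0 - p_v_vec[:, None])
    cpg_a, cpg_c, cpg_g, cpg_t = _read_counts(depth, p_c)

    # non-CpG cytosine control sites: unmethylated, C reads = failures
    ctrl_meta = [
        (locus, 1005 + 7 * i)
        for locus in loci
        for i in range(spec.n_control_per_locus)
    ]
    n_ctrl = len(ctrl_meta)
    depth_ctrl = rng.integers(
        spec.depth_range[0], spec.depth_range[1] + 1, size=(n_samp, n_ctrl)
    )
    p_fail = np.broadcast_to((1.0 - p_v_vec)[:, None], (n_samp, n_ctrl))
    ctl_a, ctl_c, ctl_g, ctl_t = _read_counts(depth_ctrl, p_fail)

    def _long(meta, site_class, n_a, n_c, n_g, n_t):
        n_sites = len(meta)
        return pd.DataFrame(
            {
                "sample_id": np.repeat(sample_ids, n_sites),
                "locus": np.tile([l for l, _ in meta], n_samp),
                "position": np.tile([p for _, p in meta], n_samp),
                "site_class": site_class,
                "n_A": n_a.ravel(),
                "n_C": n_c.ravel(),
                "n_G": n_g.ravel(),
                "n_T": n_t.ravel(),
            }
        )

    counts = pd.concat(
        [
            _long(site_meta, CPG, cpg_a, cpg_c, cpg_g, cpg_t),
            _long(ctrl_meta, NONCPG_C, ctl_a, ctl_c, ctl_g, ctl_t),
        ],
        ignore_index=True,
    )[TABLE_COLUMNS]

    age_records = degrade_ages(
        true_ages,
        rng,
        collection_dates=pd.Series(dates),
        individual_ids=pd.Series(individual_ids),
    )
    return counts, true_ages, age_records, SiteTruth(truth_table)
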