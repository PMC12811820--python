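import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiage import age_prior, uncertainty
from epiage.clocks import ClockConfig
from epiage.search import evaluate_loo
from epiage.uncertainty import (
    build_pair_registry,
    hdi,
    hdi_coverage,
    pair_ordinality,
    resample_methylation,
    resample_replicate,
    run_resampling,
)


def hdi_exhaustive(draws, mass=0.95):
    """Oracle: enumerate every window of ceil(mass * n) sorted draws."""
    s = np.sort(np.asarray(draws, dtype=float))
    n = len(s)
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    best = None
    for i in range(n - k + 1):
        width = s[i + k - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + k - 1])
    return float(best[1]), float(best[2])


class TestHDI:
    def test_constant_draws(self):
        assert hdi([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_uniform_width(self, rng):
        draws = rng.uniform(0, 1, 10_000)
        lo, hi = hdi(draws, 0.95)
        assert abs((hi - lo) - 0.95) < 0.02

    def test_outlier_window(self):
        draws = [1.0] * 9 + [100.0]
        assert hdi(draws, mass=0.9) == (1.0, 1.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 201))
            draws = rng.normal(size=n) * rng.uniform(0.1, 10)
            assert hdi(draws, 0.95) == hdi_exhaustive(draws, 0.95)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=60),
        st.floats(0.1, 1.0),
    )
    @settings(max_examples=150)
    def test_oracle_equivalence_property(self, draws, mass):
        assert hdi(draws, mass) == hdi_exhaustive(draws, mass)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hdi([1.0])


class TestResampleReplicate:
    def test_large_coverage_concentrates(self, rng):
        from epiage.methyl import MethylationMatrix

        k = 10**6
        n_m = 300_000
        counts = pd.DataFrame(
            {
                "sample_id": ["s"],
                "site_id": ["L_0"],
                "locus": ["L"],
                "n_m": [n_m],
                "K_m": [k],
            }
        )
        qc = pd.DataFrame(
            {"conversion_efficiency": [1.0]}, index=pd.Index(["s"], name="sample_id")
        )
        mat = MethylationMatrix(
            m=pd.DataFrame({"L_0": [0.0]}, index=["s"]),
            p_hat=pd.DataFrame({"L_0": [0.3]}, index=["s"]),
            counts=counts,
            sample_qc=qc,
            site_locus=pd.Series({"L_0": "L"}),
        )
        from scipy.special import expit

        m_star = resample_methylation(mat, rng)
        p_star = expit(m_star.iloc[0, 0])
        p = n_m / k
        assert abs(p_star - p) < 3 * np.sqrt(p * (1 - p) / k)

    def test_zero_counts_fall_to_half_lowest(self, small_cohort):
        from scipy.special import expit

        matrix = small_cohort["matrix"]
        counts = matrix.counts.copy()
        # zero out one cell; its replicate draw is deterministically zero and
        # the corrected value is <= 0, so the half-lowest rule must fire
        counts.loc[0, "n_m"] = 0
        from dataclasses import replace

        mat0 = replace(matrix, counts=counts)
        sid, site, locus = counts.loc[0, ["sample_id", "site_id", "locus"]]
        locus_sites = list(matrix.site_locus.index[matrix.site_locus == locus])
        for seed in (1, 2):
            m_star = resample_methylation(mat0, np.random.default_rng(seed))
            cell = float(m_star.loc[sid, site])
            assert np.isfinite(cell)
            # half the smallest positive corrected value at the locus
            others = expit(
                m_star.loc[:, [c for c in locus_sites if c != site]].to_numpy()
            )
            assert expit(cell) <= 0.5 * others.min() + 1e-12

    def test_binomial_mean_recovered(self, rng):
        draws = rng.binomial(1000, 0.3, size=2000) / 1000
        assert abs(draws.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 1000 / 2000) * 50

    def test_ages_drawn_from_priors(self, small_cohort, rng):
        matrix = small_cohort["matrix"]
        priors = age_prior.fit_priors(small_cohort["records"])
        ages, m_star = resample_replicate(matrix, priors, rng)
        assert set(ages.index) == set(matrix.sample_ids)
        assert (ages >= 0).all()
        assert m_star.shape == matrix.m.shape


@pytest.fixture(scope="module")
def resampling_run(small_cohort, desk_settings):
    X, ages, cr = small_cohort["X"], small_cohort["age_best"], small_cohort["cr"]
    priors = age_prior.fit_priors(small_cohort["records"])
    _, clock = evaluate_loo(
        ClockConfig(method="ENR", training_samples="CR4+"),
        X,
        ages,
        cr,
        settings=desk_settings,
        seed=0,
    )
    result = run_resampling(
        small_cohort["matrix"], priors, clock, cr, n_reps=60, seed=1
    )
    return result


class TestRunResampling:
    def test_reproducible(self, small_cohort, desk_settings, resampling_run):
        X, ages, cr = (
            small_cohort["X"],
            small_cohort["age_best"],
            small_cohort["cr"],
        )
        priors = age_prior.fit_priors(small_cohort["records"])
        _, clock = evaluate_loo(
            ClockConfig(method="ENR", training_samples="CR4+"),
            X,
            ages,
            cr,
            settings=desk_settings,
            seed=0,
        )
        again = run_resampling(
            small_cohort["matrix"], priors, clock, cr, n_reps=60, seed=1
        )
        pd.testing.assert_frame_equal(again.draws, resampling_run.draws)

    def test_draws_within_clamp(self, resampling_run):
        draws = resampling_run.draws.to_numpy()
        assert ((draws >= 0) & (draws <= 80)).all()

    def test_hdi_summaries_consistent(self, resampling_run):
        for dist in resampling_run.distributions.values():
            assert dist.hdi_lower <= dist.median <= dist.hdi_upper or (
                dist.hdi_lower <= dist.hdi_upper
            )
            lo, hi = hdi(dist.draws, 0.95)
            assert (lo, hi) == (dist.hdi_lower, dist.hdi_upper)

    def test_requires_two_reps(self, small_cohort):
        with pytest.raises(ValueError):
            run_resampling(small_cohort["matrix"], {}, None, None, n_reps=1)

    def test_true_age_coverage_reasonable(self, resampling_run, small_cohort):
        cov = hdi_coverage(
            resampling_run.distributions, small_cohort["true_ages"]
        )
        assert cov > 0.6  # calibration checked properly at acceptance scale


class TestCoverage:
    def _dists(self, bounds):
        from epiage.uncertainty import PredictionDistribution

        return {
            f"s{i}": PredictionDistribution(
                sample_id=f"s{i}",
                draws=np.array([lo, hi]),
                hdi_lower=lo,
                hdi_upper=hi,
                median=(lo + hi) / 2,
                mode=(lo + hi) / 2,
            )
            for i, (lo, hi) in enumerate(bounds)
        }

    def test_full_interval_covers_everything(self):
        dists = self._dists([(0.0, 80.0)] * 4)
        ages = pd.Series({f"s{i}": 10.0 * i for i in range(4)})
        assert hdi_coverage(dists, ages) == 1.0

    def test_empty_intervals_cover_nothing(self):
        dists = self._dists([(50.0, 60.0)] * 4)
        ages = pd.Series({f"s{i}": 5.0 for i in range(4)})
        assert hdi_coverage(dists, ages) == 0.0

    def test_partial_coverage_fraction(self):
        bounds = [(0.0, 20.0)] * 7 + [(50.0, 60.0)] * 3
        dists = self._dists(bounds)
        ages = pd.Series({f"s{i}": 10.0 for i in range(10)})
        assert hdi_coverage(dists, ages) == 0.7


class TestPairOrdinality:
    def _draws(self, rows):
        return pd.DataFrame(rows)

    def _registry(self, gap=5.0):
        return pd.DataFrame(
            {
                "individual_id": ["i1"],
                "earlier_sample": ["a"],
                "later_sample": ["b"],
                "true_gap_years": [gap],
            }
        )

    def test_always_older_is_certain(self):
        draws = self._draws({0: {"a": 10.0, "b": 15.0}, 1: {"a": 12.0, "b": 17.0}}).T
        draws = pd.DataFrame(
            {"a": [10.0, 12.0], "b": [15.0, 17.0]}
        ).T
        pairs = pair_ordinality(draws, self._registry())
        assert pairs[0].proportion_correct == 1.0
        assert pairs[0].correct

    def test_ties_count_as_incorrect(self):
        draws = pd.DataFrame({"a": [10.0, 12.0], "b": [10.0, 12.0]}).T
        pairs = pair_ordinality(draws, self._registry())
        assert pairs[0].proportion_correct == 0.0
        assert not pairs[0].correct

    def test_nonpositive_gap_rejected(self):
        draws = pd.DataFrame({"a": [1.0], "b": [2.0]}).T
        with pytest.raises(ValueError, match="gap"):
            pair_ordinality(draws, self._registry(gap=0.0))

    def test_registry_from_age_records(self, small_cohort):
        registry = build_pair_registry(small_cohort["records"])
        assert len(registry) == small_cohort["spec"].n_pairs
        assert (registry["true_gap_years"] > 0).all()

    def test_realistic_pair_mostly_correct(self, resampling_run, small_cohort):
        registry = build_pair_registry(small_cohort["records"])
        big_gaps = registry[registry["true_gap_years"] >= 4]
        pairs = pair_ordinality(resampling_run.draws, big_gaps)
        assert all(p.proportion_correct > 0.7 for p in pairs)


class TestMonotoneUncertainty:
    def test_wider_prior_never_shrinks_hdi(self, small_cohort, desk_settings):
        X, ages, cr = (
            small_cohort["X"],
            small_cohort["age_best"],
            small_cohort["cr"],
        )
        _, clock = evaluate_loo(
            ClockConfig(method="ENR"), X, ages, cr, settings=desk_settings, seed=0
        )
        records = small_cohort["records"]
        priors_narrow = age_prior.fit_priors(records)
        wide = records.copy()
        wide["age_min"] = (wide["age_min"] - 5).clip(lower=0)
        wide["age_max"] = wide["age_max"] + 10
        priors_wide = age_prior.fit_priors(wide)
        widths = []
        for priors in (priors_narrow, priors_wide):
            res = run_resampling(
                small_cohort["matrix"], priors, clock, cr, n_reps=40, seed=2
            )
            widths.append(
                np.median(
                    [
                        d.hdi_upper - d.hdi_lower
                        for d in res.distributions.values()
                    ]
                )
            )
        assert widths[1] >= widths[0]
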