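import numpy as np
import pandas as pd
import pytest

from epiage import methyl, simulate
from epiage.clocks import TuningSettings


@pytest.fixture(scope="session")
def desk_settings():
    return TuningSettings.desk()


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared across modelling tests."""
    spec = simulate.SynthSpec(
        n_individuals=40,
        n_pairs=5,
        n_loci=4,
        sites_per_locus=10,
        n_clock_sites=12,
        n_control_per_locus=10,
        depth_range=(1500, 4000),
        seed=11,
    )
    counts, true_ages, records, truth = simulate.generate_cohort(spec)
    matrix, report = methyl.build_methylation_matrix(counts)
    ages = records.set_index("sample_id")
    return {
        "spec": spec,
        "counts": counts,
        "true_ages": true_ages,
        "records": records,
        "truth": truth,
        "matrix": matrix,
        "report": report,
        "X": matrix.m.loc[ages.index],
        "age_best": ages["age_best"],
        "cr": ages["cr"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_count_row(sample, locus, pos, site_class, n_a=0, n_c=0, n_g=0, n_t=0):
    return {
        "sample_id": sample,
        "locus": locus,
        "position": pos,
        "site_class": site_class,
        "n_A": n_a,
        "n_C": n_c,
        "n_G": n_g,
        "n_T": n_t,
    }


@pytest.fixture(scope="session")
def qc_fixture_table():
    """10 samples x 5 CpG sites with hand-placed QC failures.

    Depths are arranged so that sample s1 has median depth 900 (below
    1000), site L_c3 has median depth 500 among the remaining samples,
    and sample s2 has only 80 reads at site L_c1.
    """
    rows = []
    samples = [f"s{i}" for i in range(10)]
    sites = [("L", i) for i in range(5)]  # positions 0..4 -> L_0..L_4
    for s in samples:
        for locus, pos in sites:
            depth = 2000
            if s == "s1":
                depth = 900  # median across sites = 900 -> stage 1
            elif pos == 3:
                depth = 500  # site median 500 among survivors -> stage 2
            elif s == "s2" and pos == 1:
                depth = 80  # below per-site minimum -> stage 3
            rows.append(
                make_count_row(
                    s, locus, pos, methyl.CPG, n_c=depth // 2, n_t=depth - depth // 2
                )
            )
        # control sites so conversion efficiency is defined
        rows.append(make_count_row(s, "L", 100, methyl.NONCPG_C, n_t=995, n_c=5))
    return pd.DataFrame(rows)
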