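"""Methylation quantification from per-site nucleotide read counts.

Input is a long-format table with one row per (sample, locus, position)
carrying A/C/G/T read counts at CpG sites and non-CpG cytosine control
sites.  Output is a samples x sites matrix of logit-scale methylation,
corrected for per-sample bisulfite conversion efficiency, together with
the raw (n_m, K_m) counts retained for downstream resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit as _logit

CPG = "CpG"
NONCPG_C = "nonCpG_C"
SITE_CLASSES = (CPG, NONCPG_C)

COUNT_COLUMNS = ["n_A", "n_C", "n_G", "n_T"]
TABLE_COLUMNS = ["sample_id", "locus", "position", "site_class"] + COUNT_COLUMNS

#: QC thresholds used in the reference analysis.
DEFAULT_SAMPLE_MEDIAN_DEPTH = 1000
DEFAULT_SITE_MEDIAN_DEPTH = 1000
DEFAULT_PER_SITE_MIN_DEPTH = 100


class MissingControlSitesError(ValueError):
    """Raised when a sample has no covered non-CpG cytosine control sites."""


class DegenerateLocusError(ValueError):
    """Raised when a locus has no strictly positive corrected methylation."""


def site_id(locus, position) -> str:
    return f"{locus}_{position}"


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a site-count table and return it with normalised dtypes.

    Checks required columns, non-negative integer counts, key uniqueness
    and that ``site_class`` is constant per (locus, position).
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    table = table.copy()
    for col in COUNT_COLUMNS + ["position"]:
        vals = pd.to_numeric(table[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"negative values in column {col!r}")
        table[col] = vals.astype(np.int64)
    bad_class = set(table["site_class"]) - set(SITE_CLASSES)
    if bad_class:
        raise ValueError(f"unknown site_class values: {sorted(bad_class)}")
    key = ["sample_id", "locus", "position"]
    if table.duplicated(key).any():
        dup = table[table.duplicated(key, keep=False)][key].head()
        raise ValueError(f"duplicate (sample, locus, position) keys, e.g.\n{dup}")
    per_site = table.groupby(["locus", "position"])["site_class"].nunique()
    if (per_site > 1).any():
        raise ValueError("site_class differs across samples for some site")
    return table


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV/CSV site-count table (delimiter chosen by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return validate_count_table(pd.read_csv(path, sep=sep))


def corrected_coverage(n_a, n_c, n_g, n_t):
    """Coverage after discarding A/G reads (treated as sequencing errors).

    Equals ``n_C + n_T`` exactly; zero when only error reads are present.
    """
    n_a, n_c, n_g, n_t = (np.asarray(x) for x in (n_a, n_c, n_g, n_t))
    if (n_a < 0).any() or (n_c < 0).any() or (n_g < 0).any() or (n_t < 0).any():
        raise ValueError("read counts must be non-negative")
    total = n_a + n_c + n_g + n_t
    out = total - (n_a + n_g)
    return out if out.ndim else out.item()


def conversion_efficiency(sample_rows: pd.DataFrame) -> float:
    """Per-sample bisulfite conversion efficiency from non-CpG cytosines.

    P_v = total T reads / total corrected coverage over the sample's
    non-CpG cytosine sites (these are assumed unmethylated, so T reads
    are correctly converted reads).
    """
    ctrl = sample_rows[sample_rows["site_class"] == NONCPG_C]
    k = corrected_coverage(ctrl["n_A"], ctrl["n_C"], ctrl["n_G"], ctrl["n_T"])
    k_total = int(np.sum(k))
    if k_total == 0:
        raise MissingControlSitesError(
            "no covered non-CpG cytosine control sites for sample"
        )
    return float(ctrl["n_T"].sum() / k_total)


def sequencing_error_rate(rows: pd.DataFrame) -> float:
    """Fraction of A/G reads among all reads at cytosine sites."""
    total = int(rows[COUNT_COLUMNS].to_numpy().sum())
    if total == 0:
        raise ValueError("no reads: sequencing error rate undefined")
    errors = int(rows["n_A"].sum() + rows["n_G"].sum())
    return errors / total


def correct_methylation(p_m, p_v, locus_min_positive=None):
    """Conversion-efficiency-corrected methylation probability.

    P_hat = 1 - (1 - P_m) / P_v.  When P_v <= 1 - P_m this is <= 0 and is
    replaced by half the smallest strictly positive corrected value seen
    at the same locus (``locus_min_positive``).
    """
    if not 0 <= p_m <= 1:
        raise ValueError(f"P_m={p_m} outside [0, 1]")
    if not 0 < p_v <= 1:
        raise ValueError(f"P_v={p_v} outside (0, 1]")
    p_hat = 1.0 - (1.0 - p_m) / p_v
    if p_hat > 0:
        return p_hat
    if locus_min_positive is None or locus_min_positive <= 0:
        raise DegenerateLocusError(
            "non-positive corrected methylation and no positive locus minimum"
        )
    return 0.5 * locus_min_positive


def logit_methylation(p_hat):
    """logit(P_hat); requires P_hat strictly inside (0, 1)."""
    p_hat = np.asarray(p_hat, dtype=float)
    if np.any(p_hat <= 0) or np.any(p_hat >= 1):
        raise ValueError("P_hat must lie strictly in (0, 1) before logit")
    out = _logit(p_hat)
    return out if out.ndim else out.item()


def _correct_frame(cells: pd.DataFrame) -> pd.Series:
    """Apply the corrected-methylation rule to a long frame of cells.

    ``cells`` needs columns locus, p_m, p_v.  Cells with non-positive raw
    corrected values borrow half the smallest positive corrected value at
    their locus; the symmetric rule shrinks P_hat == 1 below one so the
    logit stays finite.
    """
    raw = 1.0 - (1.0 - cells["p_m"]) / cells["p_v"]
    pos = raw[raw > 0]
    if pos.empty:
        raise DegenerateLocusError("no positive corrected methylation anywhere")
    locus_min = pos.groupby(cells.loc[pos.index, "locus"]).min()
    # ceiling analogue for P_hat == 1: smallest positive (1 - P_hat) per locus
    below_one = raw[raw < 1]
    locus_max_gap = (
        (1.0 - below_one[below_one > 0])
        .groupby(cells.loc[below_one[below_one > 0].index, "locus"])
        .min()
    )
    out = raw.copy()
    low = raw <= 0
    if low.any():
        repl = cells.loc[low, "locus"].map(locus_min)
        if repl.isna().any():
            bad = sorted(cells.loc[low, "locus"][repl.isna()].unique())
            raise DegenerateLocusError(
                f"loci with no positive corrected methylation: {bad}"
            )
        out[low] = 0.5 * repl
    high = raw >= 1
    if high.any():
        repl = cells.loc[high, "locus"].map(locus_max_gap)
        if repl.isna().any():
            bad = sorted(cells.loc[high, "locus"][repl.isna()].unique())
            raise DegenerateLocusError(
                f"loci with no corrected methylation below one: {bad}"
            )
        out[high] = 1.0 - 0.5 * repl
    return out


@dataclass
class FilterReport:
    """Record of the three sequential QC filter stages."""

    samples_removed_low_median_depth: list = field(default_factory=list)
    sites_removed_low_median_depth: list = field(default_factory=list)
    samples_removed_low_site_coverage: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, items in [
            ("sample_low_median_depth", self.samples_removed_low_median_depth),
            ("site_low_median_depth", self.sites_removed_low_median_depth),
            ("sample_low_site_coverage", self.samples_removed_low_site_coverage),
        ]:
            rows.extend({"stage": stage, "removed": x} for x in items)
        return pd.DataFrame(rows, columns=["stage", "removed"])


@dataclass
class MethylationMatrix:
    """Logit-scale methylation with the raw counts kept for resampling."""

    m: pd.DataFrame  # samples x sites, logit(P_hat)
    p_hat: pd.DataFrame  # samples x sites, corrected probabilities
    counts: pd.DataFrame  # long: sample_id, site_id, locus, n_m, K_m
    sample_qc: pd.DataFrame  # sample_id-indexed QC statistics
    site_locus: pd.Series  # site_id -> locus

    @property
    def sample_ids(self):
        return list(self.m.index)

    @property
    def site_ids(self):
        return list(self.m.columns)


def qc_filter(
    depth: pd.DataFrame,
    sample_median_threshold: float = DEFAULT_SAMPLE_MEDIAN_DEPTH,
    site_median_threshold: float = DEFAULT_SITE_MEDIAN_DEPTH,
    per_site_min: float = DEFAULT_PER_SITE_MIN_DEPTH,
) -> tuple[list, list, FilterReport]:
    """Three-stage depth filter on a samples x CpG-sites coverage matrix.

    Stage 1 drops samples whose median depth across all sites is below
    ``sample_median_threshold``; stage 2 drops sites whose median depth
    across the remaining samples is below ``site_median_threshold``;
    stage 3 drops samples with any remaining site below ``per_site_min``.
    Returns (kept sample ids, kept site ids, report).
    """
    if min(sample_median_threshold, site_median_threshold, per_site_min) < 0:
        raise ValueError("thresholds must be >= 0")
    report = FilterReport(
        thresholds={
            "sample_median_threshold": sample_median_threshold,
            "site_median_threshold": site_median_threshold,
            "per_site_min": per_site_min,
        }
    )
    d = depth.fillna(0.0)

    sample_median = d.median(axis=1)
    drop1 = sample_median[sample_median < sample_median_threshold].index
    report.samples_removed_low_median_depth = sorted(drop1)
    d = d.drop(index=drop1)

    if len(d):
        site_median = d.median(axis=0)
        drop2 = site_median[site_median < site_median_threshold].index
    else:
        drop2 = d.columns
    report.sites_removed_low_median_depth = sorted(drop2)
    d = d.drop(columns=drop2)

    if len(d.columns):
        bad = d.lt(per_site_min).any(axis=1)
        drop3 = d.index[bad]
    else:
        drop3 = []
    report.samples_removed_low_site_coverage = sorted(drop3)
    d = d.drop(index=drop3)

    if d.empty:
        warnings.warn("QC filter removed every sample or site", stacklevel=2)
    return list(d.index), list(d.columns), report


def sample_qc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample conversion efficiency, error rate and median CpG depth."""
    records = []
    for sample, rows in table.groupby("sample_id", sort=True):
        cpg = rows[rows["site_class"] == CPG]
        depth = corrected_coverage(cpg["n_A"], cpg["n_C"], cpg["n_G"], cpg["n_T"])
        records.append(
            {
                "sample_id": sample,
                "conversion_efficiency": conversion_efficiency(rows),
                "sequencing_error_rate": sequencing_error_rate(rows),
                "median_cpg_depth": float(np.median(depth)) if len(cpg) else 0.0,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def build_methylation_matrix(
    table: pd.DataFrame,
    sample_median_threshold: float = DEFAULT_SAMPLE_MEDIAN_DEPTH,
    site_median_threshold: float = DEFAULT_SITE_MEDIAN_DEPTH,
    per_site_min: float = DEFAULT_PER_SITE_MIN_DEPTH,
) -> tuple[MethylationMatrix, FilterReport]:
    """Full quantification pipeline: counts -> filtered logit matrix."""
    table = validate_count_table(table)
    qc = sample_qc_table(table)

    cpg = table[table["site_class"] == CPG].copy()
    cpg["site_id"] = [site_id(l, p) for l, p in zip(cpg["locus"], cpg["position"])]
    cpg["K_m"] = corrected_coverage(cpg["n_A"], cpg["n_C"], cpg["n_G"], cpg["n_T"])
    cpg["n_m"] = cpg["n_C"]

    depth = cpg.pivot(index="sample_id", columns="site_id", values="K_m")
    keep_samples, keep_sites, report = qc_filter(
        depth, sample_median_threshold, site_median_threshold, per_site_min
    )

    cells = cpg[
        cpg["sample_id"].isin(keep_samples) & cpg["site_id"].isin(keep_sites)
    ].copy()
    if cells.empty:
        empty = pd.DataFrame()
        mat = MethylationMatrix(
            m=empty,
            p_hat=empty,
            counts=cells[["sample_id", "site_id", "locus", "n_m", "K_m"]],
            sample_qc=qc,
            site_locus=pd.Series(dtype=object),
        )
        return mat, report
    if (cells["K_m"] <= 0).any():
        # zero corrected coverage should have been caught by per_site_min > 0
        bad = cells[cells["K_m"] <= 0][["sample_id", "site_id"]]
        raise ValueError(f"zero corrected coverage at retained cells:\n{bad}")

    cells["p_m"] = cells["n_m"] / cells["K_m"]
    cells["p_v"] = cells["sample_id"].map(qc["conversion_efficiency"])
    cells["p_hat"] = _correct_frame(cells)
    cells["m"] = logit_methylation(cells["p_hat"].to_numpy())

    m = cells.pivot(index="sample_id", columns="site_id", values="m")
    p_hat = cells.pivot(index="sample_id", columns="site_id", values="p_hat")
    m = m.loc[keep_samples, keep_sites]
    p_hat = p_hat.loc[keep_samples, keep_sites]
    site_locus = (
        cells[["site_id", "locus"]].drop_duplicates().set_index("site_id")["locus"]
    ).loc[keep_sites]

    counts = cells[["sample_id", "site_id", "locus", "n_m", "K_m"]].reset_index(
        drop=True
    )
    mat = MethylationMatrix(
        m=m,
        p_hat=p_hat,
        counts=counts,
        sample_qc=qc.loc[keep_samples],
        site_locus=site_locus,
    )
    return mat, report
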