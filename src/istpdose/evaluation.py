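"""Benchmarking single-time-point estimators against the MTP reference.

The headline metric is the relative absolute difference

    RAD = |theta_STP / theta_MTP - 1| * 100%

for TIA or absorbed dose, aggregated per organ by early scan time
(2, 20, 43, 69 h) or by therapy cycle group (1, 2, 3, >=4).  Paired method
comparisons use the Wilcoxon signed-rank test, unpaired ones the
Mann–Whitney U test, both two-sided at P < 0.05, with exact small-sample
p-values (full enumeration) below a configurable size and the standard
tie-corrected normal approximation above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EARLY_TIMEPOINTS_HOURS = (2.0, 20.0, 43.0, 69.0)
CYCLE_GROUPS = ("1", "2", "3", ">=4")
SIGNIFICANCE_LEVEL = 0.05


class UndefinedReferenceError(ValueError):
    """The MTP reference is non-positive, so a relative difference is undefined."""


def rad(theta_stp: float, theta_mtp: float, *, signed: bool = False) -> float:
    """Relative (absolute) difference in percent against the MTP reference."""
    if theta_mtp <= 0:
        raise UndefinedReferenceError(
            f"reference must be positive for a defined RAD, got {theta_mtp}"
        )
    rel = (theta_stp / theta_mtp - 1.0) * 100.0
    return rel if signed else abs(rel)


def comparison_records(
    stp_table: pd.DataFrame, mtp_table: pd.DataFrame, value_col: str = "tia_MBq_h"
) -> pd.DataFrame:
    """Join STP estimates to their MTP reference and attach RAD.

    ``stp_table`` needs (patient_id, cycle, organ, t_sc_hours, method,
    value_col); ``mtp_table`` needs (patient_id, cycle, organ, value_col).
    Records without a matching reference are dropped with a log line;
    references of exactly 0 are excluded (RAD undefined) with a logged
    count.
    """
    keys = ["patient_id", "cycle", "organ"]
    ref = mtp_table[keys + [value_col]].rename(columns={value_col: "theta_mtp"})
    merged = stp_table.merge(ref, on=keys, how="left")
    n_unmatched = int(merged["theta_mtp"].isna().sum())
    if n_unmatched:
        log.info("comparison_records: %d STP records without MTP reference dropped", n_unmatched)
        merged = merged.dropna(subset=["theta_mtp"])
    n_zero = int((merged["theta_mtp"] <= 0).sum())
    if n_zero:
        log.info("comparison_records: %d records with non-positive reference excluded", n_zero)
        merged = merged[merged["theta_mtp"] > 0]
    merged = merged.rename(columns={value_col: "theta_stp"})
    merged["rad_percent"] = np.abs(merged["theta_stp"] / merged["theta_mtp"] - 1.0) * 100.0
    merged["rad_signed_percent"] = (merged["theta_stp"] / merged["theta_mtp"] - 1.0) * 100.0
    return merged.reset_index(drop=True)


def timepoint_dependency_table(
    records: pd.DataFrame,
    timepoints: tuple[float, ...] = EARLY_TIMEPOINTS_HOURS,
) -> pd.DataFrame:
    """Per-(organ, method, t_sc) mean +/- SD RAD over the early scan times.

    Hänscheid rows at 2 h are flagged ``out_of_method`` — that scan time
    predates its validity window and is reported for reference only.
    """
    sub = records[records["t_sc_hours"].isin(timepoints)]
    rows = []
    for (organ, method, t_sc), grp in sub.groupby(
        ["organ", "method", "t_sc_hours"], sort=True
    ):
        vals = grp["rad_percent"].to_numpy()
        rows.append(
            {
                "organ": organ,
                "method": method,
                "t_sc_hours": t_sc,
                "n": len(vals),
                "rad_mean_percent": float(np.mean(vals)),
                "rad_sd_percent": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "out_of_method": bool(method == "hanscheid" and t_sc == 2.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "organ", "method", "t_sc_hours", "n",
            "rad_mean_percent", "rad_sd_percent", "out_of_method",
        ],
    )


def cycle_group(cycle: int) -> str:
    """Map a cycle index onto the reporting bins 1, 2, 3, >=4."""
    return str(cycle) if cycle < 4 else ">=4"


def cycle_dependency_table(
    records_per_cycle: pd.DataFrame, records_first_cycle: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cycle-group RAD summaries for the two prediction scenarios.

    Both inputs are comparison-record frames; they must cover identical
    (patient, cycle, organ, t_sc) keys.  Returns the grouped summary table
    and a per-group Mann–Whitney comparison of the two scenarios' RAD
    distributions.  Empty groups are omitted with a log line.
    """
    keys = ["patient_id", "cycle", "organ", "t_sc_hours"]
    k1 = set(map(tuple, records_per_cycle[keys].to_numpy().tolist()))
    k2 = set(map(tuple, records_first_cycle[keys].to_numpy().tolist()))
    if k1 != k2:
        offenders = sorted(k1.symmetric_difference(k2))[:10]
        raise ValueError(
            f"scenario record keys differ; first offenders: {offenders}"
        )
    summaries = []
    tests = []
    for label, recs in (
        ("per_cycle", records_per_cycle),
        ("first_cycle_only", records_first_cycle),
    ):
        recs = recs.copy()
        recs["cycle_group"] = recs["cycle"].map(cycle_group)
        for (organ, grp_name), grp in recs.groupby(["organ", "cycle_group"], sort=True):
            vals = grp["rad_percent"].to_numpy()
            summaries.append(
                {
                    "scenario": label,
                    "organ": organ,
                    "cycle_group": grp_name,
                    "n": len(vals),
                    "rad_mean_percent": float(np.mean(vals)),
                    "rad_sd_percent": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    for grp_name in CYCLE_GROUPS:
        for organ in sorted(records_per_cycle["organ"].unique()):
            a = records_per_cycle[
                (records_per_cycle["organ"] == organ)
                & (records_per_cycle["cycle"].map(cycle_group) == grp_name)
            ]["rad_percent"].to_numpy()
            b = records_first_cycle[
                (records_first_cycle["organ"] == organ)
                & (records_first_cycle["cycle"].map(cycle_group) == grp_name)
            ]["rad_percent"].to_numpy()
            if len(a) == 0 or len(b) == 0:
                log.info("cycle group %s/%s empty; omitted", organ, grp_name)
                continue
            res = mann_whitney(a, b)
            tests.append(
                {
                    "organ": organ,
                    "cycle_group": grp_name,
                    "n_per_cycle": len(a),
                    "n_first_cycle": len(b),
                    "u_statistic": res.statistic,
                    "p_value": res.pvalue,
                    "significant": bool(res.pvalue < SIGNIFICANCE_LEVEL),
                }
            )
    return pd.DataFrame(summaries), pd.DataFrame(tests)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a nonparametric two-sided test."""

    statistic: float
    pvalue: float
    n: int
    method: str
    degenerate: bool = False


#: Largest sample size for which the exact (full-enumeration) p-value is
#: computed; chosen so the enumeration stays trivial (2^14 sign patterns /
#: C(14,7)=3432 labelings).
EXACT_N_MAX = 14


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    *,
    zero_method: str = "wilcox",
    exact_n_max: int = EXACT_N_MAX,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped by default (``zero_method='wilcox'``;
    ``'pratt'`` keeps them in the ranking).  Below ``exact_n_max`` non-zero
    pairs the p-value is exact by full enumeration of sign assignments
    (ties handled by the permutation distribution); above it, the normal
    approximation with continuity/tie handling is used.  All differences
    zero is degenerate and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        return TestResult(0.0, 1.0, len(d), "degenerate", degenerate=True)
    if n_nonzero <= exact_n_max:
        method = stats.PermutationMethod(n_resamples=np.inf)
        label = "exact"
    else:
        method = "approx"
        label = "normal_approx"
    res = stats.wilcoxon(x, y, zero_method=zero_method, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), len(d), label)


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    *,
    exact_n_max: int = EXACT_N_MAX,
) -> TestResult:
    """Two-sided Mann–Whitney U test on independent samples.

    For combined sample sizes up to ``exact_n_max`` the p-value is exact by
    full enumeration of group labelings (valid with ties); larger samples
    use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) + len(y) <= exact_n_max:
        if min(len(x), len(y)) >= 2:
            method = stats.PermutationMethod(n_resamples=np.inf)
        else:
            # permutation machinery needs >=2 per sample; the U-distribution
            # exact method covers singleton groups
            method = "exact"
        label = "exact"
    else:
        method = "asymptotic"
        label = "normal_approx"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), len(x) + len(y), label)
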