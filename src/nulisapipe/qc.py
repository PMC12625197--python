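"""Panel quality control: IQR outlier masking, call rates, two-step call-rate
filtering, and LOD/CV reporting.

The QC chain operates on log2-scale abundances.  Per analyte, values more than
1.5 IQR below Q1 or above Q3 are masked to missing; call rates (proportion of
non-missing measurements) are then computed per analyte and per sample, and a
two-step threshold filter (65% then 85%, with rates recomputed between steps)
removes low-quality analytes and samples.  Limit of detection and coefficient
of variation are reported but never used as filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import AnalyteMatrix


@dataclass
class QCReport:
    """Bookkeeping for one QC pass.

    ``removed_analytes`` / ``removed_samples`` map ids to the filter step that
    removed them (``"step65"`` or ``"step85"``).  ``fences`` holds the
    per-analyte (lower, upper) IQR fences; analytes with fewer than 4
    non-missing values have NaN fences and are listed in
    ``unfenced_analytes``.
    """

    analyte_call_rates: pd.Series | None = None
    sample_call_rates: pd.Series | None = None
    fences: pd.DataFrame | None = None
    outlier_counts: pd.Series | None = None
    unfenced_analytes: list = field(default_factory=list)
    removed_analytes: dict = field(default_factory=dict)
    removed_samples: dict = field(default_factory=dict)
    cv: pd.Series | None = None
    lod: pd.Series | None = None
    quantile_convention: str = "linear interpolation between order statistics"
    lod_definition: str = "mean + 3*SD of negative controls (assumed; not defined upstream)"


def flag_iqr_outliers(matrix: AnalyteMatrix) -> tuple[AnalyteMatrix, QCReport]:
    """Mask per-analyte IQR outliers to missing.

    Per analyte with >=4 non-missing values, Q1 and Q3 are the 25th/75th
    percentiles under the linear-interpolation convention; values strictly
    outside (Q1 - 1.5*IQR, Q3 + 1.5*IQR) become NaN.  Values exactly at a
    fence are retained.  Analytes with <4 non-missing values are left
    untouched and flagged.
    """
    if matrix.scale != "log2_npq":
        raise ValueError(f"outlier flagging expects log2_npq scale, got {matrix.scale!r}")
    vals = matrix.values.copy()
    report = QCReport()
    lo = {}
    hi = {}
    counts = {}
    for a in vals.columns:
        col = vals[a]
        obs = col.dropna()
        if len(obs) < 4:
            report.unfenced_analytes.append(a)
            lo[a] = np.nan
            hi[a] = np.nan
            counts[a] = 0
            continue
        q1, q3 = np.percentile(obs.to_numpy(), [25, 75])
        iqr = q3 - q1
        fl, fh = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out = (col < fl) | (col > fh)
        vals.loc[out, a] = np.nan
        lo[a], hi[a] = fl, fh
        counts[a] = int(out.sum())
    report.fences = pd.DataFrame({"lower": pd.Series(lo), "upper": pd.Series(hi)})
    report.outlier_counts = pd.Series(counts)
    out_matrix = AnalyteMatrix(vals, matrix.scale, meta=dict(matrix.meta))
    return out_matrix, report


def compute_call_rates(matrix: AnalyteMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-analyte and per-sample call rates (non-missing / total)."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix has no call rates")
    obs = matrix.values.notna()
    analyte_rates = obs.mean(axis=0)
    sample_rates = obs.mean(axis=1)
    return analyte_rates, sample_rates


def two_step_call_rate_filter(
    matrix: AnalyteMatrix, thresholds: tuple[float, float] = (0.65, 0.85)
) -> tuple[AnalyteMatrix, QCReport]:
    """Two-step call-rate threshold filter.

    Step 1 removes analytes then samples with call rate < ``thresholds[0]``;
    rates are recomputed on the reduced matrix; step 2 repeats with
    ``thresholds[1]``.  The staged recomputation retains borderline analytes
    and samples whose rates improve once low-quality rows/columns are gone.
    """
    t1, t2 = thresholds
    if not (0 < t1 <= 1 and 0 < t2 <= 1):
        raise ValueError(f"thresholds must lie in (0, 1], got {thresholds}")
    if t2 <= t1:
        raise ValueError(f"thresholds must be increasing, got {thresholds}")
    report = QCReport()
    vals = matrix.values
    for step_name, thr in (("step65", t1), ("step85", t2)):
        # both axes judged on rates computed at step entry; recomputation
        # happens only between the two steps
        a_rates = vals.notna().mean(axis=0)
        s_rates = vals.notna().mean(axis=1)
        drop_a = a_rates.index[a_rates < thr]
        drop_s = s_rates.index[s_rates < thr]
        vals = vals.drop(columns=drop_a).drop(index=drop_s)
        for a in drop_a:
            report.removed_analytes[a] = step_name
        for s in drop_s:
            report.removed_samples[s] = step_name
    report.analyte_call_rates = vals.notna().mean(axis=0)
    report.sample_call_rates = vals.notna().mean(axis=1)
    out = AnalyteMatrix(vals.copy(), matrix.scale, meta=dict(matrix.meta))
    return out, report


def compute_lod_cv(
    matrix: AnalyteMatrix,
    control_ids: list | None = None,
    replicate_groups: list[list] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-analyte LOD and CV on the linear scale; reported, never filtered on.

    CV (%) = 100 * SD/mean within each replicate group, averaged over groups;
    NaN where no replicate groups are given.  LOD = mean + 3*SD over the
    designated negative-control samples; NaN when ``control_ids`` is empty.
    """
    if matrix.scale != "linear_npq":
        raise ValueError("LOD/CV are defined on linear-scale values")
    vals = matrix.values
    cv = pd.Series(np.nan, index=vals.columns)
    if replicate_groups:
        per_group = []
        for group in replicate_groups:
            sub = vals.loc[group]
            mean = sub.mean(axis=0, skipna=True)
            sd = sub.std(axis=0, ddof=1, skipna=True)
            per_group.append(100.0 * sd / mean)
        cv = pd.concat(per_group, axis=1).mean(axis=1)
    lod = pd.Series(np.nan, index=vals.columns)
    if control_ids:
        sub = vals.loc[control_ids]
        n_obs = sub.notna().sum(axis=0)
        mean = sub.mean(axis=0, skipna=True)
        sd = sub.std(axis=0, ddof=1, skipna=True).where(n_obs > 1, 0.0)
        lod = mean + 3.0 * sd
    return lod, cv


def run_qc(
    matrix: AnalyteMatrix, thresholds: tuple[float, float] = (0.65, 0.85)
) -> tuple[AnalyteMatrix, QCReport]:
    """Full QC chain: IQR masking, then the two-step call-rate filter."""
    masked, rep1 = flag_iqr_outliers(matrix)
    filtered, rep2 = two_step_call_rate_filter(masked, thresholds)
    rep2.fences = rep1.fences
    rep2.outlier_counts = rep1.outlier_counts
    rep2.unfenced_analytes = rep1.unfenced_analytes
    return filtered, rep2
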