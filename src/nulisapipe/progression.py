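"""Progression from cognitively unimpaired to symptomatic disease.

Per-protein Cox proportional-hazards regression (adjusted for age at draw and
sex, BH across analytes), Kaplan-Meier curves by a dichotomized biomarker
with a log-rank comparison, and fixed-horizon discrimination (logistic model
on the dichotomized marker + age + sex, AUC with a DeLong CI at 5/10/15-year
horizons).

Time-to-event is years from blood draw to symptom onset (progressors) or to
last follow-up (censored).  Survival records arrive as a DataFrame with
``time`` (> 0, years), ``event`` (0/1), the adjustment covariates and one
column per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .daa import adjust_bh
from .evaluation import ROCResult, logistic_predictor, roc_auc_delong


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    rec = records.copy()
    if (rec["time"] <= 0).any():
        raise ValueError("all survival times must be > 0")
    if not rec["event"].isin([0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return rec


@dataclass
class ProgressionModel:
    """Per-protein Cox PH model over a set of candidate markers.

    Each marker is fitted in its own model ``h(t) = h0(t) *
    exp(b*marker + c1*age + c2*sex)``; markers should be z-scored so hazard
    ratios are per-SD.
    """

    records: pd.DataFrame
    analytes: list
    covariates: tuple = ("age", "sex")
    min_events: int = 10

    def fit(self) -> "ProgressionResults":
        rec = _validate_records(self.records)
        n_events = int(rec["event"].sum())
        if n_events == 0:
            raise ValueError("no events observed")
        if n_events < self.min_events:
            raise ValueError(
                f"only {n_events} events; need >= {self.min_events} for stable fits"
            )
        rows = []
        skipped = {}
        for analyte in self.analytes:
            cols = ["time", "event", analyte, *self.covariates]
            sub = rec[cols].dropna()
            if sub[analyte].nunique() < 2:
                skipped[analyte] = "constant marker"
                continue
            cph = CoxPHFitter()
            try:
                cph.fit(sub, duration_col="time", event_col="event")
            except Exception as e:  # monotone likelihood and friends
                skipped[analyte] = f"fit failed: {e}"
                continue
            b = float(cph.params_[analyte])
            se = float(cph.standard_errors_[analyte])
            if not np.isfinite(b) or abs(b) > 20:
                skipped[analyte] = "monotone likelihood (infinite hazard ratio)"
                continue
            rows.append(
                {
                    "analyte": analyte,
                    "log_hr": b,
                    "hr": float(np.exp(b)),
                    "se": se,
                    "ci95_low": float(np.exp(b - 1.959963984540054 * se)),
                    "ci95_high": float(np.exp(b + 1.959963984540054 * se)),
                    "p_raw": float(cph.summary.loc[analyte, "p"]),
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                }
            )
        table = pd.DataFrame(rows).set_index("analyte")
        if len(table):
            table["p_fdr"] = adjust_bh(table["p_raw"].to_numpy())
        return ProgressionResults(table=table, skipped=skipped, tie_method="Efron")


@dataclass
class ProgressionResults:
    table: pd.DataFrame
    skipped: dict
    tie_method: str

    @property
    def n_significant(self) -> int:
        return int((self.table["p_fdr"] < 0.05).sum())

    def summary(self, top: int = 10) -> str:
        tab = self.table.sort_values("p_fdr")
        return (
            f"Cox proportional hazards per protein ({len(self.table)} fitted, "
            f"{len(self.skipped)} skipped; ties: {self.tie_method})\n"
            f"FDR < 0.05: {self.n_significant}\n\n"
            + tab.head(top).to_string(float_format=lambda v: f"{v:.4g}")
        )


def fit_cox_per_protein(
    records: pd.DataFrame, analytes: list, covariates: tuple = ("age", "sex")
) -> ProgressionResults:
    """Functional wrapper around :class:`ProgressionModel`."""
    return ProgressionModel(records, analytes, covariates).fit()


def km_estimate(records: pd.DataFrame, group_labels) -> dict:
    """Product-limit survival curves per group + log-rank comparison p.

    Returns ``{group: DataFrame(time, survival, at_risk)}`` plus the log-rank
    p-value (None when no events exist anywhere).
    """
    rec = _validate_records(records)
    labels = pd.Series(list(group_labels), index=rec.index)
    curves = {}
    for g in pd.unique(labels):
        sub = rec[labels == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
            }
        )
    if rec["event"].sum() == 0 or labels.nunique() < 2:
        p = None
    else:
        res = multivariate_logrank_test(rec["time"], labels, rec["event"])
        p = float(res.p_value)
    return {"curves": curves, "logrank_p": p}


def horizon_auc(
    records: pd.DataFrame,
    marker: str,
    horizons: tuple = (5.0, 10.0, 15.0),
    covariates: tuple = ("age", "sex"),
) -> dict:
    """Fixed-horizon discrimination of a dichotomized marker.

    At horizon ``h``: progressors are events with time <= h; non-progressors
    are records followed at least ``h`` years without an event; censored
    records shorter than ``h`` are ambiguous and excluded.  A logistic model
    on marker + covariates supplies the probabilities scored by the DeLong
    AUC.  Horizons with an empty class are skipped with a reason.
    """
    rec = _validate_records(records)
    out: dict[float, ROCResult | str] = {}
    for h in horizons:
        progressor = (rec["event"] == 1) & (rec["time"] <= h)
        non_progressor = rec["time"] >= h
        eligible = progressor | non_progressor
        sub = rec[eligible]
        y = progressor[eligible].astype(int)
        if y.nunique() < 2:
            out[h] = "skipped: a class is empty at this horizon"
            continue
        X = sub[[marker, *covariates]]
        try:
            scores = logistic_predictor(y.to_numpy(), X)["fitted"]
        except ValueError:
            # complete separation: the logit diverges but the ranking is
            # determined, and AUC is rank-invariant -> score the marker itself
            scores = sub[marker].to_numpy()
        out[h] = roc_auc_delong(scores, y.to_numpy())
    return out
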