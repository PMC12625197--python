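"""Per-protein differential abundance: OLS with age, sex and surrogate
variables; Benjamini-Hochberg FDR within each analysis family.

The model for each analyte ``j`` is::

    z_j = b0 + b1 * predictor + b2 * age + b3 * sex + c1 * SV1 + c2 * SV2 + e

where ``z_j`` is the z-scored (log10 linear NPQ) abundance, the predictor is
either a disease-vs-control indicator or a continuous phenotype, and the SVs
are surrogate variables estimated from the residual structure of the full
matrix to absorb unmodeled confounding (batch, processing drift).  ``b1`` with
its standard error and two-sided t-test p-value is the unit of every
downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ._utils import check_rng
from .matrix import AnalyteMatrix


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_surrogate_variables(
    matrix: AnalyteMatrix,
    design: pd.DataFrame,
    n_sv: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Estimate surrogate variables from residual expression structure.

    Missing cells are imputed by sampling observed values of the same analyte
    with replacement (seeded).  The primary design (predictor + covariates +
    intercept) is regressed out of every analyte; the SVs are the leading
    left singular vectors of the residual matrix, refined by one reweighting
    pass in which analytes are weighted by how much residual variance the
    initial SVs explain.  Returned as an (n_samples, n_sv) orthonormal array.
    """
    if matrix.scale != "zscore":
        raise ValueError("surrogate variables are estimated on the z-scored matrix")
    rng = check_rng(seed)
    Y = matrix.values.loc[design.index].to_numpy(copy=True)
    n, p = Y.shape
    if n_sv >= min(n, p):
        raise ValueError(f"n_sv={n_sv} must be < min(n_samples, n_analytes)={min(n, p)}")
    for j in range(p):
        col = Y[:, j]
        miss = np.isnan(col)
        if miss.any():
            obs = col[~miss]
            if obs.size == 0:
                raise ValueError(f"analyte column {j} is entirely missing")
            col[miss] = rng.choice(obs, size=miss.sum(), replace=True)
    X = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta

    def leading_svs(mat: np.ndarray) -> np.ndarray:
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        return u[:, :n_sv]

    sv = leading_svs(R)
    # one reweighting pass: weight analytes by how much residual variance the
    # initial SVs explain, then re-extract the SVs from the weighted *data*
    # (not the residuals) so the part of a batch factor aligned with the
    # primary design is recovered too
    denom = np.sum(R**2, axis=0)
    denom = np.where(denom == 0, 1.0, denom)
    coef, *_ = np.linalg.lstsq(sv, R, rcond=None)
    explained = np.sum((sv @ coef) ** 2, axis=0) / denom
    sv = leading_svs((Y - Y.mean(axis=0)) * np.sqrt(explained))
    # fix sign for determinism: largest-magnitude loading positive
    for k in range(sv.shape[1]):
        idx = np.argmax(np.abs(sv[:, k]))
        if sv[idx, k] < 0:
            sv[:, k] = -sv[:, k]
    return sv


@dataclass
class DifferentialAbundanceModel:
    """Per-protein regression of abundance on a contrast or phenotype.

    Parameters
    ----------
    matrix : AnalyteMatrix
        z-scored abundances.
    annotation : pandas.DataFrame
        Indexed by sample id (or holding a ``sample_id`` column); must carry
        the predictor and covariate columns.
    predictor : str
        Either ``"<disease>_vs_<reference>"`` for a group contrast (rows
        outside the two groups are dropped) or the name of a continuous /
        binary phenotype column.
    covariates : sequence of str
        Adjustment covariates; sex-like string columns are coded 0/1.
    n_sv : int
        Number of surrogate variables to estimate and adjust for.
    """

    matrix: AnalyteMatrix
    annotation: pd.DataFrame
    predictor: str
    covariates: tuple = ("age", "sex")
    n_sv: int = 2
    group_col: str = "group"
    seed: int = 0
    _design: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ann = self.annotation
        if "sample_id" in ann.columns:
            ann = ann.set_index("sample_id")
        ann = ann.loc[ann.index.intersection(self.matrix.sample_ids)]
        # cross-sectional analyses use one sample per participant: keep the
        # latest draw (highest age at draw) when repeats are present
        if "participant_id" in ann.columns and "age" in ann.columns:
            ann = (
                ann.sort_values("age", kind="mergesort")
                .groupby("participant_id", sort=False)
                .tail(1)
            )
        if "_vs_" in self.predictor:
            case, ref = self.predictor.split("_vs_")
            ann = ann[ann[self.group_col].isin([case, ref])]
            x = (ann[self.group_col] == case).astype(float)
        else:
            x = pd.to_numeric(ann[self.predictor], errors="coerce")
            ann = ann[x.notna()]
            x = x[ann.index]
        design = pd.DataFrame({"predictor": x})
        for c in self.covariates:
            col = ann[c]
            if col.dtype == object:
                col = (col == sorted(col.unique())[0]).astype(float)
            design[c] = pd.to_numeric(col)
        design = design.dropna()
        if design.shape[0] < design.shape[1] + 2:
            raise ValueError("too few complete samples for the design")
        self._design = design

    @property
    def design(self) -> pd.DataFrame:
        return self._design

    def fit(self) -> "DifferentialAbundanceResults":
        design = self._design.copy()
        if self.n_sv > 0:
            sv = estimate_surrogate_variables(
                self.matrix, design, n_sv=self.n_sv, seed=self.seed
            )
            for k in range(self.n_sv):
                design[f"SV{k + 1}"] = sv[:, k]
        else:
            sv = np.zeros((design.shape[0], 0))
        Y = self.matrix.values.loc[design.index]
        rows = []
        skipped = {}
        X_full = sm.add_constant(design, has_constant="add")
        for analyte in Y.columns:
            y = Y[analyte]
            ok = y.notna()
            n_used = int(ok.sum())
            if n_used < design.shape[1] + 2:
                skipped[analyte] = f"only {n_used} complete cases"
                continue
            X = X_full.loc[ok]
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                skipped[analyte] = "rank-deficient design"
                continue
            res = sm.OLS(y[ok].to_numpy(), X.to_numpy()).fit()
            i = list(X.columns).index("predictor")
            rows.append(
                {
                    "analyte": analyte,
                    "beta": res.params[i],
                    "se": res.bse[i],
                    "p_raw": res.pvalues[i],
                    "n_used": n_used,
                }
            )
        table = pd.DataFrame(rows).set_index("analyte")
        table["p_fdr"] = adjust_bh(table["p_raw"].to_numpy())
        return DifferentialAbundanceResults(
            table=table,
            predictor=self.predictor,
            surrogate_variables=sv,
            design=design,
            skipped=skipped,
        )


@dataclass
class DifferentialAbundanceResults:
    """Fitted per-protein associations for one contrast/phenotype."""

    table: pd.DataFrame  # index analyte; beta, se, p_raw, n_used, p_fdr
    predictor: str
    surrogate_variables: np.ndarray
    design: pd.DataFrame
    skipped: dict

    @property
    def n_significant(self) -> int:
        return int((self.table["p_fdr"] < 0.05).sum())

    def summary(self, top: int = 10) -> str:
        tab = self.table.sort_values("p_fdr")
        lines = [
            f"Differential abundance: {self.predictor}",
            f"  analytes tested: {len(self.table)}"
            + (f" (skipped {len(self.skipped)})" if self.skipped else ""),
            f"  samples: {self.design.shape[0]}",
            f"  FDR < 0.05: {self.n_significant}",
            "",
            tab.head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
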