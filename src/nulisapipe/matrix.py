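"""Sample x analyte abundance container and its normalization chain.

Targeted panel abundances arrive on a log2 "NPQ" scale (assay-normalized,
log2-transformed protein quantification units).  Downstream analyses use a
fixed normalization chain::

    log2_npq -> linear_npq -> log10 -> zscore

Each stage is a tagged state of :class:`AnalyteMatrix`; transitions outside
the chain raise :class:`ScaleTransitionError`.  The per-analyte mean/SD used
at the z-score step are retained so that cutoffs estimated on the z scale can
be mapped back to linear NPQ units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALE_CHAIN = ("log2_npq", "linear_npq", "log10", "zscore")


class ScaleTransitionError(ValueError):
    """Requested a normalization transition outside the allowed chain."""


@dataclass
class AnalyteMatrix:
    """Samples x analytes abundance grid with missing values as NaN.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns analytes; NaN marks a missing/failed
        measurement.
    scale : str
        One of ``log2_npq``, ``linear_npq``, ``log10``, ``zscore``.
    norm_params : pandas.DataFrame, optional
        Per-analyte ``mean`` and ``sd`` (of the log10 values) recorded when
        z-scoring; needed to invert z-scores back to linear NPQ.
    """

    values: pd.DataFrame
    scale: str = "log2_npq"
    norm_params: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALE_CHAIN:
            raise ScaleTransitionError(f"unknown scale tag {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate analyte ids")
        self.values = self.values.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AnalyteMatrix":
        return AnalyteMatrix(
            self.values.copy(),
            self.scale,
            None if self.norm_params is None else self.norm_params.copy(),
            dict(self.meta),
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the matrix: header row of analyte ids, first column sample id,
        empty cell = missing."""
        self.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")

    @classmethod
    def from_tsv(cls, path, scale: str = "log2_npq") -> "AnalyteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)


def linear_to_log2(matrix: AnalyteMatrix) -> AnalyteMatrix:
    """Inverse of the log2 -> linear back-transformation (round-trip helper)."""
    if matrix.scale != "linear_npq":
        raise ScaleTransitionError(f"cannot take log2 from scale {matrix.scale!r}")
    return AnalyteMatrix(np.log2(matrix.values), "log2_npq", meta=dict(matrix.meta))


def normalize_npq(matrix: AnalyteMatrix, target: str) -> AnalyteMatrix:
    """Advance the matrix along the normalization chain to ``target``.

    log2 NPQ values are back-transformed to linear NPQ (``2**x``), then
    log10-transformed, then z-scored per analyte over non-missing samples
    (sample SD, ddof=1).  Missing cells stay missing.  Requests that move
    backwards along the chain (other than linear -> log2, see
    :func:`linear_to_log2`) raise :class:`ScaleTransitionError`.
    """
    if target not in SCALE_CHAIN:
        raise ScaleTransitionError(f"unknown target scale {target!r}")
    cur = SCALE_CHAIN.index(matrix.scale)
    tgt = SCALE_CHAIN.index(target)
    if tgt < cur:
        raise ScaleTransitionError(
            f"cannot move backwards from {matrix.scale!r} to {target!r}"
        )
    out = matrix.copy()
    for step in range(cur, tgt):
        out = _STEP_FUNCS[SCALE_CHAIN[step]](out)
    return out


def _log2_to_linear(matrix: AnalyteMatrix) -> AnalyteMatrix:
    return AnalyteMatrix(
        np.power(2.0, matrix.values), "linear_npq", meta=dict(matrix.meta)
    )


def _linear_to_log10(matrix: AnalyteMatrix) -> AnalyteMatrix:
    vals = matrix.values
    bad = (vals <= 0) & vals.notna()
    if bad.any().any():
        cells = [
            (s, a) for s, a in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise ValueError(
            f"{bad.to_numpy().sum()} nonpositive linear values before log10 "
            f"(first offending cell index {cells[0]})"
        )
    return AnalyteMatrix(np.log10(vals), "log10", meta=dict(matrix.meta))


def _log10_to_zscore(matrix: AnalyteMatrix) -> AnalyteMatrix:
    vals = matrix.values
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    if (sd <= 0).any() or sd.isna().any():
        flat = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise ValueError(f"zero-variance analytes cannot be z-scored: {flat}")
    z = (vals - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return AnalyteMatrix(z, "zscore", norm_params=params, meta=dict(matrix.meta))


_STEP_FUNCS = {
    "log2_npq": _log2_to_linear,
    "linear_npq": _linear_to_log10,
    "log10": _log10_to_zscore,
}


def zscore_to_linear(z, norm_params: pd.DataFrame, analyte: str) -> np.ndarray:
    """Invert the z-score and log10 transforms for one analyte.

    ``linear = 10 ** (z * sd + mean)`` with the stored per-analyte mean/SD.
    """
    if analyte not in norm_params.index:
        raise KeyError(f"no stored normalization parameters for {analyte!r}")
    mean = norm_params.loc[analyte, "mean"]
    sd = norm_params.loc[analyte, "sd"]
    return np.power(10.0, np.asarray(z, dtype=float) * sd + mean)
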