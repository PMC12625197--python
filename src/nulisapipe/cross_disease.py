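"""Cross-disease effect-size comparison: pairwise z-tests, effect-vector
correlations, complete-linkage clustering, and the scorecard ranking.

The z-statistic for comparing two independently estimated effects is
``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` with a two-sided standard-normal
p-value, BH-adjusted across analytes within each disease pair.  The scorecard
assigns each protein a per-disease score in {-2, -1, 0, +1, +2} from the sign
and significance of its association, summed (and summed in absolute value)
across diseases to rank proteins by cross-disease consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .daa import DifferentialAbundanceResults, adjust_bh


@dataclass
class EffectSizeTable:
    """Analyte x contrast grids of beta / se / p_raw / p_fdr."""

    beta: pd.DataFrame
    se: pd.DataFrame
    p_raw: pd.DataFrame
    p_fdr: pd.DataFrame

    @classmethod
    def from_results(cls, results: dict) -> "EffectSizeTable":
        """Build from ``{contrast_name: DifferentialAbundanceResults}``."""

        def grid(col):
            return pd.DataFrame(
                {
                    name: (r.table[col] if isinstance(r, DifferentialAbundanceResults) else r[col])
                    for name, r in results.items()
                }
            )

        return cls(grid("beta"), grid("se"), grid("p_raw"), grid("p_fdr"))

    @property
    def contrasts(self) -> list:
        return list(self.beta.columns)


def effect_size_ztest(b1, se1, b2, se2) -> tuple[float, float]:
    """Two-tailed z-test for a difference of two estimated effects."""
    if se1 == 0 and se2 == 0:
        raise ValueError("z-test undefined when both standard errors are zero")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_contrasts(
    table: EffectSizeTable, pair: tuple[str, str], fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-analyte z-tests for one pair of contrasts, BH-adjusted.

    ``category`` follows the discordance-calling convention: FDR-significant
    z-test -> ``fdr_significant``, raw p < 0.05 -> ``nominal``, else ``ns``.
    """
    a, b = pair
    sub = pd.DataFrame(
        {
            "b1": table.beta[a],
            "se1": table.se[a],
            "b2": table.beta[b],
            "se2": table.se[b],
        }
    ).dropna()
    z = (sub.b1 - sub.b2) / np.sqrt(sub.se1**2 + sub.se2**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"z": z, "p_raw": p}, index=sub.index)
    out["p_fdr"] = adjust_bh(out["p_raw"].to_numpy())
    out["category"] = np.where(
        out["p_fdr"] < fdr_threshold,
        "fdr_significant",
        np.where(out["p_raw"] < 0.05, "nominal", "ns"),
    )
    return out


def correlate_effect_sizes(
    table: EffectSizeTable, pair: tuple[str, str]
) -> tuple[float, float]:
    """Pearson correlation of two contrasts' effect-size vectors."""
    a, b = pair
    sub = pd.DataFrame({"a": table.beta[a], "b": table.beta[b]}).dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 shared analytes")
    if sub["a"].nunique() == 1 or sub["b"].nunique() == 1:
        raise ValueError("correlation undefined for a zero-variance effect vector")
    r, p = stats.pearsonr(sub["a"], sub["b"])
    return float(r), float(p)


def correlation_matrix(table: EffectSizeTable) -> pd.DataFrame:
    cons = table.contrasts
    out = pd.DataFrame(np.eye(len(cons)), index=cons, columns=cons)
    for i, a in enumerate(cons):
        for j in range(i + 1, len(cons)):
            r, _ = correlate_effect_sizes(table, (a, cons[j]))
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def cluster_effect_matrix(table: EffectSizeTable) -> dict:
    """Complete-linkage hierarchical clustering of rows and columns.

    Euclidean distance, complete linkage; rows with any missing beta are
    dropped; input rows are sorted lexicographically by label first so the
    tree is deterministic under input permutation.  Returns scipy linkage
    matrices plus leaf labels and Newick strings for both axes.
    """
    betas = table.beta.dropna(axis=0)
    if betas.shape[0] < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    betas = betas.sort_index()

    def one_axis(mat: pd.DataFrame) -> tuple[np.ndarray, list, str]:
        labels = list(mat.index)
        if len(labels) == 1:  # trivial single-leaf tree
            return np.empty((0, 4)), labels, f"{labels[0]}:0;"
        Z = hierarchy.linkage(mat.to_numpy(), method="complete", metric="euclidean")
        return Z, labels, _to_newick(Z, labels)

    row_Z, row_labels, row_newick = one_axis(betas)
    col_Z, col_labels, col_newick = one_axis(betas.T.sort_index())
    return {
        "row_linkage": row_Z,
        "row_labels": row_labels,
        "row_newick": row_newick,
        "col_linkage": col_Z,
        "col_labels": col_labels,
        "col_newick": col_newick,
    }


def _to_newick(Z: np.ndarray, labels: list) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def build_scorecard(
    table: EffectSizeTable,
    diseases: tuple = ("AD", "DLB", "FTD", "PD"),
    nominal: float = 0.05,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Scorecard ranking proteins by cross-disease association consistency.

    Per disease: +2 for a positive FDR-significant association, +1 for
    positive and nominally significant only, mirrored -1/-2 for negative
    associations, 0 otherwise (missing cells score 0 and set ``incomplete``).
    ``total`` sums the signed scores; ``absolute_total`` the magnitudes.
    Rows are ordered by absolute_total then total (both descending).
    """
    missing = [d for d in diseases if d not in table.beta.columns]
    if missing:
        raise ValueError(f"contrasts absent from table: {missing}")
    scores = pd.DataFrame(0, index=table.beta.index, columns=list(diseases))
    incomplete = pd.Series(False, index=table.beta.index)
    for d in diseases:
        b = table.beta[d]
        praw = table.p_raw[d]
        pfdr = table.p_fdr[d]
        na = b.isna() | praw.isna() | pfdr.isna()
        incomplete |= na
        mag = np.where(pfdr < fdr, 2, np.where(praw < nominal, 1, 0))
        s = np.sign(b.fillna(0)).astype(int) * mag
        s[na.to_numpy()] = 0
        scores[d] = s
    out = scores.copy()
    out["total"] = scores.sum(axis=1)
    out["absolute_total"] = scores.abs().sum(axis=1)
    out["incomplete"] = incomplete
    return out.sort_values(
        ["absolute_total", "total"], ascending=[False, False], kind="mergesort"
    )
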