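"""Agreement and discrimination metrics.

Confusion/concordance summaries, ROC-AUC with a DeLong 95% CI, logistic
predictors, Kruskal-Wallis with Dunn post-hoc contrasts, replicate/platform
correlation summaries, APOE-e4 proteoform vs genotype concordance, and a
generic hypergeometric over-representation test with fold enrichment.

Reported percentages use two decimals with ties rounded away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._utils import pct
from .daa import adjust_bh


# ---------------------------------------------------------------------------
# confusion / concordance
# ---------------------------------------------------------------------------
@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def concordance(self) -> float:
        """Percent agreement, two decimals."""
        return pct(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def summary(self) -> str:
        return (
            f"n={self.n} (excluded {self.n_excluded})  "
            f"concordance={self.concordance:.2f}%  "
            f"sens={self.sensitivity:.3f} spec={self.specificity:.3f} "
            f"ppv={self.ppv:.3f} npv={self.npv:.3f}"
        )


def confusion_metrics(predicted, reference) -> ConfusionSummary:
    """2x2 agreement between binary predicted and reference labels.

    Non-binary entries (NaN, ``"intermediate"``, ...) in either vector
    exclude the pair into ``n_excluded``.
    """
    pred = pd.Series(list(predicted))
    ref = pd.Series(list(reference))
    if len(pred) != len(ref):
        raise ValueError("label vectors must be paired")
    if len(pred) == 0:
        raise ValueError("empty label pairing")

    def as_binary(s: pd.Series) -> pd.Series:
        mapped = s.map(
            {0: 0, 1: 1, 0.0: 0, 1.0: 1, False: 0, True: 1, "0": 0, "1": 1}
        )
        return mapped

    p = as_binary(pred)
    r = as_binary(ref)
    ok = p.notna() & r.notna()
    n_excluded = int((~ok).sum())
    p, r = p[ok].astype(int), r[ok].astype(int)
    if len(p) == 0:
        raise ValueError("no usable binary pairs")
    tp = int(((p == 1) & (r == 1)).sum())
    fp = int(((p == 1) & (r == 0)).sum())
    tn = int(((p == 0) & (r == 0)).sum())
    fn = int(((p == 0) & (r == 1)).sum())
    return ConfusionSummary(tp, fp, tn, fn, n_excluded)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------
@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def summary(self) -> str:
        return f"AUC={self.auc:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}, n+={self.n_pos}, n-={self.n_neg})"


def roc_auc_delong(scores, labels) -> ROCResult:
    """AUC (Mann-Whitney with ties counted 1/2) and DeLong 95% CI.

    The DeLong variance is computed from placement values:
    ``var = S10/m + S01/n`` with S10/S01 the sample variances of the
    per-positive and per-negative placements.  The CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("AUC undefined with a single class")
    # placement of each positive among negatives (and vice versa), ties = 1/2
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    auc = float(psi.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.975)
    return ROCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n_pos=m,
        n_neg=n,
    )


def logistic_predictor(outcome, predictors: pd.DataFrame) -> dict:
    """Maximum-likelihood logistic regression; probabilities feed the ROC.

    Raises on detected complete separation rather than returning a silently
    diverged fit.
    """
    y = np.asarray(outcome).astype(float)
    X = sm.add_constant(pd.DataFrame(predictors).astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise ValueError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False) or np.any(
        np.abs(res.params) > 50
    ):
        raise ValueError("complete or quasi-complete separation detected")
    return {
        "coefficients": pd.Series(res.params, index=X.columns),
        "se": pd.Series(res.bse, index=X.columns),
        "fitted": np.asarray(res.predict(X)),
        "converged": True,
    }


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------
def kruskal_dunn(values, groups, comparisons: list[tuple[str, str]]) -> dict:
    """Kruskal-Wallis across all groups plus Dunn's post-hoc z-tests.

    Dunn z for groups i, j compares mean ranks with the tie-corrected
    variance; Bonferroni is applied over the *requested* comparisons only
    (e.g. AD versus each other group).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: values[groups == g] for g in names}
    for g, v in samples.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    H, p = stats.kruskal(*[samples[g] for g in names])

    N = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    m = len(comparisons)
    for a, b in comparisons:
        na, nb = samples[a].size, samples[b].size
        z = (mean_rank[a] - mean_rank[b]) / np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        praw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "comparison": f"{a}_vs_{b}",
                "z": float(z),
                "p_raw": float(praw),
                "p_bonferroni": float(min(1.0, m * praw)),
            }
        )
    return {"H": float(H), "p": float(p), "dunn": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# replicate / platform correlation
# ---------------------------------------------------------------------------
def platform_correlation(
    matched: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, dict]:
    """Per-analyte Pearson correlation between two platforms/runs.

    ``matched`` has columns ``analyte``, ``x``, ``y`` (one row per paired
    measurement).  Analytes with <3 pairs or a constant vector are skipped
    with a reason.  The summary reports the mean r and the percentage of
    analytes with r above ``threshold`` (two decimals).
    """
    rows = []
    skipped = {}
    for analyte, sub in matched.groupby("analyte", sort=True):
        sub = sub[["x", "y"]].dropna()
        if len(sub) < 3:
            skipped[analyte] = "fewer than 3 paired observations"
            continue
        if sub["x"].nunique() == 1 or sub["y"].nunique() == 1:
            skipped[analyte] = "constant vector"
            continue
        r, p = stats.pearsonr(sub["x"], sub["y"])
        rows.append({"analyte": analyte, "r": float(r), "p": float(p), "n": len(sub)})
    table = pd.DataFrame(rows).set_index("analyte") if rows else pd.DataFrame()
    if len(table):
        above = int((table["r"] > threshold).sum())
        summary = {
            "mean_r": float(table["r"].mean()),
            "n_analytes": len(table),
            "n_above_threshold": above,
            "pct_above_threshold": pct(above, len(table)),
            "threshold": threshold,
            "skipped": skipped,
        }
    else:
        summary = {"skipped": skipped}
    return table, summary


# ---------------------------------------------------------------------------
# APOE concordance
# ---------------------------------------------------------------------------
E4_POSITIVE = {"e2/e4", "e3/e4", "e4/e4"}
E4_NEGATIVE = {"e2/e2", "e2/e3", "e3/e3"}


def apoe_concordance(calls, genotypes) -> dict:
    """Concordance of a binary e4-proteoform call against APOE genotypes.

    A genotype containing e4 defines the positive reference.  Returns the
    overall :class:`ConfusionSummary` plus per-genotype accuracy, accuracy
    within the genotyped-negative stratum, and accuracy over e3-allele
    carriers (percentages to two decimals).  Unknown genotype strings are
    excluded and logged.
    """
    calls = pd.Series(list(calls))
    genos = pd.Series(list(genotypes)).str.replace("ε", "e", regex=False).str.lower()
    known = genos.isin(E4_POSITIVE | E4_NEGATIVE)
    excluded = sorted(genos[~known].unique())
    calls, genos = calls[known], genos[known]
    ref = genos.isin(E4_POSITIVE).astype(int)
    overall = confusion_metrics(calls, ref)
    overall.n_excluded += int((~known).sum())
    correct = calls.astype(int).to_numpy() == ref.to_numpy()
    per_genotype = {}
    for g in sorted(genos.unique()):
        mask = (genos == g).to_numpy()
        per_genotype[g] = {
            "n": int(mask.sum()),
            "n_correct": int(correct[mask].sum()),
            "accuracy_pct": pct(correct[mask].sum(), mask.sum()),
        }
    neg_mask = genos.isin(E4_NEGATIVE).to_numpy()
    e3_mask = genos.str.contains("e3").to_numpy()

    def stratum(mask):
        n = int(mask.sum())
        return {
            "n": n,
            "n_correct": int(correct[mask].sum()),
            "accuracy_pct": pct(correct[mask].sum(), n) if n else None,
        }

    strata = {"e4_negative": stratum(neg_mask), "e3_carriers": stratum(e3_mask)}
    return {
        "overall": overall,
        "per_genotype": per_genotype,
        "strata": strata,
        "excluded_genotypes": excluded,
    }


def call_e4_from_proteoform(values, threshold: float | None = None) -> np.ndarray:
    """Binary e4 call from the e4-proteoform analyte.

    By default the threshold is the equal-likelihood crossing of a
    two-component Gaussian mixture fitted to the values (carrier vs
    non-carrier abundance modes, shared variance: the assay noise is the same
    in both, and the shared-variance crossing is unique and always lies
    between the means); pass ``threshold`` to override.
    """
    from .cutoffs import fit_two_component_gmm, gmm_crossing_cutoff

    values = np.asarray(values, dtype=float)
    if threshold is None:
        fit = fit_two_component_gmm(
            values[np.isfinite(values)], variance_structure="equal"
        )
        threshold = gmm_crossing_cutoff(fit)
    return (values > threshold).astype(int)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------
def overrepresentation_test(
    da_set, annotation_map: dict, background
) -> pd.DataFrame:
    """Hypergeometric over-representation with fold enrichment.

    For each pathway with K background members, k of the n differentially
    abundant proteins: upper-tail hypergeometric p and
    ``fold_enrichment = (k/n) / (K/N)``; BH across pathways.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    da = set(da_set)
    if not da <= background:
        raise ValueError("da_set must be a subset of the background")
    N, n = len(background), len(da)
    rows = []
    for pathway, members in annotation_map.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & da)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fe = (k / n) / (K / N) if n else float("nan")
        rows.append(
            {"pathway": pathway, "k": k, "K": K, "n": n, "N": N,
             "fold_enrichment": fe, "p_raw": min(p, 1.0)}
        )
    table = pd.DataFrame(rows).set_index("pathway")
    if len(table):
        table["p_fdr"] = adjust_bh(table["p_raw"].to_numpy())
    return table


def write_gmt(annotation_map: dict, path, description: str = "na") -> None:
    """Write a pathway -> members map as standard GMT (tab-separated:
    name, description, members...)."""
    with open(path, "w") as fh:
        for pathway, members in annotation_map.items():
            fh.write("\t".join([str(pathway), description, *sorted(map(str, members))]) + "\n")


def read_gmt(path) -> dict:
    """Read a GMT file into a pathway -> set-of-members map."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out
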