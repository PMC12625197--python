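"""Published validation-count summaries as reconstructable inputs.

Large plasma-proteomics validation studies report their agreement analyses as
count summaries: a 2x2 table of biomarker calls against amyloid-PET
positivity, tri-class sample counts from a dual-cutoff scheme, per-genotype
tallies of APOE-e4 proteoform calls against SNP genotyping, and the number of
analytes whose between-run correlation clears a threshold.  The functions
here expand such summaries into the label vectors the evaluation module
consumes, so every reported rate can be recomputed rather than transcribed.

Counts not uniquely pinned down by a summary (e.g. the split of APOE
discordances across rare genotypes) are completed with plausible values; only
quantities fully determined by the summary should be asserted on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import check_rng


def expand_confusion(tp: int, fp: int, tn: int, fn: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand 2x2 counts into paired (predicted, reference) 0/1 vectors."""
    pred = np.concatenate(
        [np.ones(tp), np.ones(fp), np.zeros(tn), np.zeros(fn)]
    ).astype(int)
    ref = np.concatenate(
        [np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
    ).astype(int)
    return pred, ref


# plasma p-tau217 call vs amyloid-PET positivity, n=325: the unique integer
# 2x2 consistent with 28 discordant pairs, PPV 0.82 and NPV 0.96
PET_CONFUSION = {"tp": 88, "fp": 19, "tn": 209, "fn": 9}


def pet_confusion_labels() -> tuple[np.ndarray, np.ndarray]:
    return expand_confusion(**PET_CONFUSION)


# dual-cutoff concordance restricted to the low/high classes: 273 retained
# pairs, 17 discordant
DUAL_RETAINED = {"n": 273, "discordant": 17}


def dual_retained_labels() -> tuple[np.ndarray, np.ndarray]:
    n, d = DUAL_RETAINED["n"], DUAL_RETAINED["discordant"]
    pred = np.concatenate([np.ones(150), np.zeros(n - 150)]).astype(int)
    ref = pred.copy()
    ref[:d] = 0  # flip d pairs to discordance
    return pred, ref


# tri-class counts from the dual cutoffs (-0.26 / 0.35 on the z scale)
TRICLASS = {"low": 79, "intermediate": 52, "high": 194}
TRICLASS_CUTOFFS = (-0.26, 0.35)


def triclass_values() -> np.ndarray:
    """Biomarker z-values placed to reproduce the tri-class counts."""
    lo, hi = TRICLASS_CUTOFFS
    return np.concatenate(
        [
            np.full(TRICLASS["low"], lo - 0.5),
            np.full(TRICLASS["intermediate"], (lo + hi) / 2),
            np.full(TRICLASS["high"], hi + 0.5),
        ]
    )


# APOE-e4 proteoform call vs SNP genotype: per-genotype (total, discordant).
# Marginals pinned by the summary: 1573 genotyped e4+ with 24 missed calls
# (3 of 232 e4/e4; 19 carried e3), 2319 e4- with 15 false positives (14
# e3/e3, 1 e2/e3), 3520 e3 carriers with 34 discordant.  Genotype totals for
# e2/e2, e2/e3, e2/e4 and e3/e4 are plausible completions.
APOE_TABLE = {
    "e2/e2": (120, 0),
    "e2/e3": (32, 1),
    "e3/e3": (2167, 14),
    "e2/e4": (20, 2),
    "e3/e4": (1321, 19),
    "e4/e4": (232, 3),
}
_E4_POS = {"e2/e4", "e3/e4", "e4/e4"}


def apoe_labels() -> tuple[list, list]:
    """(proteoform calls, genotype strings) reproducing the APOE tallies."""
    calls: list[int] = []
    genos: list[str] = []
    for g, (total, discordant) in APOE_TABLE.items():
        truth = 1 if g in _E4_POS else 0
        calls += [1 - truth] * discordant + [truth] * (total - discordant)
        genos += [g] * total
    return calls, genos


def matched_platform_table(
    n_high: int = 86,
    n_total: int = 123,
    n_pairs: int = 300,
    r_high: float = 0.92,
    r_low: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cross-run matched measurements with a planted correlation
    profile: ``n_high`` analytes correlate at ``r_high`` (safely above the
    0.7 reporting threshold), the rest at ``r_low``.  Returns the
    ``analyte``/``x``/``y`` long table :func:`platform_correlation` expects.
    """
    rng = check_rng(seed)
    rows = []
    for i in range(n_total):
        r = r_high if i < n_high else r_low
        x = rng.normal(size=n_pairs)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n_pairs)
        rows.append(pd.DataFrame({"analyte": f"A{i:03d}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)
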