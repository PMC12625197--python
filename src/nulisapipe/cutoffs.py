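"""Data-driven biomarker positivity cutoffs on a z-scored biomarker.

Three complementary cutoff constructions:

* **GMM crossing** — fit a two-component Gaussian mixture by EM and place the
  cutoff where a sample is equally likely to belong to either component,
  i.e. the solution of ``pi1 * N(x; mu1, s1) = pi2 * N(x; mu2, s2)`` between
  the two means.  Unsupervised: needs no reference labels.
* **Youden single cutoff** — maximize J = sensitivity + specificity - 1
  against a binary reference (e.g. amyloid-PET positivity at 20 Centiloids).
* **Dual cutoffs** — the largest threshold retaining 95% sensitivity (lower)
  and the smallest retaining 95% specificity (upper), defining a tri-class
  low / intermediate / high labeling with an indeterminate middle zone.

Cutoffs derived on the z scale can be mapped back to linear NPQ units through
the stored normalization parameters (see :func:`nulisapipe.matrix.zscore_to_linear`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import pct


class DegenerateFitError(RuntimeError):
    """EM collapsed onto a near-zero-variance component."""


@dataclass
class GMMResults:
    """A fitted two-component Gaussian mixture (components ordered mu1 < mu2)."""

    weights: tuple
    means: tuple
    sds: tuple
    log_likelihood: list
    converged: bool
    n_iter: int
    variance_floor_active: bool = False
    variance_structure: str = "free"  # "free" or "equal"
    bic: float | None = None

    @property
    def overlapping(self) -> bool:
        """Components closer than one pooled SD: the split is not trustworthy."""
        pooled = np.sqrt(
            self.weights[0] * self.sds[0] ** 2 + self.weights[1] * self.sds[1] ** 2
        )
        return (self.means[1] - self.means[0]) < pooled

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.weights[0] * stats.norm.pdf(x, self.means[0], self.sds[0]) + (
            self.weights[1] * stats.norm.pdf(x, self.means[1], self.sds[1])
        )

    def posterior(self, x) -> np.ndarray:
        """Posterior probability of the upper component at ``x``."""
        x = np.asarray(x, dtype=float)
        a = self.weights[0] * stats.norm.pdf(x, self.means[0], self.sds[0])
        b = self.weights[1] * stats.norm.pdf(x, self.means[1], self.sds[1])
        return b / (a + b)

    def crossing_cutoff(self) -> float:
        return gmm_crossing_cutoff(self)

    def summary(self) -> str:
        return (
            "Two-component Gaussian mixture\n"
            f"  weights: {self.weights[0]:.4f} / {self.weights[1]:.4f}\n"
            f"  means:   {self.means[0]:.4f} / {self.means[1]:.4f}\n"
            f"  sds:     {self.sds[0]:.4f} / {self.sds[1]:.4f}\n"
            f"  log-likelihood: {self.log_likelihood[-1]:.4f} "
            f"({self.n_iter} iterations, converged={self.converged})"
        )


@dataclass
class TwoComponentGMM:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialization is a deterministic median split (values below/above the
    median seed the components), so repeated fits are identical without
    multi-start.  A variance floor of ``1e-4 * var(values)`` averts component
    collapse; if the floor binds at convergence the fit is flagged and a
    :class:`DegenerateFitError` is raised unless ``allow_floor=True``.

    ``variance_structure`` mirrors the model-selection default of standard
    mixture software: ``"select"`` fits both the shared-variance and the
    free-variance model and keeps the one with the lower BIC; ``"equal"`` and
    ``"free"`` force a structure.  The equal-variance model stabilizes the
    equal-likelihood crossing considerably when the components' spreads do
    not genuinely differ.
    """

    values: np.ndarray
    tol: float = 1e-8
    max_iter: int = 1000
    allow_floor: bool = False
    variance_structure: str = "select"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 10:
            raise ValueError(f"need >= 10 finite values, got {v.size}")
        self.values = v

    def fit(self) -> GMMResults:
        if self.variance_structure not in ("select", "equal", "free"):
            raise ValueError(f"unknown variance_structure {self.variance_structure!r}")
        if self.variance_structure == "select":
            fits = [self._fit_one(eq) for eq in (True, False)]
            result = min(fits, key=lambda f: f.bic)
        else:
            result = self._fit_one(self.variance_structure == "equal")
        if result.variance_floor_active and not self.allow_floor:
            raise DegenerateFitError(
                "variance collapsed to the floor; rerun with allow_floor=True "
                "if an (unreliable) fit is still wanted"
            )
        return result

    def _fit_one(self, equal_variance: bool) -> GMMResults:
        x = self.values
        n = x.size
        floor = 1e-4 * np.var(x)
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        w = np.array([lo.size / n, hi.size / n])
        mu = np.array([lo.mean(), hi.mean()])
        var = np.array([max(lo.var(), floor), max(hi.var(), floor)])
        if equal_variance:
            var[:] = var.mean()
        loglik: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E step
            dens = w * stats.norm.pdf(x[:, None], mu, np.sqrt(var))
            total = dens.sum(axis=1)
            total = np.where(total <= 0, np.finfo(float).tiny, total)
            resp = dens / total[:, None]
            ll = float(np.log(total).sum())
            loglik.append(ll)
            if len(loglik) > 1 and abs(loglik[-1] - loglik[-2]) < self.tol:
                converged = True
                break
            # M step
            nk = resp.sum(axis=0)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
            if equal_variance:
                var[:] = (nk * var).sum() / n
            var = np.maximum(var, floor)
        floor_active = bool(np.any(var <= floor * (1 + 1e-12)))
        order = np.argsort(mu)
        n_params = 4 if equal_variance else 5
        return GMMResults(
            weights=tuple(w[order]),
            means=tuple(mu[order]),
            sds=tuple(np.sqrt(var[order])),
            log_likelihood=loglik,
            converged=converged,
            n_iter=it,
            variance_floor_active=floor_active,
            variance_structure="equal" if equal_variance else "free",
            bic=float(n_params * np.log(n) - 2.0 * loglik[-1]),
        )


def fit_two_component_gmm(
    values,
    tol: float = 1e-8,
    max_iter: int = 1000,
    allow_floor: bool = False,
    variance_structure: str = "select",
) -> GMMResults:
    """Functional wrapper around :class:`TwoComponentGMM`."""
    return TwoComponentGMM(
        values,
        tol=tol,
        max_iter=max_iter,
        allow_floor=allow_floor,
        variance_structure=variance_structure,
    ).fit()


def gmm_crossing_cutoff(fit: GMMResults) -> float:
    """Equal-likelihood crossing of the two weighted component densities.

    Solves ``pi1 N(x; mu1, s1) = pi2 N(x; mu2, s2)`` analytically (quadratic
    in x after taking logs) and returns the root between the two means, at
    which the posterior probability of each component is exactly 0.5.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    # log w1 - log s1 - (x-m1)^2 / (2 s1^2) = log w2 - log s2 - (x-m2)^2 / (2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log(w1 / w2)
        + np.log(s2 / s1)
    )
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise ValueError("identical components have no crossing")
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise ValueError("no real crossing between the component densities")
        roots = np.array(
            [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        )
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise ValueError(
            f"no crossing between the means ({m1:.4g}, {m2:.4g}); "
            f"roots at {roots}: extreme weight imbalance"
        )
    return float(inside[0])


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _sens_spec_curve(
    values: np.ndarray, labels: np.ndarray, cands: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity (P(x > t | pos)) and specificity (P(x <= t | neg)) at each
    candidate threshold, via sorted-array bisection."""
    pos = np.sort(values[labels == 1])
    neg = np.sort(values[labels == 0])
    sens = 1.0 - np.searchsorted(pos, cands, side="right") / pos.size
    spec = np.searchsorted(neg, cands, side="right") / neg.size
    return sens, spec


def youden_cutoff(values, labels) -> dict:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent sorted unique values (plus
    sentinels beyond the data range); a value above the cutoff is called
    positive.  Ties in J resolve toward the smallest cutoff.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden's index needs both classes present")
    cands = _candidate_thresholds(values)
    sens, spec = _sens_spec_curve(values, labels, cands)
    j = sens + spec - 1.0
    i = int(np.argmax(j > j.max() - 1e-12))  # ties -> smallest cutoff
    return {
        "cutoff": float(cands[i]),
        "J": float(j[i]),
        "sensitivity": float(sens[i]),
        "specificity": float(spec[i]),
    }


def dual_cutoffs(values, labels, sens_target: float = 0.95, spec_target: float = 0.95) -> dict:
    """Lower (95% sensitivity) and upper (95% specificity) cutoffs.

    ``lower`` is the largest candidate threshold whose sensitivity still
    meets ``sens_target``; ``upper`` the smallest meeting ``spec_target``.
    On well-separated classes the two may cross (lower >= upper); that is
    allowed and flagged as an empty intermediate zone.
    """
    if not (0.5 < sens_target < 1 and 0.5 < spec_target < 1):
        raise ValueError("targets must lie in (0.5, 1)")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    if len(np.unique(labels)) < 2:
        raise ValueError("dual cutoffs need both classes present")
    cands = _candidate_thresholds(values)
    sens, spec = _sens_spec_curve(values, labels, cands)
    meets_sens = np.nonzero(sens >= sens_target)[0]
    meets_spec = np.nonzero(spec >= spec_target)[0]
    warnings = []
    if meets_sens.size:
        lower = float(cands[meets_sens[-1]])
        lower_sens = float(sens[meets_sens[-1]])
    else:  # unattainable: fall back to the boundary
        lower = float(cands[0])
        lower_sens = float(sens[0])
        warnings.append(f"sensitivity target {sens_target} unattainable")
    if meets_spec.size:
        upper = float(cands[meets_spec[0]])
        upper_spec = float(spec[meets_spec[0]])
    else:
        upper = float(cands[-1])
        upper_spec = float(spec[-1])
        warnings.append(f"specificity target {spec_target} unattainable")
    if lower >= upper:
        warnings.append("cutoffs cross: no intermediate zone (well-separated classes)")
    return {
        "lower": lower,
        "upper": upper,
        "sensitivity_at_lower": lower_sens,
        "specificity_at_upper": upper_spec,
        "warnings": warnings,
    }


@dataclass
class CutoffSet:
    """All derived cutoffs for one biomarker, on the z scale."""

    gmm_cutoff: float | None = None
    youden_cutoff: float | None = None
    lower_cutoff: float | None = None
    upper_cutoff: float | None = None
    linear_npq_equivalents: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def with_linear(self, norm_params, analyte: str) -> "CutoffSet":
        from .matrix import zscore_to_linear

        eq = {}
        for name in ("gmm_cutoff", "youden_cutoff", "lower_cutoff", "upper_cutoff"):
            z = getattr(self, name)
            if z is not None:
                eq[name] = float(zscore_to_linear(z, norm_params, analyte))
        self.linear_npq_equivalents = eq
        return self


def classify_three_way(values, lower: float, upper: float) -> dict:
    """Tri-class labeling: low (< lower), intermediate, high (> upper).

    Missing values are excluded and counted separately; class counts sum to
    the number of finite values; percentages reported to two decimals (half
    away from zero).
    """
    if lower > upper:
        raise ValueError(f"lower cutoff {lower} exceeds upper cutoff {upper}")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    v = values[finite]
    labels = np.full(values.shape, "missing", dtype=object)
    lab = np.where(v < lower, "low", np.where(v > upper, "high", "intermediate"))
    labels[finite] = lab
    n = int(v.size)
    counts = {k: int(np.sum(lab == k)) for k in ("low", "intermediate", "high")}
    percents = {k: pct(c, n) for k, c in counts.items()} if n else {}
    return {
        "labels": labels,
        "counts": counts,
        "percent": percents,
        "n": n,
        "n_missing": int((~finite).sum()),
    }
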