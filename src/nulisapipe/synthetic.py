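"""Synthetic mixed-dementia cohort generator.

Emulates the statistical structure a targeted plasma-proteomics panel study
assumes, so every downstream stage (QC, surrogate-variable-adjusted
differential abundance, cutoff derivation, concordance, progression) can be
exercised with known ground truth and no external data:

* ~123 analytes on a log2 abundance (NPQ) scale with heteroscedastic
  per-analyte noise,
* five diagnostic groups (CO, AD, DLB, FTD, PD) with configurable per-protein
  effect sizes in within-group-SD units, plus age and sex covariate effects,
* latent batch factors of configurable rank (the confounding surrogate
  variables are meant to absorb),
* missing-completely-at-random cells and +/-(3-6)xIQR outliers (so the QC
  fence provably catches them),
* a bimodal biomarker (two-component Gaussian mixture on the z scale) coupled
  to a latent amyloid variable with a Centiloid-style positivity threshold,
* an APOE-e4 proteoform signal separated by genotype with configurable
  overlap,
* proportional-hazards progression times for baseline-unimpaired
  participants.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_rng
from .matrix import AnalyteMatrix

GROUPS = ("CO", "AD", "DLB", "FTD", "PD")
DISEASES = ("AD", "DLB", "FTD", "PD")

# group-level demographics in the style of a memory-clinic cohort
_AGE_MEAN = {"CO": 72.8, "AD": 77.4, "DLB": 75.2, "FTD": 67.3, "PD": 71.7}
_AGE_SD = {"CO": 10.6, "AD": 8.5, "DLB": 8.1, "FTD": 9.2, "PD": 8.5}
_FEMALE_FRAC = {"CO": 0.597, "AD": 0.558, "DLB": 0.333, "FTD": 0.362, "PD": 0.365}

DEFAULT_APOE_FREQS = {
    "e2/e2": 0.01,
    "e2/e3": 0.12,
    "e3/e3": 0.52,
    "e2/e4": 0.02,
    "e3/e4": 0.27,
    "e4/e4": 0.06,
}

BIOMARKER_ANALYTE = "pTau217"
APOE_ANALYTE = "APOE4_proteoform"


class ConfigurationError(ValueError):
    """A cohort configuration field violates its invariant."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Effects are expressed in within-group SD units; ``effect_matrix`` has one
    row per analyte and one column per disease group (AD, DLB, FTD, PD), with
    CO as the implicit reference.  ``mixture_params`` are (weight, mean, sd)
    pairs for the bimodal biomarker on its z scale.
    """

    n_per_group: int = 200
    n_analytes: int = 123
    effect_matrix: np.ndarray | None = None  # (n_analytes, 4); None -> zeros
    age_effect: np.ndarray | None = None  # per-analyte slope per year of age
    sex_effect: np.ndarray | None = None  # per-analyte female-vs-male shift
    n_latent: int = 2
    latent_sd: float = 0.3
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    mixture_params: tuple = ((0.54, -0.8, 0.6), (0.46, 0.9, 0.7))
    amyloid_coupling: float = 0.8
    centiloid_threshold: float = 20.0
    hazard_log_hr: dict = field(default_factory=dict)  # analyte -> log HR
    baseline_rate: float = 0.02  # events per year for the reference subject
    censor_rate: float = 0.6
    apoe_freqs: dict = field(default_factory=lambda: dict(DEFAULT_APOE_FREQS))
    apoe_separation: float = 2.5  # proteoform shift per e4 allele, in noise SDs
    repeat_fraction: float = 0.0  # fraction of participants with a second draw
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_analytes < 1:
            raise ConfigurationError("n_analytes must be >= 1")
        for name in ("missing_rate", "outlier_rate", "censor_rate", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.amyloid_coupling <= 1.0:
            raise ConfigurationError("amyloid_coupling must lie in [-1, 1]")
        weights = [p[0] for p in self.mixture_params]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("mixture_params weights must sum to 1")
        if any(p[2] <= 0 for p in self.mixture_params):
            raise ConfigurationError("mixture_params sds must be > 0")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be > 0")
        if self.n_latent < 0:
            raise ConfigurationError("n_latent must be >= 0")
        if self.latent_sd < 0:
            raise ConfigurationError("latent_sd must be >= 0")
        if abs(sum(self.apoe_freqs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("apoe_freqs must sum to 1")
        if self.effect_matrix is not None:
            em = np.asarray(self.effect_matrix, dtype=float)
            if em.shape != (self.n_analytes, len(DISEASES)):
                raise ConfigurationError(
                    f"effect_matrix must have shape ({self.n_analytes}, "
                    f"{len(DISEASES)}), got {em.shape}"
                )


@dataclass
class SyntheticCohort:
    """A generated cohort: abundance matrix, sample annotation, ground truth."""

    matrix: AnalyteMatrix
    annotation: pd.DataFrame
    truth: dict
    config: CohortConfig

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_tsv(outdir / "matrix.tsv")
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        serializable = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        (outdir / "truth.json").write_text(json.dumps(serializable, indent=1))


def default_effect_matrix(
    n_analytes: int,
    rng,
    frac_affected: dict | None = None,
    effect_sd: float = 0.45,
) -> np.ndarray:
    """A study-like sparse effect matrix: most signal for AD, least for FTD.

    Per disease a fraction of analytes carries a nonzero effect drawn
    N(0, effect_sd^2); fractions default to the relative discovery yields of
    a mixed-dementia panel (AD >> PD > DLB > FTD).
    """
    rng = check_rng(rng)
    frac = frac_affected or {"AD": 0.65, "DLB": 0.17, "FTD": 0.05, "PD": 0.4}
    em = np.zeros((n_analytes, len(DISEASES)))
    for j, dis in enumerate(DISEASES):
        hit = rng.random(n_analytes) < frac[dis]
        em[hit, j] = rng.normal(0.0, effect_sd, hit.sum())
    return em


def generate_bimodal_biomarker(
    config: CohortConfig, n: int, rng=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the bimodal biomarker with its coupled latent amyloid variable.

    Returns ``(values, centiloid, positive, component)``.  Values come from
    the stated two-component normal mixture; the latent amyloid variable is a
    Gaussian blend with correlation ``amyloid_coupling`` to the standardized
    biomarker, rescaled to a Centiloid-like axis centred on the positivity
    threshold; positivity = centiloid > threshold.
    """
    if len(config.mixture_params) != 2:
        raise ConfigurationError(
            f"bimodal biomarker requires exactly 2 mixture components, "
            f"got {len(config.mixture_params)}"
        )
    rng = check_rng(rng if rng is not None else config.seed)
    (w1, m1, s1), (w2, m2, s2) = config.mixture_params
    component = (rng.random(n) < w2).astype(int)
    means = np.where(component == 1, m2, m1)
    sds = np.where(component == 1, s2, s1)
    values = rng.normal(means, sds)
    mix_mean = w1 * m1 + w2 * m2
    mix_var = w1 * (s1**2 + m1**2) + w2 * (s2**2 + m2**2) - mix_mean**2
    b_std = (values - mix_mean) / np.sqrt(mix_var)
    c = config.amyloid_coupling
    latent = c * b_std + np.sqrt(max(0.0, 1.0 - c**2)) * rng.normal(size=n)
    centiloid = config.centiloid_threshold + 30.0 * latent
    positive = centiloid > config.centiloid_threshold
    return values, centiloid, positive, component


def generate_survival_times(
    config: CohortConfig, covariates: np.ndarray, log_hr: np.ndarray | None = None, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Proportional-hazards event times over an exponential baseline.

    ``covariates`` is (n, p); ``log_hr`` the p per-covariate log hazard
    ratios (defaults to the values in ``config.hazard_log_hr`` order).
    Censoring is an independent exponential with rate chosen so that the
    expected censoring fraction for a reference subject equals
    ``config.censor_rate``; ``censor_rate=0`` disables it.
    """
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if log_hr is None:
        log_hr = np.asarray(list(config.hazard_log_hr.values()), dtype=float)
    log_hr = np.asarray(log_hr, dtype=float)
    if covariates.shape[1] != log_hr.shape[0]:
        raise ConfigurationError(
            f"hazard_log_hr length {log_hr.shape[0]} does not match "
            f"covariate count {covariates.shape[1]}"
        )
    if config.baseline_rate <= 0:
        raise ConfigurationError("baseline_rate must be > 0")
    rng = check_rng(rng if rng is not None else config.seed)
    n = covariates.shape[0]
    rate = config.baseline_rate * np.exp(covariates @ log_hr)
    times = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        cens_rate = config.baseline_rate * config.censor_rate / (1.0 - config.censor_rate)
        cens = rng.exponential(1.0 / cens_rate, size=n)
    else:
        cens = np.full(n, np.inf)
    observed = np.minimum(times, cens)
    event = (times <= cens).astype(int)
    return observed, event


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort per the configuration (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_a = config.n_analytes
    analyte_ids = [f"P{i:03d}" for i in range(n_a)]
    # the last two analytes play the named biomarker / APOE proteoform roles
    if n_a >= 2:
        analyte_ids[-2] = BIOMARKER_ANALYTE
        analyte_ids[-1] = APOE_ANALYTE

    groups = np.repeat(GROUPS, config.n_per_group)
    n = len(groups)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    participant_ids = [f"PT{i:04d}" for i in range(n)]

    age = np.array(
        [rng.normal(_AGE_MEAN[g], _AGE_SD[g]) for g in groups]
    ).clip(45, 100)
    female = np.array(
        [rng.random() < _FEMALE_FRAC[g] for g in groups]
    ).astype(int)

    genotypes = list(config.apoe_freqs)
    probs = np.array([config.apoe_freqs[g] for g in genotypes])
    apoe = rng.choice(genotypes, size=n, p=probs)
    e4_dose = np.array([g.count("e4") for g in apoe])

    analyte_sd = np.exp(rng.uniform(np.log(0.2), np.log(1.0), n_a))
    baseline = rng.uniform(8.0, 16.0, n_a)
    em = (
        np.zeros((n_a, len(DISEASES)))
        if config.effect_matrix is None
        else np.asarray(config.effect_matrix, dtype=float)
    )
    age_eff = (
        np.zeros(n_a) if config.age_effect is None else np.asarray(config.age_effect)
    )
    sex_eff = (
        np.zeros(n_a) if config.sex_effect is None else np.asarray(config.sex_effect)
    )

    y = np.tile(baseline, (n, 1))
    for j, dis in enumerate(DISEASES):
        in_g = groups == dis
        y[in_g] += em[:, j] * analyte_sd
    y += np.outer(age - 73.0, age_eff)
    y += np.outer(female, sex_eff)

    if config.n_latent > 0:
        loadings = rng.normal(0.0, config.latent_sd, (n_a, config.n_latent))
        factors = rng.normal(size=(n, config.n_latent))
        y += (factors @ loadings.T) * analyte_sd
    else:
        loadings = np.zeros((n_a, 0))
        factors = np.zeros((n, 0))

    y += rng.normal(0.0, 1.0, (n, n_a)) * analyte_sd

    # bimodal biomarker column (log2 scale: mixture z values mapped onto a
    # realistic abundance axis) + latent amyloid
    bio_vals, centiloid, amyloid_pos, component = generate_bimodal_biomarker(
        config, n, rng
    )
    if n_a >= 2:
        bio_col = analyte_ids.index(BIOMARKER_ANALYTE)
        y[:, bio_col] = 12.0 + 1.2 * bio_vals
        # APOE proteoform: genotype-conditional normals with configurable
        # overlap; carrier status dominates, with a small homozygote bump
        apoe_col = analyte_ids.index(APOE_ANALYTE)
        y[:, apoe_col] = (
            9.0
            + config.apoe_separation * (e4_dose > 0)
            + 0.3 * (e4_dose == 2)
            + rng.normal(size=n)
        )

    # outliers then missingness, so the QC fence sees the planted spikes
    outlier_mask = rng.random((n, n_a)) < config.outlier_rate
    if outlier_mask.any():
        q1 = np.percentile(y, 25, axis=0)
        q3 = np.percentile(y, 75, axis=0)
        iqr = np.maximum(q3 - q1, 1e-6)
        magnitude = rng.uniform(3.0, 6.0, (n, n_a)) * iqr
        sign = np.where(rng.random((n, n_a)) < 0.5, -1.0, 1.0)
        y = np.where(outlier_mask, y + sign * magnitude, y)
    missing_mask = rng.random((n, n_a)) < config.missing_rate
    y = np.where(missing_mask, np.nan, y)

    # progression among baseline controls: hazard driven by configured analytes
    is_co = groups == "CO"
    n_co = int(is_co.sum())
    hr_analytes = list(config.hazard_log_hr)
    if hr_analytes:
        cols = [analyte_ids.index(a) for a in hr_analytes]
        cov = y[np.ix_(is_co, cols)]
        col_mean = np.nanmean(cov, axis=0)
        col_sd = np.nanstd(cov, axis=0, ddof=1)
        cov = (np.where(np.isnan(cov), col_mean, cov) - col_mean) / col_sd
        log_hr = np.array([config.hazard_log_hr[a] for a in hr_analytes])
    else:
        cov = np.zeros((n_co, 0))
        log_hr = np.zeros(0)
    surv_time, surv_event = generate_survival_times(config, cov, log_hr, rng)
    surv_time = np.clip(surv_time, 0.05, None)

    time_col = np.full(n, np.nan)
    event_col = np.full(n, np.nan)
    time_col[is_co] = surv_time
    event_col[is_co] = surv_event

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "participant_id": participant_ids,
            "group": groups,
            "age": np.round(age, 1),
            "sex": np.where(female == 1, "F", "M"),
            "apoe": apoe,
            "centiloid": np.round(centiloid, 2),
            "amyloid_positive": amyloid_pos.astype(int),
            "time_to_event": time_col,
            "event": event_col,
        }
    )

    # optional repeated draws: a fraction of participants contributes a
    # second, later sample (same biology, fresh measurement noise) so the
    # one-sample-per-participant selection rule downstream is exercisable
    if config.repeat_fraction > 0:
        n_rep = int(round(config.repeat_fraction * n))
        rep_idx = rng.choice(n, size=n_rep, replace=False)
        rep_rows = []
        for k, i in enumerate(sorted(rep_idx)):
            rep_vals = y[i] + rng.normal(0.0, 0.3, n_a) * analyte_sd
            rep_id = f"S{n + k:04d}"
            rep_rows.append((rep_id, i, rep_vals))
        if rep_rows:
            extra = pd.DataFrame(
                [r[2] for r in rep_rows],
                index=[r[0] for r in rep_rows],
                columns=analyte_ids,
            )
            extra_ann = annotation.iloc[[r[1] for r in rep_rows]].copy()
            extra_ann["sample_id"] = [r[0] for r in rep_rows]
            extra_ann["age"] = extra_ann["age"] + np.round(
                rng.uniform(0.5, 3.0, len(rep_rows)), 1
            )
            annotation = pd.concat([annotation, extra_ann], ignore_index=True)
    else:
        extra = None

    values_df = pd.DataFrame(y, index=sample_ids, columns=analyte_ids)
    if extra is not None:
        values_df = pd.concat([values_df, extra])
    matrix = AnalyteMatrix(
        values_df,
        scale="log2_npq",
        meta={"seed": config.seed},
    )
    truth = {
        "effect_matrix": em,
        "analyte_sd": analyte_sd,
        "baseline": baseline,
        "latent_factors": factors,
        "latent_loadings": loadings,
        "component": component,
        "amyloid_positive": amyloid_pos.astype(int),
        "centiloid": centiloid,
        "log_hr": {a: config.hazard_log_hr[a] for a in hr_analytes},
        "apoe_genotype": list(apoe),
        "outlier_mask": outlier_mask,
        "missing_mask": missing_mask,
        "diseases": list(DISEASES),
        "analyte_ids": analyte_ids,
    }
    return SyntheticCohort(matrix, annotation, truth, config)
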