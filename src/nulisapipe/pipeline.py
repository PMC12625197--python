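"""End-to-end orchestration: simulate -> qc -> normalize -> daa -> compare ->
cutoff -> evaluate -> progress, driven by one YAML config, with a JSON run
manifest recording seeds, input hashes and per-stage outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_disease import (
    EffectSizeTable,
    build_scorecard,
    cluster_effect_matrix,
    compare_contrasts,
    correlation_matrix,
)
from .cutoffs import (
    CutoffSet,
    classify_three_way,
    dual_cutoffs,
    fit_two_component_gmm,
    gmm_crossing_cutoff,
    youden_cutoff,
)
from .daa import DifferentialAbundanceModel
from .evaluation import confusion_metrics, roc_auc_delong
from .matrix import AnalyteMatrix, normalize_npq
from .progression import fit_cox_per_protein, horizon_auc, km_estimate
from .qc import run_qc
from .synthetic import (
    BIOMARKER_ANALYTE,
    DISEASES,
    CohortConfig,
    default_effect_matrix,
    generate_cohort,
)


@dataclass
class RunConfig:
    """Pipeline run configuration (all thresholds surfaced, none hard-coded)."""

    outdir: str = "run_out"
    seed: int = 0
    n_per_group: int = 200
    n_analytes: int = 40
    call_rate_thresholds: tuple = (0.65, 0.85)
    fdr_threshold: float = 0.05
    nominal_threshold: float = 0.05
    centiloid_threshold: float = 20.0
    tau_suvr_threshold: float = 1.5
    csf_ratio_threshold: float = 0.0673
    n_sv: int = 2
    horizons: tuple = (5.0, 10.0, 15.0)
    hazard_log_hr: dict = field(default_factory=dict)
    stages: tuple = ("simulate", "qc", "daa", "compare", "cutoff", "evaluate", "progress")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("call_rate_thresholds", "horizons", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        t1, t2 = self.call_rate_thresholds
        if not (0 < t1 < t2 <= 1):
            raise ValueError("call_rate_thresholds must be increasing in (0, 1]")
        for name in ("fdr_threshold", "nominal_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages on a seeded synthetic cohort.

    Returns (and writes) a manifest mapping each stage to its outputs; a
    stage failure marks the stage failed and skips dependents.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    state: dict = {}

    def record(stage: str, outputs: dict) -> None:
        hashed = {}
        for name, path in outputs.items():
            p = Path(path)
            hashed[name] = {"path": str(p), "sha256_16": _hash_file(p)}
        manifest["stages"][stage] = {"status": "ok", "outputs": hashed}

    stage_order = [s for s in ("simulate", "qc", "daa", "compare", "cutoff", "evaluate", "progress") if s in config.stages]
    failed = False
    for stage in stage_order:
        if failed:
            manifest["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        try:
            _STAGES[stage](config, state, outdir, rng, record)
        except Exception as e:  # noqa: BLE001 - manifest must record any failure
            manifest["stages"][stage] = {"status": f"failed: {e}"}
            failed = True
    manifest["ok"] = not failed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_simulate(config, state, outdir, rng, record):
    em = default_effect_matrix(config.n_analytes, np.random.default_rng(config.seed + 1))
    hazard = config.hazard_log_hr or {BIOMARKER_ANALYTE: 0.47, "P000": -0.4}
    cc = CohortConfig(
        n_per_group=config.n_per_group,
        n_analytes=config.n_analytes,
        effect_matrix=em,
        hazard_log_hr=hazard,
        centiloid_threshold=config.centiloid_threshold,
        seed=config.seed,
    )
    cohort = generate_cohort(cc)
    cohort.write(outdir / "cohort")
    state["cohort"] = cohort
    record(
        "simulate",
        {
            "matrix": outdir / "cohort" / "matrix.tsv",
            "annotation": outdir / "cohort" / "annotation.tsv",
            "truth": outdir / "cohort" / "truth.json",
        },
    )


def _stage_qc(config, state, outdir, rng, record):
    cohort = state["cohort"]
    filtered, report = run_qc(cohort.matrix, config.call_rate_thresholds)
    z = normalize_npq(filtered, "zscore")
    state["qced"] = filtered
    state["z"] = z
    qc_rows = pd.DataFrame(
        {
            "id": list(report.removed_analytes) + list(report.removed_samples),
            "axis": ["analyte"] * len(report.removed_analytes)
            + ["sample"] * len(report.removed_samples),
            "step": list(report.removed_analytes.values())
            + list(report.removed_samples.values()),
        }
    )
    qc_path = outdir / "qc_report.tsv"
    qc_rows.to_csv(qc_path, sep="\t", index=False)
    summary = {
        "seed": config.seed,
        "n_analytes_in": cohort.matrix.shape[1],
        "n_samples_in": cohort.matrix.shape[0],
        "n_analytes_out": filtered.shape[1],
        "n_samples_out": filtered.shape[0],
        "outliers_masked": int(report.outlier_counts.sum()),
        "quantile_convention": report.quantile_convention,
    }
    (outdir / "qc_summary.json").write_text(json.dumps(summary, indent=1))
    record("qc", {"qc_report": qc_path, "qc_summary": outdir / "qc_summary.json"})


def _stage_daa(config, state, outdir, rng, record):
    z = state["z"]
    ann = state["cohort"].annotation
    results = {}
    outputs = {}
    for disease in DISEASES:
        model = DifferentialAbundanceModel(
            z, ann, f"{disease}_vs_CO", n_sv=config.n_sv, seed=config.seed
        )
        res = model.fit()
        results[disease] = res
        path = outdir / f"daa_{disease}_vs_CO.tsv"
        res.to_tsv(path)
        outputs[f"daa_{disease}"] = path
    state["daa"] = results
    record("daa", outputs)


def _stage_compare(config, state, outdir, rng, record):
    table = EffectSizeTable.from_results(state["daa"])
    state["effect_table"] = table
    outputs = {}
    pairs = [
        (a, b)
        for i, a in enumerate(table.contrasts)
        for b in table.contrasts[i + 1 :]
    ]
    for pair in pairs:
        ztab = compare_contrasts(table, pair, config.fdr_threshold)
        path = outdir / f"ztest_{pair[0]}_{pair[1]}.tsv"
        ztab.to_csv(path, sep="\t")
        outputs[f"ztest_{pair[0]}_{pair[1]}"] = path
    corr = correlation_matrix(table)
    corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
    outputs["correlation_matrix"] = outdir / "correlation_matrix.tsv"
    card = build_scorecard(table, DISEASES, config.nominal_threshold, config.fdr_threshold)
    card.to_csv(outdir / "scorecard.tsv", sep="\t")
    outputs["scorecard"] = outdir / "scorecard.tsv"
    trees = cluster_effect_matrix(table)
    (outdir / "dendrogram.newick").write_text(
        trees["row_newick"] + "\n" + trees["col_newick"] + "\n"
    )
    outputs["dendrogram"] = outdir / "dendrogram.newick"
    record("compare", outputs)


def _stage_cutoff(config, state, outdir, rng, record):
    z = state["z"]
    ann = state["cohort"].annotation.set_index("sample_id")
    vals = z.values[BIOMARKER_ANALYTE].dropna()
    fit = fit_two_component_gmm(vals.to_numpy())
    gmm_cut = gmm_crossing_cutoff(fit)
    labels = ann.loc[vals.index, "amyloid_positive"].astype(int)
    yj = youden_cutoff(vals.to_numpy(), labels.to_numpy())
    dual = dual_cutoffs(vals.to_numpy(), labels.to_numpy())
    cuts = CutoffSet(
        gmm_cutoff=gmm_cut,
        youden_cutoff=yj["cutoff"],
        lower_cutoff=dual["lower"],
        upper_cutoff=dual["upper"],
        details={"youden": yj, "dual": dual, "gmm": fit.summary()},
    ).with_linear(z.norm_params, BIOMARKER_ANALYTE)
    state["cutoffs"] = cuts
    state["biomarker_values"] = vals
    state["biomarker_labels"] = labels
    payload = {
        "seed": config.seed,
        "gmm_cutoff": cuts.gmm_cutoff,
        "youden_cutoff": cuts.youden_cutoff,
        "lower_cutoff": cuts.lower_cutoff,
        "upper_cutoff": cuts.upper_cutoff,
        "linear_npq_equivalents": cuts.linear_npq_equivalents,
        "gmm": {
            "weights": list(fit.weights),
            "means": list(fit.means),
            "sds": list(fit.sds),
            "converged": fit.converged,
        },
    }
    (outdir / "cutoffs.json").write_text(json.dumps(payload, indent=1))
    if cuts.lower_cutoff <= cuts.upper_cutoff:
        tri = classify_three_way(vals.to_numpy(), cuts.lower_cutoff, cuts.upper_cutoff)
        pd.DataFrame({"sample_id": vals.index, "class": tri["labels"]}).to_csv(
            outdir / "triclass.tsv", sep="\t", index=False
        )
    record("cutoff", {"cutoffs": outdir / "cutoffs.json"})


def _stage_evaluate(config, state, outdir, rng, record):
    vals = state["biomarker_values"]
    labels = state["biomarker_labels"]
    cuts = state["cutoffs"]
    pred = (vals > cuts.gmm_cutoff).astype(int)
    conf = confusion_metrics(pred, labels)
    roc = roc_auc_delong(vals.to_numpy(), labels.to_numpy())
    metrics = {
        "seed": config.seed,
        "pet_concordance_pct": conf.concordance,
        "ppv": conf.ppv,
        "npv": conf.npv,
        "auc": roc.auc,
        "auc_ci": [roc.ci_low, roc.ci_high],
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    record("evaluate", {"metrics": outdir / "metrics.json"})


def _stage_progress(config, state, outdir, rng, record):
    z = state["z"]
    ann = state["cohort"].annotation.set_index("sample_id")
    co = ann[ann["group"] == "CO"].dropna(subset=["time_to_event", "event"])
    idx = co.index.intersection(z.values.index)
    markers = [a for a in (BIOMARKER_ANALYTE, "P000") if a in z.values.columns]
    rec = pd.DataFrame(
        {
            "time": co.loc[idx, "time_to_event"],
            "event": co.loc[idx, "event"].astype(int),
            "age": co.loc[idx, "age"],
            "sex": (co.loc[idx, "sex"] == "F").astype(float),
        }
    )
    for m in markers:
        rec[m] = z.values.loc[idx, m]
    res = fit_cox_per_protein(rec, markers)
    res.table.to_csv(outdir / "cox_results.tsv", sep="\t")
    cuts = state["cutoffs"]
    km_rec = rec.dropna(subset=[BIOMARKER_ANALYTE])
    dicho = (km_rec[BIOMARKER_ANALYTE] > cuts.gmm_cutoff).map({True: "high", False: "low"})
    km = km_estimate(km_rec, dicho)
    for g, curve in km["curves"].items():
        curve.to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
    rec["marker_high"] = (rec[BIOMARKER_ANALYTE] > cuts.gmm_cutoff).astype(float)
    aucs = horizon_auc(rec.dropna(), "marker_high", config.horizons)
    payload = {
        "seed": config.seed,
        "logrank_p": km["logrank_p"],
        "horizon_auc": {
            str(h): (r.auc if hasattr(r, "auc") else r) for h, r in aucs.items()
        },
    }
    (outdir / "horizon_auc.json").write_text(json.dumps(payload, indent=1))
    record(
        "progress",
        {"cox": outdir / "cox_results.tsv", "horizon_auc": outdir / "horizon_auc.json"},
    )


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "daa": _stage_daa,
    "compare": _stage_compare,
    "cutoff": _stage_cutoff,
    "evaluate": _stage_evaluate,
    "progress": _stage_progress,
}
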