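"""End-to-end orchestration: peak lists → matrix → scores → cohort report.

Ties the stage modules together in the order a study would run them:
per-sample quality filtering, charge deconvolution, migration-time
calibration, housekeeping normalization; cross-sample matching into the
peptide matrix; classifier scoring; and the cohort statistics (score vs
eGFR and proteinuria, stage-group GLM, clustering, per-peptide
correlations, monotone-peptide selection, prognostic table).  Every
statistic lands in a machine-readable report together with the full
configuration and input hashes.
"""

from __future__ import annotations

import hashlib
import time as _time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .classify import ClassifierModel, prognostic_table, score_matrix
from .cohort import (
    assign_stage_group,
    cluster_patients,
    compare_clusters,
    correlate,
    fit_line,
    glm_f_unbalanced,
    mdrd_egfr,
    monotone_peptides,
    per_peptide_egfr_correlation,
)
from .config import RunConfig
from .errors import StageError
from .matching import PeptideMatrix, build_matrix, presence_filter
from .peaks import PeptideFeature, RawSignal, deconvolute, filter_signals
from .register import (
    CalibrationDiagnostics,
    HousekeepingPanel,
    ReferencePanel,
    calibrate_times,
    normalize_intensities,
)


@dataclass
class SampleQC:
    sample_id: str
    n_signals_raw: int
    n_signals_filtered: int
    n_features: int
    calibration: CalibrationDiagnostics
    scale_factor: float
    n_housekeeping: int


@dataclass
class StudyResult:
    patients: pd.DataFrame
    matrix: PeptideMatrix          # presence-filtered
    matrix_full: PeptideMatrix
    scores: pd.DataFrame
    qc: list[SampleQC]
    report: dict = field(default_factory=dict)


def process_sample(
    signals: Sequence[RawSignal],
    reference: ReferencePanel,
    housekeeping: HousekeepingPanel,
    cfg: RunConfig,
    sample_id: str = "sample",
) -> tuple[list[PeptideFeature], SampleQC]:
    """Raw peak list → filtered, deconvoluted, calibrated, normalized features."""
    t = cfg.tolerances
    kept = filter_signals(
        signals, min_charge_excl=t.min_charge_excl, min_snr=t.snr,
        min_spectra=t.min_spectra,
    )
    features = deconvolute(kept, mass_tol_ppm=t.deconv_ppm, time_tol_min=t.deconv_dt_min)
    features, diag = calibrate_times(
        features, reference,
        span=cfg.calibration.span, min_anchors=cfg.calibration.min_anchors,
        ppm=t.ppm, anchor_dt=cfg.calibration.anchor_dt, control_dt=t.dt_min,
        sample_id=sample_id,
    )
    features, scale, n_hk = normalize_intensities(
        features, housekeeping, ppm=t.ppm, dt=t.dt_min,
        min_hk=cfg.normalization.min_hk, sample_id=sample_id,
    )
    qc = SampleQC(
        sample_id=sample_id,
        n_signals_raw=len(list(signals)),
        n_signals_filtered=len(kept),
        n_features=len(features),
        calibration=diag,
        scale_factor=scale,
        n_housekeeping=n_hk,
    )
    return features, qc


def analyze_cohort(
    matrix: PeptideMatrix,
    patients: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Cohort statistics on the assembled matrix, clinical table and scores.

    Dialysis patients get no eGFR (it does not apply under dialysis) and
    are excluded from every eGFR-based association; they remain in the
    clustering and outcome analyses.
    """
    a = cfg.analysis
    patients = patients.copy()
    egfr = pd.Series(
        mdrd_egfr(
            patients["creatinine_umol_l"].to_numpy(dtype=float),
            patients["age_years"].to_numpy(dtype=float),
            list(patients["sex"]),
        ),
        index=patients.index,
    )
    egfr[patients["dialysis"].astype(bool)] = np.nan
    patients["egfr"] = egfr

    common = [s for s in matrix.sample_ids if s in patients.index]
    sc = scores.loc[common, "score"]
    p = patients.loc[common]

    non_dial = p.index[~p["dialysis"].astype(bool)]
    report: dict = {"n_samples": len(common), "n_dialysis": int(p["dialysis"].sum())}

    pear = correlate(sc.loc[non_dial], p.loc[non_dial, "egfr"], "pearson")
    spear_egfr = correlate(sc.loc[non_dial], p.loc[non_dial, "egfr"], "spearman")
    line = fit_line(p.loc[non_dial, "egfr"], sc.loc[non_dial])
    rho_prot = correlate(sc, p["urine_protein_g_per_g"], "spearman")
    report["score_vs_egfr"] = {
        "pearson_r": pear.value, "pearson_p": pear.p_value,
        "spearman_rho": spear_egfr.value, "n": pear.n,
        "ols_slope": line.slope, "ols_intercept": line.intercept,
        "ols_r_squared": line.r_squared,
    }
    report["score_vs_proteinuria"] = {
        "spearman_rho": rho_prot.value, "p": rho_prot.p_value, "n": rho_prot.n,
    }

    stage = pd.Series(
        assign_stage_group(p.loc[non_dial, "egfr"].to_numpy(dtype=float), a.stage_cutpoints),
        index=non_dial,
    )
    if stage.nunique() >= 2:
        glm = glm_f_unbalanced(sc.loc[non_dial].to_numpy(), stage.to_numpy())
        report["score_by_stage"] = {
            "glm_f": glm.value, "p": glm.p_value, "df": list(glm.df),
            "group_sizes": {int(k): int(v) for k, v in stage.value_counts().sort_index().items()},
        }

    assignments, _Z = cluster_patients(matrix, k=a.k_clusters)
    report["clusters"] = {
        "k": a.k_clusters,
        "sizes": {int(k): int(v) for k, v in assignments.value_counts().sort_index().items()},
    }
    try:
        comp = compare_clusters(
            patients, assignments,
            ["egfr", "creatinine_umol_l", "urine_protein_g_per_g", "age_years"],
        )
        report["cluster_comparison"] = comp.reset_index().to_dict(orient="records")
    except Exception as exc:  # degenerate clustering on tiny cohorts
        report["cluster_comparison"] = {"error": str(exc)}

    ppc = per_peptide_egfr_correlation(matrix, patients)
    report["per_peptide"] = {
        "n_peptides": int(len(ppc)),
        "n_significant_raw": int((ppc["p"] < 0.05).sum()),
        "n_significant_bh": int((ppc["p_adj"] < 0.05).sum()),
        "n_increased_with_ckd": int(
            ((ppc["p"] < 0.05) & (ppc["direction"] == "increased-with-CKD")).sum()
        ),
        "n_decreased_with_ckd": int(
            ((ppc["p"] < 0.05) & (ppc["direction"] == "decreased-with-CKD")).sum()
        ),
    }

    if stage.nunique() >= 2:
        selected, _table = monotone_peptides(matrix, stage, min_frac=a.presence_frac)
        report["monotone_peptides"] = {"n_selected": len(selected)}

    tab = prognostic_table(scores.loc[common], p["event"], cutoff=a.cutoff)
    report["prognosis"] = {
        "cutoff": a.cutoff,
        "events_above": tab.events_above,
        "events_below": tab.events_below,
        "nonevents_above": tab.nonevents_above,
        "nonevents_below": tab.nonevents_below,
        "n_unknown_outcome": tab.n_unknown_outcome,
        "sensitivity": tab.sensitivity,
        "specificity": tab.specificity,
        "npv": tab.npv,
    }
    report["cohort"] = {
        "mean_creatinine_umol_l": float(p["creatinine_umol_l"].mean()),
        "mean_egfr": float(p.loc[non_dial, "egfr"].mean()),
        "lost_to_followup_pct": 100.0 * float(p["event"].isna().mean()),
    }
    return report


def run_study(
    samples: Mapping[str, Sequence[RawSignal]],
    patients: pd.DataFrame,
    reference: ReferencePanel,
    housekeeping: HousekeepingPanel,
    model: ClassifierModel,
    cfg: RunConfig | None = None,
) -> StudyResult:
    """Full pipeline over a set of per-sample peak lists."""
    cfg = cfg or RunConfig()
    per_sample: dict[str, list[PeptideFeature]] = {}
    qcs: list[SampleQC] = []
    for sid, signals in samples.items():
        feats, qc = process_sample(signals, reference, housekeeping, cfg, sample_id=sid)
        per_sample[sid] = feats
        qcs.append(qc)

    matrix_full = build_matrix(per_sample, ppm=cfg.tolerances.ppm, dt=cfg.tolerances.dt_min)
    matrix = presence_filter(matrix_full, min_frac=cfg.analysis.presence_frac)
    scores = score_matrix(matrix_full, model, ppm=cfg.tolerances.ppm, dt=cfg.tolerances.dt_min)
    report = analyze_cohort(matrix, patients, scores, cfg)
    report["qc"] = {
        "n_samples": len(qcs),
        "all_calibration_controls_passed": bool(all(q.calibration.passed_control for q in qcs)),
        "max_calibration_residual_min": max((q.calibration.max_residual for q in qcs), default=0.0),
        "median_scale_factor": float(np.median([q.scale_factor for q in qcs])) if qcs else None,
    }
    return StudyResult(
        patients=patients, matrix=matrix, matrix_full=matrix_full,
        scores=scores, qc=qcs, report=report,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(input_dir, out_dir, model_path, cfg: RunConfig | None = None) -> dict:
    """Directory-level pipeline: read inputs, run the study, write everything.

    Expects in ``input_dir``: clinical.tsv, reference_panel.tsv,
    housekeeping_panel.tsv and one ``<patient_id>.peaks.tsv`` per sample;
    the classifier model JSON is given separately.  Writes the feature
    matrix, scores, and a JSON report carrying every statistic, the full
    configuration actually used, stage timings, per-sample QC and the
    SHA-256 of every input consumed.
    """
    from pathlib import Path

    cfg = cfg or RunConfig()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    hashes: dict[str, str] = {}
    timings: dict[str, float] = {}

    t0 = _time.perf_counter()
    patients = cio.read_clinical(input_dir / "clinical.tsv")
    reference = cio.read_reference_panel(input_dir / "reference_panel.tsv")
    housekeeping = cio.read_housekeeping_panel(input_dir / "housekeeping_panel.tsv")
    model = cio.read_model(model_path)
    for f in ["clinical.tsv", "reference_panel.tsv", "housekeeping_panel.tsv"]:
        hashes[f] = _sha256(input_dir / f)
    hashes[Path(model_path).name] = _sha256(model_path)

    samples: dict[str, list[RawSignal]] = {}
    for pid in patients.index:
        peak_path = input_dir / f"{pid}.peaks.tsv"
        if not peak_path.exists():
            raise StageError("read", pid, f"missing peak list {peak_path}")
        samples[pid] = cio.read_peaklist(peak_path)
        hashes[peak_path.name] = _sha256(peak_path)
    timings["read_s"] = _time.perf_counter() - t0

    t1 = _time.perf_counter()
    result = run_study(samples, patients, reference, housekeeping, model, cfg)
    timings["pipeline_s"] = _time.perf_counter() - t1

    out_dir.mkdir(parents=True, exist_ok=True)
    cio.write_matrix(result.matrix_full, out_dir / "matrix.tsv")
    result.scores.reset_index().to_csv(
        out_dir / "scores.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report = {
        "config": cfg.to_dict(),
        "input_hashes": hashes,
        "timings": timings,
        "statistics": result.report,
        "per_sample_qc": [
            {
                "sample_id": q.sample_id,
                "n_signals_raw": q.n_signals_raw,
                "n_signals_filtered": q.n_signals_filtered,
                "n_features": q.n_features,
                "n_anchors": q.calibration.n_anchors,
                "calibration_residual_sd": q.calibration.residual_sd,
                "calibration_max_residual": q.calibration.max_residual,
                "calibration_passed": q.calibration.passed_control,
                "scale_factor": q.scale_factor,
                "n_housekeeping": q.n_housekeeping,
            }
            for q in result.qc
        ],
    }
    cio.write_json(report, out_dir / "report.json")
    return report
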