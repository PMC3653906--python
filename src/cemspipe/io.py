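"""Readers and writers for the pipeline's on-disk formats.

All tabular files are TSV: UTF-8, LF line endings, dot decimal separator,
mandatory header row, numbers serialized with 10 significant digits so
that write-then-read round-trips.  Headers are validated strictly; a
missing column, a non-numeric cell or a duplicate id is reported with
the offending column name and (for cells) the 1-based data line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierModel
from .errors import SchemaError
from .matching import PeptideMatrix
from .peaks import PeptideFeature, RawSignal
from .register import HousekeepingPanel, ReferencePanel

_FLOAT_FMT = "%.12g"

PEAKLIST_COLUMNS = ["mz", "charge", "intensity", "migration_time_min", "snr", "n_spectra"]
FEATURE_COLUMNS = ["mass_da", "time_min", "intensity", "charges"]
CLINICAL_COLUMNS = [
    "patient_id", "age_years", "sex", "dialysis", "creatinine_umol_l",
    "urine_protein_g_per_g", "event", "followup_years",
]
PANEL_COLUMNS = ["peptide_id", "mass_da", "time_min"]


def _read_tsv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        raw = df[col].replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 1  # 1-based data line
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column '{col}' at data line {line}"
            )
        df[col] = vals
    return df


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------- peak lists

def write_peaklist(signals, path) -> None:
    df = pd.DataFrame(
        {
            "mz": [s.mz for s in signals],
            "charge": [s.z for s in signals],
            "intensity": [s.intensity for s in signals],
            "migration_time_min": [s.time for s in signals],
            "snr": [s.snr for s in signals],
            "n_spectra": [s.n_spectra for s in signals],
        }
    )
    _write_tsv(df, path)


def read_peaklist(path) -> list[RawSignal]:
    df = _read_tsv(path, PEAKLIST_COLUMNS, PEAKLIST_COLUMNS)
    return [
        RawSignal(
            mz=float(r.mz), z=int(r.charge), intensity=float(r.intensity),
            time=float(r.migration_time_min), snr=float(r.snr),
            n_spectra=int(r.n_spectra),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ features

def write_features(features, path) -> None:
    df = pd.DataFrame(
        {
            "mass_da": [f.mass for f in features],
            "time_min": [f.time for f in features],
            "intensity": [f.intensity for f in features],
            "charges": [",".join(str(z) for z in sorted(f.source_charges)) for f in features],
        }
    )
    _write_tsv(df, path)


def read_features(path) -> list[PeptideFeature]:
    df = _read_tsv(path, FEATURE_COLUMNS, ["mass_da", "time_min", "intensity"])
    out = []
    for r in df.itertuples():
        charges = frozenset(int(z) for z in str(r.charges).split(",") if z not in ("", "nan"))
        out.append(
            PeptideFeature(mass=float(r.mass_da), time=float(r.time_min),
                           intensity=float(r.intensity), source_charges=charges)
        )
    return out


# -------------------------------------------------------------------- panels

def write_panel(panel: ReferencePanel | HousekeepingPanel, path) -> None:
    _write_tsv(panel.to_frame(), path)


def read_reference_panel(path) -> ReferencePanel:
    df = _read_tsv(path, PANEL_COLUMNS, ["mass_da", "time_min"])
    if df["peptide_id"].duplicated().any():
        dup = df["peptide_id"][df["peptide_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate peptide_id {dup!r}")
    return ReferencePanel.from_frame(df)


def read_housekeeping_panel(path) -> HousekeepingPanel:
    df = _read_tsv(path, PANEL_COLUMNS + ["ref_intensity"],
                   ["mass_da", "time_min", "ref_intensity"])
    if df["peptide_id"].duplicated().any():
        dup = df["peptide_id"][df["peptide_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate peptide_id {dup!r}")
    return HousekeepingPanel.from_frame(df)


# -------------------------------------------------------------------- matrix

def write_matrix(matrix: PeptideMatrix, path) -> None:
    _write_tsv(matrix.to_frame(), path)


def read_matrix(path) -> PeptideMatrix:
    df = _read_tsv(path, ["peptide_id", "mass_da", "time_min"], ["mass_da", "time_min"])
    if df["peptide_id"].duplicated().any():
        dup = df["peptide_id"][df["peptide_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate peptide_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in ("peptide_id", "mass_da", "time_min")]
    for col in sample_cols:
        raw = df[col].replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric value in sample column '{col}' "
                f"at data line {int(bad.idxmax()) + 1}"
            )
        df[col] = vals
    return PeptideMatrix.from_frame(df)


# ------------------------------------------------------------------ clinical

def write_clinical(patients: pd.DataFrame, path) -> None:
    df = patients.reset_index()
    ev = df["event"]
    df["event"] = ev.map(lambda v: "" if pd.isna(v) else int(bool(v)))
    df["dialysis"] = df["dialysis"].astype(int)
    _write_tsv(df[CLINICAL_COLUMNS], path)


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(
        path, CLINICAL_COLUMNS,
        ["age_years", "creatinine_umol_l", "urine_protein_g_per_g", "followup_years"],
    )
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate patient_id {dup!r}")
    df["dialysis"] = df["dialysis"].map({"0": False, "1": True, "True": True, "False": False})
    if df["dialysis"].isna().any():
        raise SchemaError(f"{path}: dialysis column must be 0/1")
    df["event"] = df["event"].map(
        lambda v: pd.NA if v == "" else bool(int(v))
    ).astype("boolean")
    return df.set_index("patient_id")


# ---------------------------------------------------------------- model/json

def write_model(model: ClassifierModel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(model.to_json() + "\n", encoding="utf-8")


def read_model(path) -> ClassifierModel:
    return ClassifierModel.from_json(Path(path).read_text(encoding="utf-8"))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
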