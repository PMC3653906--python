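"""Migration-time calibration and intensity normalization.

CE migration times drift from run to run (buffer aging, EOF variation),
and urinary peptide intensities are confounded by urine dilution and
analytical variance.  Both are corrected against panels of reference
peptides:

* time calibration maps observed times onto the canonical times of a
  reference panel by locally weighted regression (LOWESS), and
* intensities are rescaled so that a panel of "housekeeping" peptides —
  peptides whose abundance is stable across subjects — matches its
  reference intensities (median-of-ratios scale factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import CalibrationError, NormalizationError, ValidationError
from .peaks import PeptideFeature


@dataclass(frozen=True)
class ReferencePanel:
    """Reference peptides with canonical migration times, used as calibration anchors."""

    ids: tuple[str, ...]
    mass_da: np.ndarray
    time_min: np.ndarray

    def __post_init__(self):
        if len(self.ids) != len(self.mass_da) or len(self.ids) != len(self.time_min):
            raise ValidationError("panel columns have inconsistent lengths")
        if len(self.ids) and np.any(self.time_min <= 0):
            raise ValidationError("canonical times must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferencePanel":
        return cls(
            ids=tuple(df["peptide_id"].astype(str)),
            mass_da=df["mass_da"].to_numpy(dtype=float),
            time_min=df["time_min"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peptide_id": self.ids, "mass_da": self.mass_da, "time_min": self.time_min}
        )


@dataclass(frozen=True)
class HousekeepingPanel:
    """Stable-abundance peptides with reference intensities for dilution correction."""

    ids: tuple[str, ...]
    mass_da: np.ndarray
    time_min: np.ndarray
    ref_intensity: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if any(len(a) != n for a in (self.mass_da, self.time_min, self.ref_intensity)):
            raise ValidationError("panel columns have inconsistent lengths")
        if n and np.any(self.ref_intensity <= 0):
            raise ValidationError("reference intensities must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HousekeepingPanel":
        return cls(
            ids=tuple(df["peptide_id"].astype(str)),
            mass_da=df["mass_da"].to_numpy(dtype=float),
            time_min=df["time_min"].to_numpy(dtype=float),
            ref_intensity=df["ref_intensity"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": self.ids,
                "mass_da": self.mass_da,
                "time_min": self.time_min,
                "ref_intensity": self.ref_intensity,
            }
        )

    def as_reference(self) -> ReferencePanel:
        return ReferencePanel(self.ids, self.mass_da, self.time_min)


@dataclass(frozen=True)
class CalibrationDiagnostics:
    """QC record for one sample's time calibration."""

    n_anchors: int
    residual_sd: float
    max_residual: float
    passed_control: bool  # max anchor deviation below the 0.35 min control


def match_to_panel(
    features: Sequence[PeptideFeature],
    panel: ReferencePanel,
    ppm: float = 50.0,
    dt: float = 0.35,
) -> list[tuple[int, int, float]]:
    """One-to-one greedy matching of features to panel entries.

    Candidate pairs must agree within ``ppm`` (relative to the smaller
    mass) and ``dt`` minutes.  Pairs are assigned greedily by ascending
    ppm deviation; ties are broken in favour of the earlier-migrating
    feature, then by index, so the result is deterministic.

    Returns
    -------
    list of (feature_index, panel_index, ppm_deviation)
    """
    if len(panel) == 0:
        raise ValidationError("reference panel is empty")
    if not features:
        return []

    f_mass = np.array([f.mass for f in features])
    f_time = np.array([f.time for f in features])
    order = np.argsort(panel.mass_da, kind="stable")
    p_mass = panel.mass_da[order]
    p_time = panel.time_min[order]

    candidates = []
    for i in range(len(features)):
        lo = np.searchsorted(p_mass, f_mass[i] * (1 - ppm * 1e-6) - 1e-9)
        hi = np.searchsorted(p_mass, f_mass[i] * (1 + ppm * 1e-6) + 1e-9, side="right")
        for k in range(lo, hi):
            smaller = min(f_mass[i], p_mass[k])
            dev = abs(f_mass[i] - p_mass[k]) / smaller * 1e6
            if dev < ppm and abs(f_time[i] - p_time[k]) <= dt:
                candidates.append((dev, f_time[i], i, int(order[k])))

    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    used_f: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for dev, _t, i, j in candidates:
        if i in used_f or j in used_p:
            continue
        used_f.add(i)
        used_p.add(j)
        pairs.append((i, j, dev))
    pairs.sort(key=lambda p: p[0])
    return pairs


def _monotone_map(x: np.ndarray, y: np.ndarray):
    """Return f(t): piecewise-linear interpolant of (x, y) with linear
    extrapolation from the terminal segments; y is forced non-decreasing."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # collapse duplicate abscissae (mean of fits) so interp is well defined
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    np.add.at(counts, inv, 1)
    uy = uy / counts
    uy = np.maximum.accumulate(uy)  # enforce monotone non-decreasing

    if len(ux) == 1:
        off = uy[0] - ux[0]
        return lambda t: np.asarray(t, dtype=float) + off

    slope_lo = (uy[1] - uy[0]) / (ux[1] - ux[0])
    slope_hi = (uy[-1] - uy[-2]) / (ux[-1] - ux[-2])

    def f(t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, ux, uy)
        below = t < ux[0]
        above = t > ux[-1]
        out = np.where(below, uy[0] + slope_lo * (t - ux[0]), out)
        out = np.where(above, uy[-1] + slope_hi * (t - ux[-1]), out)
        return out

    return f


def calibrate_times(
    features: Sequence[PeptideFeature],
    panel: ReferencePanel,
    span: float | None = None,
    min_anchors: int = 10,
    ppm: float = 50.0,
    anchor_dt: float = 2.0,
    control_dt: float = 0.35,
    sample_id: str | None = None,
) -> tuple[list[PeptideFeature], CalibrationDiagnostics]:
    """Calibrate migration times against a reference panel by LOWESS.

    Features are matched to the panel inside a coarse time window
    (``anchor_dt``, wider than the cross-sample tolerance because raw
    run-to-run drift exceeds it); the matched pairs serve as anchors for
    a locally weighted regression of canonical time on observed time
    (tricube weights, local linear fits, 2 robustifying iterations,
    window fraction ``span``).  When ``span`` is None the window adapts
    to anchor density — it covers about 30 anchors, bounded to fractions
    [0.1, 0.67] — so that dense panels track drift structure while
    sparse ones keep enough points per fit.  The fitted map is forced monotone
    non-decreasing and extended linearly beyond the anchor range, then
    applied to *all* feature times.

    Post-calibration anchor deviations are the QC quantity: the sample
    passes the control when the maximum deviation is below ``control_dt``
    (0.35 min by default).

    Raises
    ------
    CalibrationError
        If fewer than ``min_anchors`` panel matches are found.
    """
    if span is not None and not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    pairs = match_to_panel(features, panel, ppm=ppm, dt=anchor_dt)
    if len(pairs) < min_anchors:
        raise CalibrationError(
            sample_id,
            f"only {len(pairs)} reference anchors matched (need {min_anchors})",
        )

    observed = np.array([features[i].time for i, _j, _d in pairs])
    canonical = np.array([panel.time_min[j] for _i, j, _d in pairs])

    frac = span if span is not None else float(np.clip(30.0 / len(pairs), 0.1, 0.67))
    fitted = lowess(
        canonical, observed, frac=frac, it=2, return_sorted=False
    )
    warp = _monotone_map(observed, fitted)

    residuals = warp(observed) - canonical
    new_times = warp(np.array([f.time for f in features]))
    calibrated = [
        PeptideFeature(
            mass=f.mass,
            time=float(t),
            intensity=f.intensity,
            source_charges=f.source_charges,
        )
        for f, t in zip(features, new_times)
    ]
    max_res = float(np.max(np.abs(residuals))) if len(residuals) else 0.0
    diag = CalibrationDiagnostics(
        n_anchors=len(pairs),
        residual_sd=float(np.std(residuals)),
        max_residual=max_res,
        passed_control=max_res < control_dt,
    )
    return calibrated, diag


def normalize_intensities(
    features: Sequence[PeptideFeature],
    hk: HousekeepingPanel,
    ppm: float = 50.0,
    dt: float = 0.35,
    min_hk: int = 3,
    sample_id: str | None = None,
) -> tuple[list[PeptideFeature], float, int]:
    """Rescale intensities so housekeeping peptides match their references.

    The scale factor is the median over detected housekeeping peptides of
    reference_intensity / observed_intensity — robust to an aberrant
    housekeeping signal — and every feature intensity is multiplied by it.
    This removes urine-dilution and analytical intensity variance.

    Returns ``(scaled features, scale factor, n housekeeping detected)``.

    Raises
    ------
    NormalizationError
        If fewer than ``min_hk`` housekeeping peptides are detected.
    """
    pairs = match_to_panel(features, hk.as_reference(), ppm=ppm, dt=dt)
    pairs = [(i, j, d) for i, j, d in pairs if features[i].intensity > 0]
    if len(pairs) < min_hk:
        raise NormalizationError(
            sample_id,
            f"only {len(pairs)} housekeeping peptides detected (need {min_hk})",
        )
    ratios = np.array([hk.ref_intensity[j] / features[i].intensity for i, j, _d in pairs])
    s = float(np.median(ratios))
    scaled = [
        PeptideFeature(
            mass=f.mass,
            time=f.time,
            intensity=f.intensity * s,
            source_charges=f.source_charges,
        )
        for f in features
    ]
    return scaled, s, len(pairs)
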