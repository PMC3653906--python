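"""Multi-peptide linear classifier: representation, scoring, training, prognosis.

A CKD273-style classifier combines the amplitudes of a panel of urinary
peptides into one numeric score

    score = offset + sum_i  w_i * log10(1 + I_i)

where I_i is the (calibrated, normalized) intensity of panel peptide i in
the sample, matched by mass/time tolerance, and w_i its weight.  A
prognostic cutoff (0.55 by default) splits samples into a high-risk side
(score strictly above the cutoff) and a low-risk side.

The original published panel weights are not reproducible from the
literature alone; the model JSON format accepts any panel so that a real
classifier can be loaded, and :func:`train_model` fits a regularized
linear discriminant on synthetic (or any labelled) cohorts to exercise
the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ValidationError
from .matching import PeptideMatrix
from .peaks import PeptideFeature

MISSING_POLICIES = ("zero", "min_observed")


@dataclass(frozen=True)
class ClassifierModel:
    """Peptide panel + linear weights + offset + prognostic cutoff."""

    panel: pd.DataFrame  # columns: peptide_id, mass_da, time_min, weight
    offset: float
    cutoff: float = 0.55
    missing_policy: str = "zero"

    def __post_init__(self):
        required = {"peptide_id", "mass_da", "time_min", "weight"}
        if not required.issubset(self.panel.columns):
            raise ValidationError(
                f"model panel is missing columns {sorted(required - set(self.panel.columns))}"
            )
        if len(self.panel) == 0:
            raise ValidationError("model panel is empty")
        if self.panel["peptide_id"].duplicated().any():
            raise ValidationError("duplicate peptide ids in model panel")
        if not np.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValidationError(
                f"unknown missing_policy {self.missing_policy!r}; expected one of {MISSING_POLICIES}"
            )

    def to_json(self) -> str:
        obj = {
            "panel": self.panel[["peptide_id", "mass_da", "time_min", "weight"]].to_dict(
                orient="records"
            ),
            "offset": self.offset,
            "cutoff": self.cutoff,
            "missing_policy": self.missing_policy,
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        obj = json.loads(text)
        try:
            panel = pd.DataFrame(obj["panel"])
            return cls(
                panel=panel,
                offset=float(obj["offset"]),
                cutoff=float(obj["cutoff"]),
                missing_policy=obj.get("missing_policy", "zero"),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed model JSON: {exc}") from exc


@dataclass(frozen=True)
class ScoreResult:
    """Classifier output for one sample."""

    sample_id: str
    score: float
    n_panel_detected: int
    above_cutoff: bool = field(default=False)

    @classmethod
    def make(cls, sample_id: str, score: float, n_detected: int, cutoff: float):
        return cls(sample_id, score, n_detected, above_cutoff=score > cutoff)


def _transform(intensity: float) -> float:
    return float(np.log10(1.0 + intensity))


def score_sample(
    features: Sequence[PeptideFeature],
    model: ClassifierModel,
    ppm: float = 50.0,
    dt: float = 0.35,
    sample_id: str = "sample",
) -> ScoreResult:
    """Score one sample's feature list with a classifier model.

    Panel peptides are matched to features one-to-one, greedily by
    ascending ppm deviation within the mass/time tolerances; matched
    intensities enter as log10(1 + I), unmatched panel peptides take the
    missing-policy value (0 for "zero"; the minimum matched transform for
    "min_observed").
    """
    from .register import ReferencePanel, match_to_panel

    panel_ref = ReferencePanel(
        ids=tuple(model.panel["peptide_id"].astype(str)),
        mass_da=model.panel["mass_da"].to_numpy(dtype=float),
        time_min=model.panel["time_min"].to_numpy(dtype=float),
    )
    pairs = match_to_panel(features, panel_ref, ppm=ppm, dt=dt)
    weights = model.panel["weight"].to_numpy(dtype=float)

    x = np.full(len(model.panel), np.nan)
    for fi, pj, _dev in pairs:
        x[pj] = _transform(features[fi].intensity)
    n_detected = int(np.sum(~np.isnan(x)))
    x = _fill_missing(x, model.missing_policy)
    score = float(model.offset + np.dot(weights, x))
    return ScoreResult.make(sample_id, score, n_detected, model.cutoff)


def _fill_missing(x: np.ndarray, policy: str) -> np.ndarray:
    missing = np.isnan(x)
    if not missing.any():
        return x
    if policy == "zero":
        fill = 0.0
    elif policy == "min_observed":
        fill = float(np.nanmin(x)) if (~missing).any() else 0.0
    else:  # pragma: no cover - guarded in the model constructor
        raise ValidationError(f"unknown missing_policy {policy!r}")
    out = x.copy()
    out[missing] = fill
    return out


def score_matrix(
    matrix: PeptideMatrix,
    model: ClassifierModel,
    ppm: float = 50.0,
    dt: float = 0.35,
) -> pd.DataFrame:
    """Score every sample of a peptide matrix.

    Consensus peptides are matched to the model panel once (one-to-one,
    nearest ppm within tolerance); each sample's row is then scored like
    :func:`score_sample`.  Returns a DataFrame indexed by sample id with
    columns score, n_panel_detected, above_cutoff.
    """
    from .register import ReferencePanel, match_to_panel

    panel_ref = ReferencePanel(
        ids=tuple(model.panel["peptide_id"].astype(str)),
        mass_da=model.panel["mass_da"].to_numpy(dtype=float),
        time_min=model.panel["time_min"].to_numpy(dtype=float),
    )
    pseudo = [
        PeptideFeature(mass=m, time=t, intensity=1.0)
        for m, t in zip(matrix.peptides["mass_da"], matrix.peptides["time_min"])
    ]
    pairs = match_to_panel(pseudo, panel_ref, ppm=ppm, dt=dt)
    weights = model.panel["weight"].to_numpy(dtype=float)
    vals = matrix.intensities.to_numpy(dtype=float)

    records = []
    for si, sid in enumerate(matrix.sample_ids):
        x = np.full(len(model.panel), np.nan)
        for ri, pj, _dev in pairs:
            v = vals[ri, si]
            if not np.isnan(v):
                x[pj] = _transform(v)
        n_detected = int(np.sum(~np.isnan(x)))
        x = _fill_missing(x, model.missing_policy)
        score = float(model.offset + np.dot(weights, x))
        records.append(
            {
                "sample_id": sid,
                "score": score,
                "n_panel_detected": n_detected,
                "above_cutoff": score > model.cutoff,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def train_model(
    matrix: PeptideMatrix,
    labels: pd.Series | dict,
    regularization: float = 0.5,
    cutoff: float = 0.0,
    missing_policy: str = "zero",
) -> ClassifierModel:
    """Fit a regularized linear discriminant of two classes on log-intensities.

    ``labels`` maps sample id -> {0, 1}.  Missing cells take the missing-
    policy value before fitting.  The returned model's score is the signed
    discriminant value (positive side = class 1); the default cutoff 0 is
    the decision boundary.  Deterministic: the solver is closed-form.
    """
    labels = pd.Series(labels)
    common = [s for s in matrix.sample_ids if s in labels.index]
    if len(common) < 2:
        raise ValidationError("need at least 2 labelled samples")
    y = labels.loc[common].astype(int).to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {len(classes)}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValidationError("need at least 2 samples per class")
    if not 0 <= regularization <= 1:
        raise ValidationError("regularization (shrinkage) must be in [0, 1]")

    X = np.log10(1.0 + matrix.intensities[common].to_numpy(dtype=float).T)
    if missing_policy == "zero":
        X = np.nan_to_num(X, nan=0.0)
    elif missing_policy == "min_observed":
        col_min = np.nanmin(X, axis=0)
        col_min = np.where(np.isnan(col_min), 0.0, col_min)
        inds = np.where(np.isnan(X))
        X[inds] = col_min[inds[1]]
    else:
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")

    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=regularization)
    lda.fit(X, y)

    panel = pd.DataFrame(
        {
            "peptide_id": matrix.intensities.index,
            "mass_da": matrix.peptides["mass_da"].to_numpy(),
            "time_min": matrix.peptides["time_min"].to_numpy(),
            "weight": lda.coef_[0],
        }
    ).reset_index(drop=True)
    return ClassifierModel(
        panel=panel,
        offset=float(lda.intercept_[0]),
        cutoff=cutoff,
        missing_policy=missing_policy,
    )


@dataclass(frozen=True)
class PrognosticTable:
    """2x2 outcome counts around the prognostic cutoff, with derived rates."""

    cutoff: float
    events_above: int
    events_below: int
    nonevents_above: int
    nonevents_below: int
    n_unknown_outcome: int

    @property
    def n_known(self) -> int:
        return (
            self.events_above + self.events_below
            + self.nonevents_above + self.nonevents_below
        )

    @property
    def sensitivity(self) -> float:
        """P(score > cutoff | event); NaN when no events."""
        d = self.events_above + self.events_below
        return self.events_above / d if d else float("nan")

    @property
    def specificity(self) -> float:
        """P(score <= cutoff | no event); NaN when no non-events."""
        d = self.nonevents_above + self.nonevents_below
        return self.nonevents_below / d if d else float("nan")

    @property
    def npv(self) -> float:
        """P(no event | score <= cutoff); NaN when nobody is below the cutoff."""
        d = self.events_below + self.nonevents_below
        return self.nonevents_below / d if d else float("nan")


def prognostic_table(
    scores: pd.DataFrame | Sequence[ScoreResult],
    events: pd.Series | dict,
    cutoff: float = 0.55,
) -> PrognosticTable:
    """Cross-tabulate outcomes against the prognostic cutoff.

    ``scores`` is either the frame from :func:`score_matrix` or a list of
    :class:`ScoreResult`; ``events`` maps sample id to True/False/NA.
    Samples without a known outcome are excluded and counted.  High risk
    is score strictly above the cutoff.
    """
    if isinstance(scores, pd.DataFrame):
        score_map = scores["score"]
    else:
        score_map = pd.Series({r.sample_id: r.score for r in scores})
    events = pd.Series(events)
    common = score_map.index.intersection(events.index)
    if len(common) == 0:
        raise ValidationError("no overlapping sample ids between scores and outcomes")

    ev = events.loc[common]
    sc = score_map.loc[common]
    known = ev.notna()
    ev_b = ev[known].astype(bool)
    above = sc[known] > cutoff
    return PrognosticTable(
        cutoff=cutoff,
        events_above=int((ev_b & above).sum()),
        events_below=int((ev_b & ~above).sum()),
        nonevents_above=int((~ev_b & above).sum()),
        nonevents_below=int((~ev_b & ~above).sum()),
        n_unknown_outcome=int((~known).sum()),
    )
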