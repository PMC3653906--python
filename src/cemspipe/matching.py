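"""Cross-sample peptide matching and the peptide × sample intensity matrix.

After calibration and normalization, each sample is a list of
(mass, time, intensity) features.  Peptides in different samples are
considered identical when their masses agree within 50 ppm and their
calibrated migration times within 0.35 minutes; matched peptides are
accumulated into *consensus peptides* whose mass and time are running
means, mirroring how a peptide database is built up sample by sample.
The result is a consensus-peptide × sample matrix with missing cells
wherever a peptide was not detected in a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peaks import PeptideFeature


@dataclass
class ConsensusPeptide:
    """A cross-sample peptide identity with running-mean coordinates."""

    id: str
    mass: float  # intensity-weighted running mean
    time: float  # running mean
    support: int  # number of samples in which it was detected
    _mass_weight: float = 0.0  # accumulated intensity for the weighted mean

    def update(self, mass: float, time: float, intensity: float) -> None:
        w = max(intensity, 1e-12)
        self.mass = (self.mass * self._mass_weight + mass * w) / (self._mass_weight + w)
        self._mass_weight += w
        self.time = (self.time * self.support + time) / (self.support + 1)
        self.support += 1


class PeptideMatrix:
    """Consensus peptides × samples intensity matrix with missingness.

    ``intensities`` is a pandas DataFrame (rows: peptide ids, columns:
    sample ids, NaN = not detected); ``peptides`` carries per-row
    metadata (mass_da, time_min, support).
    """

    def __init__(self, intensities: pd.DataFrame, peptides: pd.DataFrame):
        if not intensities.index.equals(peptides.index):
            raise ValidationError("matrix and metadata indices disagree")
        vals = intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("intensities must be non-negative where present")
        self.intensities = intensities
        self.peptides = peptides

    @property
    def n_peptides(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def support(self) -> pd.Series:
        return self.intensities.notna().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Flat representation used by the matrix TSV on disk."""
        out = self.peptides[["mass_da", "time_min"]].copy()
        out.insert(0, "peptide_id", self.intensities.index)
        return pd.concat([out.reset_index(drop=True),
                          self.intensities.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeptideMatrix":
        meta_cols = ["peptide_id", "mass_da", "time_min"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        idx = pd.Index(df["peptide_id"].astype(str), name="peptide_id")
        intens = df[sample_cols].astype(float)
        intens.index = idx
        meta = df[["mass_da", "time_min"]].astype(float)
        meta.index = idx
        meta["support"] = intens.notna().sum(axis=1)
        return cls(intens, meta)

    def subset(self, peptide_ids: Sequence[str]) -> "PeptideMatrix":
        ids = list(peptide_ids)
        return PeptideMatrix(self.intensities.loc[ids], self.peptides.loc[ids])


def build_matrix(
    samples: Mapping[str, Sequence[PeptideFeature]],
    ppm: float = 50.0,
    dt: float = 0.35,
) -> PeptideMatrix:
    """Greedy sequential matching of per-sample features into consensus peptides.

    Samples are processed in input order.  Each feature joins the nearest
    (in ppm, measured against the current consensus mass) existing
    consensus peptide within both tolerances, otherwise it founds a new
    one.  At most one feature per sample may join a given consensus
    peptide: when two features of the same sample compete, the nearer in
    ppm wins and the loser founds a new peptide.  Consensus mass is an
    intensity-weighted running mean; consensus time a plain running mean.
    """
    sample_ids = list(samples.keys())
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError("duplicate sample ids")
    if ppm < 0 or dt < 0:
        raise ValidationError("tolerances must be non-negative")

    consensus: list[ConsensusPeptide] = []
    cells: dict[str, dict[str, float]] = {}  # consensus id -> {sample id: intensity}

    def new_consensus(f: PeptideFeature, sid: str) -> None:
        cid = f"C{len(consensus) + 1:05d}"
        cp = ConsensusPeptide(id=cid, mass=f.mass, time=f.time, support=1,
                              _mass_weight=max(f.intensity, 1e-12))
        consensus.append(cp)
        cells[cid] = {sid: f.intensity}

    for sid in sample_ids:
        feats = list(samples[sid])
        # best existing consensus candidate for each feature of this sample
        cand: list[tuple[float, int, int]] = []  # (ppm_dev, feature idx, consensus idx)
        masses = np.array([c.mass for c in consensus])
        times = np.array([c.time for c in consensus])
        for fi, f in enumerate(feats):
            if len(consensus) == 0:
                continue
            dev = np.abs(masses - f.mass) / masses * 1e6
            ok = (dev < ppm) & (np.abs(times - f.time) <= dt)
            if ok.any():
                idx = np.where(ok)[0]
                best = idx[np.argmin(dev[idx])]
                cand.append((float(dev[best]), fi, int(best)))

        # resolve within-sample competition: nearest ppm wins
        cand.sort(key=lambda c: (c[0], c[1]))
        taken_cons: set[int] = set()
        assigned: dict[int, int] = {}
        for dev, fi, ci in cand:
            if ci in taken_cons or fi in assigned:
                continue
            taken_cons.add(ci)
            assigned[fi] = ci

        for fi, f in enumerate(feats):
            if fi in assigned:
                cp = consensus[assigned[fi]]
                cp.update(f.mass, f.time, f.intensity)
                cells[cp.id][sid] = f.intensity
            else:
                new_consensus(f, sid)

    ids = [c.id for c in consensus]
    intens = pd.DataFrame(
        np.nan, index=pd.Index(ids, name="peptide_id"), columns=sample_ids, dtype=float
    )
    for cid, row in cells.items():
        for sid, v in row.items():
            intens.at[cid, sid] = v
    meta = pd.DataFrame(
        {
            "mass_da": [c.mass for c in consensus],
            "time_min": [c.time for c in consensus],
            "support": [c.support for c in consensus],
        },
        index=pd.Index(ids, name="peptide_id"),
    )
    return PeptideMatrix(intens, meta)


def presence_filter(matrix: PeptideMatrix, min_frac: float = 0.5) -> PeptideMatrix:
    """Keep peptides detected in strictly more than ``min_frac`` of samples.

    The strict inequality mirrors the ">50% of the samples" selection:
    a peptide present in exactly half the samples is dropped.
    """
    if not 0 <= min_frac < 1:
        raise ValidationError(f"min_frac must be in [0, 1), got {min_frac}")
    if matrix.n_samples == 0:
        raise ValidationError("matrix has no samples")
    frac = matrix.support() / matrix.n_samples
    keep = matrix.intensities.index[frac > min_frac]
    return matrix.subset(keep)
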