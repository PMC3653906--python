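"""Raw CE-MS signal filtering and charge-state deconvolution.

A CE-MS peak list reports one row per detected ion: mass-to-charge ratio,
charge state, signal intensity, migration time, signal-to-noise ratio and
the number of consecutive spectra in which the ion was seen.  One peptide
typically appears at several charge states; deconvolution collapses those
signals into a single neutral monoisotopic mass, yielding one
(mass, time, intensity) feature per peptide per run.

Quality filters follow standard CE-MS practice: singly charged ions are
discarded (dominated by matrix/chemical noise), and signals must reach a
minimum signal-to-noise ratio and be seen in a minimum number of
consecutive spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Mass of a proton in Da; fixed so the m/z <-> neutral mass round trip is exact.
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class RawSignal:
    """One centroided CE-MS ion signal.

    Attributes
    ----------
    mz : float
        Mass-to-charge ratio in Thomson. Must be positive.
    z : int
        Charge state, >= 1.
    intensity : float
        Signal amplitude, arbitrary units, >= 0.
    time : float
        CE migration time in minutes.
    snr : float
        Signal-to-noise ratio, >= 0.
    n_spectra : int
        Number of consecutive spectra the signal was observed in, >= 1.
    """

    mz: float
    z: int
    intensity: float
    time: float
    snr: float
    n_spectra: int

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.z < 1:
            raise ValueError(f"charge must be >= 1, got {self.z}")
        if self.n_spectra < 1:
            raise ValueError(f"n_spectra must be >= 1, got {self.n_spectra}")
        if self.intensity < 0 or self.snr < 0:
            raise ValueError("intensity and snr must be non-negative")


@dataclass(frozen=True)
class PeptideFeature:
    """A deconvoluted peptide: neutral monoisotopic mass, time, summed intensity."""

    mass: float
    time: float
    intensity: float
    source_charges: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


def filter_signals(
    signals: Iterable[RawSignal],
    min_charge_excl: int = 1,
    min_snr: float = 4.0,
    min_spectra: int = 3,
) -> list[RawSignal]:
    """Apply the standard CE-MS quality filters to a peak list.

    Keeps exactly the signals with ``z > min_charge_excl`` and
    ``snr >= min_snr`` and ``n_spectra >= min_spectra`` (both boundaries
    inclusive), preserving input order.
    """
    if min_charge_excl < 0 or min_snr < 0 or min_spectra < 0:
        raise ValueError("filter thresholds must be non-negative")
    return [
        s
        for s in signals
        if s.z > min_charge_excl and s.snr >= min_snr and s.n_spectra >= min_spectra
    ]


def neutral_mass(mz: float, z: int) -> float:
    """Neutral monoisotopic mass M = z * (mz - m_proton) for a [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if mz <= PROTON_MASS:
        raise ValueError(f"mz must exceed the proton mass, got {mz}")
    return z * (mz - PROTON_MASS)


def mz_for(mass: float, z: int) -> float:
    """Inverse of :func:`neutral_mass`: m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def deconvolute(
    signals: Sequence[RawSignal],
    mass_tol_ppm: float = 25.0,
    time_tol_min: float = 0.1,
) -> list[PeptideFeature]:
    """Merge charge-state series into neutral-mass peptide features.

    Two signals are considered to originate from the same peptide when
    their neutral masses agree within ``mass_tol_ppm`` (ppm computed
    relative to the smaller of the two masses) and their migration times
    agree within ``time_tol_min``.  Grouping is the transitive closure of
    this pairwise relation, computed with a union-find over a sliding
    window on mass-sorted signals, so the result is deterministic and
    independent of input order.

    Each feature takes the intensity-weighted mean mass and time of its
    member signals and the sum of their intensities; every input signal
    belongs to exactly one feature, so total intensity is conserved.
    """
    if mass_tol_ppm < 0 or time_tol_min < 0:
        raise ValueError("tolerances must be non-negative")
    signals = list(signals)
    n = len(signals)
    if n == 0:
        return []

    masses = np.array([neutral_mass(s.mz, s.z) for s in signals])
    times = np.array([s.time for s in signals])
    order = np.argsort(masses, kind="stable")

    uf = _UnionFind(n)
    rel_tol = mass_tol_ppm * 1e-6
    for a in range(n):
        ia = order[a]
        ma = masses[ia]
        for b in range(a + 1, n):
            ib = order[b]
            if (masses[ib] - ma) > rel_tol * ma:  # ppm relative to smaller mass
                break
            if abs(times[ib] - times[ia]) <= time_tol_min:
                uf.union(ia, ib)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    features = []
    for members in groups.values():
        w = np.array([signals[i].intensity for i in members])
        total = w.sum()
        if total > 0:
            mass = float(np.average(masses[members], weights=w))
            time = float(np.average(times[members], weights=w))
        else:  # all-zero intensities: fall back to plain means
            mass = float(masses[members].mean())
            time = float(times[members].mean())
        features.append(
            PeptideFeature(
                mass=mass,
                time=time,
                intensity=float(total),
                source_charges=frozenset(signals[i].z for i in members),
            )
        )
    features.sort(key=lambda f: (f.mass, f.time))
    return features
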