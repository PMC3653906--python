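"""Synthetic CKD cohorts and per-sample CE-MS peak lists.

The generator emulates the statistical structure a urinary-peptidomics
analysis assumes, at the scale of a single-centre CKD cohort:

* a cohort spanning CKD stages I–V (latent disease severity drives a
  log-linearly decreasing eGFR, inverted through the MDRD formula into
  serum creatinine), with a dialysed subgroup, rising proteinuria, and a
  combined death/dialysis endpoint concentrated at high severity;
* a reference peptide panel in which serum-protein-like markers rise and
  collagen/uromodulin-like markers fall with severity, housekeeping
  peptides with stable abundance, and uninformative background peptides;
* per-sample peak lists with multiple charge states per peptide,
  lognormal abundance noise, lognormal urine dilution, a monotone
  piecewise-linear migration-time warp per run, left-censoring at a
  detection limit, spurious noise peptides, and sub-threshold junk
  signals that the quality filters must remove.

Ground truth (severity, dilution, warp, per-peptide abundances) is kept
so that downstream modules can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np
import pandas as pd

from .classify import ClassifierModel
from .cohort import invert_mdrd_creatinine, mdrd_egfr
from .errors import ConfigError, ValidationError
from .peaks import RawSignal, mz_for
from .register import HousekeepingPanel, ReferencePanel


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of the simulated study.

    The defaults describe a ~53-patient single-centre CKD cohort profiled
    on a CE-MS platform: 72 disease markers (30 serum-protein-like going
    up with severity, 42 collagen/uromodulin-like going down), 29
    housekeeping peptides, a 200-peptide calibration reference panel
    (a scaled stand-in for a production panel of 1770), ~0.5 min
    run-to-run migration drift, lognormal urine dilution (log-SD 0.5),
    a fixed detection limit, and a combined endpoint over a 3.6-year
    follow-up window with ~7.5% loss to follow-up.
    """

    n_patients: int = 53
    seed: int = 0
    n_marker_up: int = 30
    n_marker_down: int = 42
    n_housekeeping: int = 29
    n_reference: int = 200
    n_noise_peptides: int = 100
    dilution_sd: float = 0.5          # SD of ln(dilution factor)
    drift_amplitude: float = 0.5      # max |knot offset| of the time warp, minutes
    detection_limit: float = 1500.0   # intensity units, left-censoring threshold
    effect_size: float = 1.2          # marker log10-abundance change per unit severity
    # secondary knobs (held at study conditions)
    n_dialysis: int = 6
    marker_noise_sd: float = 0.15     # log10 units, markers and background peptides
    hk_noise_sd: float = 0.08         # log10 units, housekeeping peptides (stable)
    time_jitter_sd: float = 0.02      # minutes, residual per-signal time noise
    event_severity_floor: float = 0.6  # no endpoint events below this severity
    lost_frac: float = 4.0 / 53.0     # fraction lost to follow-up
    followup_years: float = 3.6
    n_junk_signals: int = 30          # per sample, removed by the quality filters

    def __post_init__(self):
        counts = (
            self.n_patients, self.n_marker_up, self.n_marker_down,
            self.n_housekeeping, self.n_reference, self.n_noise_peptides,
            self.n_dialysis, self.n_junk_signals,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {type(self.seed).__name__}")
        if self.n_housekeeping < 3:
            raise ConfigError("need at least 3 housekeeping peptides")
        if self.detection_limit < 0:
            raise ConfigError("detection limit must be non-negative")
        if self.dilution_sd < 0 or self.drift_amplitude < 0:
            raise ConfigError("dilution_sd and drift_amplitude must be non-negative")
        if self.n_reference < self.n_marker_up + self.n_marker_down + self.n_housekeeping:
            raise ConfigError(
                "reference panel must accommodate markers and housekeeping peptides"
            )

    def replace(self, **kw) -> "SyntheticConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kw)
        return SyntheticConfig(**current)


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    severity: pd.Series | None = None          # latent disease severity in [0, 1]
    egfr_true: pd.Series | None = None         # NaN for dialysis patients
    dilution: pd.Series | None = None          # per-sample dilution factor
    warps: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    warp_knots: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    abundance: pd.DataFrame | None = None      # peptides x patients, true mean intensity


@dataclass
class SimulatedStudy:
    """Everything the generator emits for one synthetic study."""

    patients: pd.DataFrame
    truth: SyntheticTruth
    samples: dict[str, list[RawSignal]]
    reference_panel: ReferencePanel
    housekeeping_panel: HousekeepingPanel
    marker_directions: pd.DataFrame  # peptide_id, direction (+1 up with severity, -1 down)
    panel_meta: pd.DataFrame         # peptide_id, mass_da, time_min, base_log10, role


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stream])


def simulate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a synthetic CKD cohort: demographics, chemistry, outcome.

    Latent severity s ~ U(0,1) drives everything: target eGFR falls
    log-linearly (120·exp(-3s), spanning stages I–V), urine protein rises
    lognormally, and the combined endpoint is Bernoulli with a logistic
    link on severity above a floor below which no events occur.  Serum
    creatinine is obtained by exact inversion of the MDRD formula from
    the target eGFR, so generated eGFR and MDRD(creatinine, age, sex)
    round-trip.  The most severe patients are dialysed; their eGFR is
    marked not-applicable.  A fixed fraction of patients is lost to
    follow-up (unknown outcome).  Reproducible for a fixed seed.
    """
    n = config.n_patients
    truth = SyntheticTruth()
    cols = [
        "age_years", "sex", "dialysis", "creatinine_umol_l",
        "urine_protein_g_per_g", "event", "followup_years",
    ]
    if n == 0:
        empty = pd.DataFrame(columns=cols, index=pd.Index([], name="patient_id"))
        truth.severity = pd.Series(dtype=float)
        truth.egfr_true = pd.Series(dtype=float)
        return empty, truth

    rng = _rng_for(config, 0)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    severity = rng.uniform(0.0, 1.0, size=n)
    age = np.clip(rng.normal(70.0, 11.5, size=n), 30.0, 92.0)
    sex = np.where(rng.uniform(size=n) < 33.0 / 53.0, "M", "F")

    egfr = 120.0 * np.exp(-3.0 * severity + rng.normal(0.0, 0.06, size=n))
    egfr = np.maximum(egfr, 4.0)

    # dialysis: the most severe patients; creatinine there is drawn directly
    # (dialysis decouples creatinine from GFR), eGFR not applicable
    n_dial = min(config.n_dialysis, n)
    dial_idx = np.argsort(-severity)[:n_dial]
    dialysis = np.zeros(n, dtype=bool)
    dialysis[dial_idx] = True

    creat = invert_mdrd_creatinine(egfr, age, sex)
    creat[dialysis] = rng.uniform(450.0, 900.0, size=n_dial)
    egfr_rec = np.asarray(mdrd_egfr(creat, age, sex), dtype=float)
    egfr_rec[dialysis] = np.nan

    uprot = np.exp(rng.normal(-1.5 + 3.0 * severity, 0.6))

    p_event = np.where(
        severity >= config.event_severity_floor,
        1.0 / (1.0 + np.exp(-6.0 * (severity - 0.65))),
        0.0,
    )
    event = rng.uniform(size=n) < p_event
    event_col = pd.array(event, dtype="boolean")
    n_lost = int(round(config.lost_frac * n))
    if n_lost:
        lost = rng.choice(n, size=n_lost, replace=False)
        event_col[lost] = pd.NA

    patients = pd.DataFrame(
        {
            "age_years": np.round(age, 1),
            "sex": sex,
            "dialysis": dialysis,
            "creatinine_umol_l": creat,
            "urine_protein_g_per_g": uprot,
            "event": event_col,
            "followup_years": config.followup_years,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    truth.severity = pd.Series(severity, index=ids)
    truth.egfr_true = pd.Series(egfr_rec, index=ids)
    return patients, truth


def _separated_panel(rng: np.random.Generator, n: int,
                     min_ppm: float = 150.0, min_dt: float = 1.0):
    """Random (mass, time) panel whose entries are pairwise resolvable:
    any two entries differ by > min_ppm in mass or > min_dt in time."""
    masses: list[float] = []
    times: list[float] = []
    attempts = 0
    while len(masses) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValidationError("could not place a separated peptide panel")
        m = float(np.exp(rng.uniform(np.log(800.0), np.log(12000.0))))
        t = float(rng.uniform(18.0, 45.0))
        ok = True
        for m2, t2 in zip(masses, times):
            if abs(m - m2) / min(m, m2) * 1e6 <= min_ppm and abs(t - t2) <= min_dt:
                ok = False
                break
        if ok:
            masses.append(m)
            times.append(t)
    return np.array(masses), np.array(times)


def _charge_states(mass: float) -> list[tuple[int, float]]:
    """Deterministic charge-state emission profile for a peptide mass.

    Charges are restricted to 2..6 and to an m/z window of roughly
    350-2500 Th; intensity is split over up to three states.
    """
    z_min = max(2, int(np.ceil(mass / 2500.0)))
    z_max = min(6, max(z_min, int(np.floor(mass / 350.0))))
    zs = list(range(z_min, min(z_max, z_min + 2) + 1))
    fracs = [0.5, 0.3, 0.2][: len(zs)]
    total = sum(fracs)
    return [(z, f / total) for z, f in zip(zs, fracs)]


def make_warp(rng: np.random.Generator, amplitude: float,
              t_lo: float = 18.0, t_hi: float = 45.0, n_knots: int = 5):
    """Monotone piecewise-linear time warp with <= 5 knots.

    Knot offsets are drawn uniformly in ±amplitude; knot spacing is wide
    relative to the amplitude, so the warp is strictly increasing.
    """
    knots = np.linspace(t_lo, t_hi, n_knots)
    offsets = rng.uniform(-amplitude, amplitude, size=n_knots)
    warped = knots + offsets
    if np.any(np.diff(warped) <= 0):  # only reachable at extreme amplitudes
        warped = np.maximum.accumulate(warped + np.arange(n_knots) * 1e-6)

    def warp(t):
        return np.interp(np.asarray(t, dtype=float), knots, warped)

    return warp, (knots, warped)


def simulate_peaklists(
    patients: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> SimulatedStudy:
    """Emit per-sample CE-MS peak lists plus panels and ground truth.

    For every panel peptide and patient, the true mean abundance is
    lognormal: log10 A = base + direction·effect_size·(severity − 0.5) +
    noise, with direction +1 for serum-protein-like markers, −1 for
    collagen/uromodulin-like markers and 0 for housekeeping/background
    peptides.  Observed intensity is abundance × the sample's dilution
    factor; peptides below the detection limit are dropped.  Each
    detectable peptide is emitted at 1-3 charge states at
    m/z = (M + z·1.007276)/z, with migration time passed through the
    sample's monotone warp plus jitter.  Spurious noise peptides (which
    pass the quality filters) and junk signals (which must be removed by
    them) complete the peak list.
    """
    if truth.severity is None:
        raise ValidationError("truth must come from simulate_cohort")
    if config.detection_limit < 0:
        raise ValidationError("detection limit must be non-negative")

    rng = _rng_for(config, 1)
    n_up, n_down, n_hk = config.n_marker_up, config.n_marker_down, config.n_housekeeping
    n_ref = config.n_reference

    masses, times = _separated_panel(rng, n_ref)
    roles = np.array(
        ["marker_up"] * n_up + ["marker_down"] * n_down + ["housekeeping"] * n_hk
        + ["background"] * (n_ref - n_up - n_down - n_hk)
    )
    order = rng.permutation(n_ref)  # de-correlate role from panel position
    roles = roles[order]
    pep_ids = np.array([f"REF{i + 1:04d}" for i in range(n_ref)])
    base_log10 = rng.uniform(3.5, 5.5, size=n_ref)
    direction = np.where(roles == "marker_up", 1, np.where(roles == "marker_down", -1, 0))

    panel_meta = pd.DataFrame(
        {
            "peptide_id": pep_ids,
            "mass_da": masses,
            "time_min": times,
            "base_log10": base_log10,
            "role": roles,
        }
    ).set_index("peptide_id")

    reference_panel = ReferencePanel(tuple(pep_ids), masses.copy(), times.copy())
    hk_mask = roles == "housekeeping"
    housekeeping_panel = HousekeepingPanel(
        ids=tuple(pep_ids[hk_mask]),
        mass_da=masses[hk_mask].copy(),
        time_min=times[hk_mask].copy(),
        ref_intensity=10.0 ** base_log10[hk_mask],
    )
    marker_mask = direction != 0
    marker_directions = pd.DataFrame(
        {"peptide_id": pep_ids[marker_mask], "direction": direction[marker_mask]}
    ).set_index("peptide_id")

    ids = list(patients.index)
    severity = truth.severity.loc[ids].to_numpy() if len(ids) else np.array([])
    noise_sd = np.where(hk_mask, config.hk_noise_sd, config.marker_noise_sd)

    dilution = np.exp(rng.normal(0.0, config.dilution_sd, size=len(ids)))
    truth.dilution = pd.Series(dilution, index=ids)

    abundance = np.empty((n_ref, len(ids)))
    samples: dict[str, list[RawSignal]] = {}
    for si, sid in enumerate(ids):
        s = severity[si]
        log_a = (
            base_log10
            + direction * config.effect_size * (s - 0.5)
            + rng.normal(0.0, 1.0, size=n_ref) * noise_sd
        )
        abundance[:, si] = 10.0 ** log_a

        warp, knots = make_warp(rng, config.drift_amplitude)
        truth.warps[sid] = warp
        truth.warp_knots[sid] = knots

        signals: list[RawSignal] = []
        observed = abundance[:, si] * dilution[si]
        for pi in range(n_ref):
            inten = observed[pi]
            if inten < config.detection_limit:
                continue  # left-censored: below the detection limit
            t_obs = float(warp(times[pi]) + rng.normal(0.0, config.time_jitter_sd))
            snr = 10.0 if config.detection_limit == 0 else 4.0 * inten / config.detection_limit
            n_spec = 3 + int(min(20, np.log10(1.0 + inten)))
            for z, frac in _charge_states(masses[pi]):
                signals.append(
                    RawSignal(
                        mz=mz_for(masses[pi], z),
                        z=z,
                        intensity=inten * frac,
                        time=t_obs,
                        snr=min(snr, 1e4),
                        n_spectra=n_spec,
                    )
                )

        # spurious peptides that survive the quality filters
        for _ in range(config.n_noise_peptides):
            m = float(np.exp(rng.uniform(np.log(800.0), np.log(12000.0))))
            t = float(rng.uniform(18.0, 45.0))
            inten = 10.0 ** rng.uniform(
                np.log10(max(config.detection_limit, 10.0)),
                np.log10(max(config.detection_limit, 10.0)) + 1.2,
            )
            z = int(rng.integers(2, 5))
            signals.append(
                RawSignal(
                    mz=mz_for(m, z), z=z, intensity=inten, time=t,
                    snr=float(rng.uniform(4.0, 20.0)), n_spectra=3,
                )
            )

        # junk the filters must remove: z=1, low S/N, too few spectra
        for _ in range(config.n_junk_signals):
            m = float(np.exp(rng.uniform(np.log(400.0), np.log(5000.0))))
            mode = rng.integers(0, 3)
            z = 1 if mode == 0 else int(rng.integers(2, 5))
            snr = float(rng.uniform(0.5, 3.9)) if mode == 1 else float(rng.uniform(4.0, 10.0))
            n_spec = int(rng.integers(1, 3)) if mode == 2 else 3
            signals.append(
                RawSignal(
                    mz=mz_for(m, z), z=z,
                    intensity=float(10.0 ** rng.uniform(2.0, 3.5)),
                    time=float(rng.uniform(18.0, 45.0)),
                    snr=snr, n_spectra=n_spec,
                )
            )
        samples[sid] = signals

    truth.abundance = pd.DataFrame(abundance, index=pd.Index(pep_ids, name="peptide_id"),
                                   columns=ids)
    return SimulatedStudy(
        patients=patients,
        truth=truth,
        samples=samples,
        reference_panel=reference_panel,
        housekeeping_panel=housekeeping_panel,
        marker_directions=marker_directions,
        panel_meta=panel_meta,
    )


def simulate_study(config: SyntheticConfig) -> SimulatedStudy:
    """Convenience wrapper: cohort + peak lists in one call."""
    patients, truth = simulate_cohort(config)
    return simulate_peaklists(patients, truth, config)


def make_planted_model(
    study: SimulatedStudy,
    config: SyntheticConfig,
    cutoff: float = 0.55,
    score_range: float = 2.0,
) -> ClassifierModel:
    """Build the classifier whose signal the generator planted.

    Weights are ±w on the marker peptides (sign = planted direction), with
    w chosen so the expected score spans ``score_range`` units over the
    severity range; the offset places the expected score at mid-severity
    exactly at the prognostic ``cutoff``.  This mirrors applying a
    previously trained multi-peptide classifier to a new cohort.
    """
    meta = study.panel_meta
    markers = meta[meta["role"].isin(["marker_up", "marker_down"])]
    n_markers = len(markers)
    if n_markers == 0:
        raise ValidationError("the study has no marker peptides")
    w = score_range / (n_markers * config.effect_size)
    weights = np.where(markers["role"] == "marker_up", w, -w)
    expected_mid = np.log10(1.0 + 10.0 ** markers["base_log10"].to_numpy())
    offset = cutoff - float(np.dot(weights, expected_mid))
    panel = pd.DataFrame(
        {
            "peptide_id": markers.index,
            "mass_da": markers["mass_da"].to_numpy(),
            "time_min": markers["time_min"].to_numpy(),
            "weight": weights,
        }
    ).reset_index(drop=True)
    return ClassifierModel(panel=panel, offset=offset, cutoff=cutoff, missing_policy="zero")
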