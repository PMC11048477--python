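"""Ground-truthed synthetic CW-NIRS recordings for breath-hold scenarios.

The generator emulates a wearable forehead probe: a three-wavelength LED
(730/800/850 nm) with photodiodes at 3 and 4 cm, sampled at 120 Hz.  Every
recording carries a ground-truth sidecar (true concentrations, StO₂ and all
generating parameters plus the seed), so each pipeline stage can be tested
against known truth.

Two forward modes separate algorithm correctness from physics fidelity:

``"mbll-exact"``
    I(λ,ρ) = I₀(λ)·g(ρ)·10^(−DPF·ρ·μa(λ) − G).  The single-separation StO₂
    estimator is provably exact on this model, so it serves as the
    unit-test mode.

``"diffusion"``
    steady-state reflectance of a semi-infinite homogeneous medium
    (extrapolated-boundary two-dipole solution), the physically realistic
    mode, for which recovery tolerances are established empirically.

The breath-hold response is a smooth shape-preserving cubic through an
initial dip (default 10 s after onset) and a supra-baseline peak (default
27.5 s), followed by an exponential-like return to baseline; dip/peak
amplitudes default to the group-mean magnitudes of the study conditions this
generator emulates (ΔHbO −0.002/+0.021 µM; ΔStO₂ −0.04/+1.22 % on the
single-separation scale, −0.10/+0.48 % on the SRS scale).

Physiological noise is modeled where it physically arises: cardiac (1.1 Hz),
respiratory (0.25 Hz) and Mayer-wave (0.1 Hz) oscillations perturb HbO
concentration; white noise, slow drift and (optional) motion spikes act
multiplicatively on detected intensities.  Spike events are shared across the
far-separation channels with per-wavelength amplitude jitter, reproducing the
shared-artifact behavior of two-separation probes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import fsolve
from scipy.stats import norm

from .errors import ValidationError
from .io import Recording, channel_name, write_raw_worksheet
from .optics import (
    ChromophoreState,
    DPFSet,
    WavelengthTriple,
    default_extinction_table,
)

__all__ = [
    "TissueModel",
    "InstrumentModel",
    "BreathHoldScenario",
    "NoiseModel",
    "GroupVariability",
    "SimulatedRecording",
    "GroupTrial",
    "GroupDataset",
    "diffusion_reflectance",
    "breath_hold_concentrations",
    "simulate_recording",
    "simulate_group",
    "sample_hold_durations",
]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueModel:
    """Homogeneous tissue standing in for the probed forehead volume."""

    baseline_sto2_pct: float = 70.0
    baseline_thb_um: float = 60.0
    musp_cm1: tuple[float, float, float] = (10.0, 10.0, 10.0)
    refractive_index: float = 1.4
    #: coupling loss per (wavelength-independent) channel, OD, keyed by separation
    coupling_od: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.musp_cm1) <= 0:
            raise ValidationError("μs' must be > 0")
        if self.baseline_thb_um <= 0:
            raise ValidationError("THb must be > 0")
        ChromophoreState.from_sto2(self.baseline_sto2_pct, self.baseline_thb_um)

    @property
    def baseline_state(self) -> ChromophoreState:
        return ChromophoreState.from_sto2(self.baseline_sto2_pct, self.baseline_thb_um)


@dataclass(frozen=True)
class InstrumentModel:
    """The probe: LED wavelengths, detector geometry, gains, sampling."""

    fs_hz: float = 120.0
    wavelengths: WavelengthTriple = field(default_factory=WavelengthTriple)
    separations_cm: tuple[float, float] = (3.0, 4.0)
    source_intensities: tuple[float, float, float] = (1.0, 0.9, 1.1)
    detector_gains: tuple[float, float] = (1.0, 1.0)
    dpf: DPFSet = field(default_factory=DPFSet)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be > 0")
        if min(self.source_intensities) <= 0 or min(self.detector_gains) <= 0:
            raise ValidationError("source intensities and gains must be > 0")


@dataclass(frozen=True)
class BreathHoldScenario:
    """Canonical breath-hold hemodynamic response: dip then supra-baseline peak."""

    t_onset_s: float = 15.0
    hold_duration_s: float = 41.4
    dip_time_s: float = 10.0      # after onset
    peak_time_s: float = 27.5     # after onset
    recovery_tau_s: float = 18.0
    hbo_dip_um: float = -0.002
    hbo_peak_um: float = 0.021
    sto2_dip_pct: float = -0.04
    sto2_peak_pct: float = 1.22

    def __post_init__(self) -> None:
        if self.peak_time_s <= self.dip_time_s:
            raise ValidationError(
                f"peak time ({self.peak_time_s}s) must follow dip time "
                f"({self.dip_time_s}s)"
            )
        if self.hold_duration_s <= 0 or self.recovery_tau_s <= 0:
            raise ValidationError("hold duration and recovery tau must be > 0")

    @classmethod
    def canonical_ssds_scale(cls, **kw) -> "BreathHoldScenario":
        """Amplitudes on the single-separation estimator's group-mean scale."""
        return cls(sto2_dip_pct=-0.04, sto2_peak_pct=1.22, **kw)

    @classmethod
    def canonical_srs_scale(cls, **kw) -> "BreathHoldScenario":
        """Amplitudes on the SRS estimator's group-mean scale."""
        return cls(sto2_dip_pct=-0.10, sto2_peak_pct=0.48, **kw)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument + physiology noise; identical seed ⇒ identical recording."""

    white_sd_rel: float = 0.001
    cardiac_amp_um: float = 0.02
    cardiac_hz: float = 1.1
    resp_amp_um: float = 0.01
    resp_hz: float = 0.25
    mayer_amp_um: float = 0.01
    mayer_hz: float = 0.1
    drift_rel_per_min_sd: float = 0.0005
    spike_rate_hz: float = 0.0
    spike_amp_rel: float = 0.2
    spike_wavelength_jitter: float = 0.3
    spike_duration_s: float = 0.1
    hold_fluct_sd_pct: float = 0.3
    hold_fluct_threshold_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("white_sd_rel", "cardiac_amp_um", "resp_amp_um",
                     "mayer_amp_um", "spike_rate_hz", "spike_amp_rel",
                     "hold_fluct_sd_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be ≥ 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """All noise amplitudes zero (noiseless forward model)."""
        return cls(white_sd_rel=0, cardiac_amp_um=0, resp_amp_um=0,
                   mayer_amp_um=0, drift_rel_per_min_sd=0, spike_rate_hz=0,
                   hold_fluct_sd_pct=0, seed=seed)


# ---------------------------------------------------------------------------
# diffusion forward model
# ---------------------------------------------------------------------------

def _effective_reflection_parameter(n: float) -> float:
    """Groenhuis/Egan internal-reflection parameter for refractive mismatch."""
    r_eff = -1.440 * n ** -2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffusion_reflectance(mu_a, musp, rho, n: float = 1.4):
    """Steady-state reflectance of a semi-infinite homogeneous medium.

    Extrapolated-boundary two-dipole solution: isotropic source at depth
    z0 = 1/(μa+μs′), image source mirrored about the extrapolated boundary at
    −(z0 + 2·zb) with zb = 2·D·A(n), and μeff = sqrt(3·μa·(μa+μs′)).  Output
    is in arbitrary linear units; strictly decreasing in ρ and in μa.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    musp_a = np.asarray(musp, dtype=float)
    rho_a = np.asarray(rho, dtype=float)
    if np.any(mu_a < 0) or np.any(musp_a <= 0) or np.any(rho_a <= 0):
        raise ValidationError("need μa ≥ 0, μs' > 0, ρ > 0")
    mu_t = mu_a + musp_a
    z0 = 1.0 / mu_t
    D = 1.0 / (3.0 * mu_t)
    zb = 2.0 * D * _effective_reflection_parameter(n)
    mueff = np.sqrt(3.0 * mu_a * mu_t)
    r1 = np.sqrt(rho_a ** 2 + z0 ** 2)
    r2 = np.sqrt(rho_a ** 2 + (z0 + 2.0 * zb) ** 2)
    return (1.0 / (4.0 * np.pi)) * (
        z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1 ** 2
        + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2 ** 2
    )


# ---------------------------------------------------------------------------
# breath-hold response
# ---------------------------------------------------------------------------

def _response_curve(
    t: np.ndarray,
    onset: float,
    dip_time: float,
    dip_amp: float,
    peak_time: float,
    peak_amp: float,
    tau: float,
) -> np.ndarray:
    """Smooth response: 0 before onset, through (dip, peak), decaying recovery.

    Shape-preserving monotone cubic (PCHIP) through knots whose interior
    extrema are exactly the configured dip and peak, then exponential-decay
    knots every 5 s back toward baseline.
    """
    if dip_amp == 0 and peak_amp == 0:
        return np.zeros_like(t)
    knots_t = [t[0] - 1.0, onset, onset + dip_time, onset + peak_time]
    knots_v = [0.0, 0.0, dip_amp, peak_amp]
    step = 5.0
    t_k = onset + peak_time + step
    while t_k < t[-1] + 2 * step:
        knots_v.append(peak_amp * np.exp(-(t_k - onset - peak_time) / tau))
        knots_t.append(t_k)
        t_k += step
    return PchipInterpolator(np.asarray(knots_t), np.asarray(knots_v))(t)


def concentrations_from_deltas(
    tissue: TissueModel, d_hbo: np.ndarray, d_sto2: np.ndarray
) -> pd.DataFrame:
    """Chromophore trajectory consistent with given ΔHbO (µM) and ΔStO₂ (%).

    HbO follows the ΔHbO curve directly; Hb is chosen so the saturation
    follows the ΔStO₂ curve:  THb = HbO/s,  Hb = THb − HbO.
    """
    base = tissue.baseline_state
    c_hbo = base.c_hbo + np.asarray(d_hbo, dtype=float)
    s = (tissue.baseline_sto2_pct + np.asarray(d_sto2, dtype=float)) / 100.0
    if np.any(s <= 0) or np.any(s >= 1):
        raise ValidationError("StO2 trajectory left the open interval (0, 100)%")
    thb = c_hbo / s
    c_hb = thb - c_hbo
    if np.any(c_hbo < 0) or np.any(c_hb < 0):
        raise ValidationError("concentration trajectory became negative")
    return pd.DataFrame(
        {"c_hbo": c_hbo, "c_hb": c_hb, "thb": thb, "sto2": 100.0 * s}
    )


def breath_hold_concentrations(
    scenario: BreathHoldScenario, tissue: TissueModel, t: np.ndarray
) -> pd.DataFrame:
    """Noiseless ground-truth chromophore time series for a scenario.

    The grid must cover onset−5 s through onset+dip and onset+peak.
    """
    t = np.asarray(t, dtype=float)
    if t[0] > scenario.t_onset_s - 5.0 or t[-1] < scenario.t_onset_s + scenario.peak_time_s:
        raise ValidationError(
            "time grid must cover onset−5 s through the response peak"
        )
    d_hbo = _response_curve(
        t, scenario.t_onset_s, scenario.dip_time_s, scenario.hbo_dip_um,
        scenario.peak_time_s, scenario.hbo_peak_um, scenario.recovery_tau_s,
    )
    d_sto2 = _response_curve(
        t, scenario.t_onset_s, scenario.dip_time_s, scenario.sto2_dip_pct,
        scenario.peak_time_s, scenario.sto2_peak_pct, scenario.recovery_tau_s,
    )
    out = concentrations_from_deltas(tissue, d_hbo, d_sto2)
    out.insert(0, "time_s", t)
    out["d_hbo_scenario"] = d_hbo
    out["d_sto2_scenario"] = d_sto2
    return out


# ---------------------------------------------------------------------------
# full recording simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRecording:
    """A raw recording plus its ground truth and generating parameters."""

    recording: Recording
    truth: pd.DataFrame
    params: dict

    def write(self, out_dir, stem: str) -> dict:
        """Write raw worksheet, truth CSV and JSON sidecar; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "raw": out_dir / f"{stem}_raw.csv",
            "truth": out_dir / f"{stem}_truth.csv",
            "sidecar": out_dir / f"{stem}_sidecar.json",
        }
        write_raw_worksheet(self.recording, paths["raw"])
        self.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
        sidecar = dict(self.params)
        sidecar["files"] = {k: p.name for k, p in paths.items()}
        paths["sidecar"].write_text(json.dumps(sidecar, indent=1, default=str))
        return paths


def simulate_recording(
    tissue: TissueModel = TissueModel(),
    scenario: BreathHoldScenario = BreathHoldScenario(),
    noise: NoiseModel = NoiseModel(),
    instrument: InstrumentModel = InstrumentModel(),
    mode: str = "diffusion",
    duration_s: float | None = None,
) -> SimulatedRecording:
    """Simulate one breath-hold recording.

    Pipeline per sample: concentrations (scenario + physiological
    oscillations) → μa(λ) → forward model per separation → channel gains and
    coupling losses → white noise, drift and spikes.  Deterministic for a
    given ``noise.seed``.
    """
    if mode not in ("diffusion", "mbll-exact"):
        raise ValidationError(f"unknown forward mode '{mode}'")
    rng = np.random.default_rng(noise.seed)
    fs = instrument.fs_hz
    if duration_s is None:
        duration_s = scenario.t_onset_s + max(45.0, scenario.hold_duration_s) + 10.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # --- scenario curves, plus long-hold low-frequency fluctuation ---
    d_hbo = _response_curve(
        t, scenario.t_onset_s, scenario.dip_time_s, scenario.hbo_dip_um,
        scenario.peak_time_s, scenario.hbo_peak_um, scenario.recovery_tau_s,
    )
    d_sto2 = _response_curve(
        t, scenario.t_onset_s, scenario.dip_time_s, scenario.sto2_dip_pct,
        scenario.peak_time_s, scenario.sto2_peak_pct, scenario.recovery_tau_s,
    )
    if (
        scenario.hold_duration_s > noise.hold_fluct_threshold_s
        and noise.hold_fluct_sd_pct > 0
    ):
        fluct = gaussian_filter1d(rng.standard_normal(n), sigma=fs * 1.0)
        sd = fluct.std()
        if sd > 0:
            fluct *= noise.hold_fluct_sd_pct / sd
        in_hold = (t >= scenario.t_onset_s) & (
            t <= scenario.t_onset_s + scenario.hold_duration_s
        )
        d_sto2 = d_sto2 + np.where(in_hold, fluct, 0.0)

    # --- physiological oscillations on HbO ---
    osc = np.zeros(n)
    for amp, freq in (
        (noise.cardiac_amp_um, noise.cardiac_hz),
        (noise.resp_amp_um, noise.resp_hz),
        (noise.mayer_amp_um, noise.mayer_hz),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        if amp > 0:
            osc += amp * np.sin(2 * np.pi * freq * t + phase)
    conc = concentrations_from_deltas(tissue, d_hbo + osc, d_sto2)
    conc.insert(0, "time_s", t)
    conc["d_hbo_scenario"] = d_hbo
    conc["d_sto2_scenario"] = d_sto2

    # --- forward model ---
    table = default_extinction_table()
    E = table.matrix(instrument.wavelengths)  # (3, 2)
    mua = np.column_stack([conc["c_hbo"], conc["c_hb"]]) @ E.T  # (T, 3)

    far_sep = max(instrument.separations_cm)
    spike_envelope = None
    spike_times = np.array([])
    if noise.spike_rate_hz > 0:
        n_spikes = rng.poisson(noise.spike_rate_hz * duration_s)
        spike_times = np.sort(rng.uniform(0, duration_s, n_spikes))
        spike_envelope = np.zeros(n)
        for t_k in spike_times:
            tail = t >= t_k
            spike_envelope[tail] += np.exp(-(t[tail] - t_k) / noise.spike_duration_s)

    data = {"time_s": t}
    for sep, gain, g_od in zip(
        instrument.separations_cm, instrument.detector_gains, tissue.coupling_od
    ):
        for j, wl in enumerate(instrument.wavelengths):
            i0 = instrument.source_intensities[j]
            if mode == "mbll-exact":
                dpf_j = instrument.dpf.as_array()[j]
                clean = i0 * 10.0 ** (-dpf_j * sep * mua[:, j] - g_od)
            else:
                clean = i0 * diffusion_reflectance(
                    mua[:, j], tissue.musp_cm1[j], sep, tissue.refractive_index
                ) * 10.0 ** (-g_od)
            signal = clean * gain
            if noise.white_sd_rel > 0:
                signal = signal * (1.0 + noise.white_sd_rel * rng.standard_normal(n))
            if noise.drift_rel_per_min_sd > 0:
                slope = rng.normal(0.0, noise.drift_rel_per_min_sd)
                signal = signal * (1.0 + slope * t / 60.0)
            if spike_envelope is not None and sep == far_sep:
                jitter = 1.0 + noise.spike_wavelength_jitter * rng.standard_normal()
                signal = signal * np.clip(
                    1.0 - noise.spike_amp_rel * jitter * spike_envelope, 1e-6, None
                )
            data[channel_name(wl, sep)] = signal

    recording = Recording(
        frame=pd.DataFrame(data),
        fs=fs,
        wavelengths=instrument.wavelengths,
        separations=tuple(instrument.separations_cm),
        meta={
            "source_intensities": tuple(instrument.source_intensities),
            "mode": mode,
            "seed": noise.seed,
        },
    )
    params = {
        "tissue": asdict(tissue),
        "scenario": asdict(scenario),
        "noise": asdict(noise),
        "instrument": asdict(instrument),
        "mode": mode,
        "seed": noise.seed,
        "spike_times_s": spike_times.tolist(),
        "k_true": (
            instrument.source_intensities[0] / instrument.source_intensities[1],
            instrument.source_intensities[2] / instrument.source_intensities[1],
        ),
    }
    return SimulatedRecording(recording=recording, truth=conc, params=params)


# ---------------------------------------------------------------------------
# group simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupVariability:
    """Between-subject / between-trial spread of the group scenario."""

    sto2_baseline_sd_pct: float = 3.0
    thb_sd_um: float = 8.0
    amplitude_rel_sd: float = 0.3
    hold_mean_s: float = 41.4
    hold_sd_s: float = 22.4
    hold_range_s: tuple[float, float] = (17.5, 120.0)

    @classmethod
    def none(cls) -> "GroupVariability":
        return cls(sto2_baseline_sd_pct=0.0, thb_sd_um=0.0,
                   amplitude_rel_sd=0.0, hold_sd_s=0.0)


@lru_cache(maxsize=8)
def _calibrate_truncated_lognormal(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """(μ, σ) of the underlying lognormal whose truncation to [lo, hi] has the
    requested mean and sd (solved from the analytic truncated moments)."""

    def truncated_moments(mu, sigma):
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        z = norm.cdf(b) - norm.cdf(a)
        m1 = np.exp(mu + sigma ** 2 / 2) * (norm.cdf(b - sigma) - norm.cdf(a - sigma)) / z
        m2 = (
            np.exp(2 * mu + 2 * sigma ** 2)
            * (norm.cdf(b - 2 * sigma) - norm.cdf(a - 2 * sigma)) / z
        )
        return m1, np.sqrt(m2 - m1 ** 2)

    def residual(p):
        m1, s1 = truncated_moments(p[0], p[1])
        return [m1 - mean, s1 - sd]

    sol, info, ier, msg = fsolve(residual, [np.log(mean), 0.7], full_output=True)
    if ier != 1:
        raise RuntimeError(f"truncated-lognormal calibration failed: {msg}")
    return float(sol[0]), float(sol[1])


def sample_hold_durations(
    n: int, rng: np.random.Generator, variability: GroupVariability = GroupVariability()
) -> np.ndarray:
    """Draw breath-hold durations from the calibrated truncated lognormal."""
    if variability.hold_sd_s == 0:
        return np.full(n, variability.hold_mean_s)
    lo, hi = variability.hold_range_s
    mu, sigma = _calibrate_truncated_lognormal(
        variability.hold_mean_s, variability.hold_sd_s, lo, hi
    )
    u_lo = norm.cdf((np.log(lo) - mu) / sigma)
    u_hi = norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(u_lo, u_hi, n)
    return np.exp(mu + sigma * norm.ppf(u))


@dataclass
class GroupTrial:
    subject_id: int
    trial_id: int
    onset_s: float
    hold_s: float
    sim: SimulatedRecording


@dataclass
class GroupDataset:
    """A simulated cohort: one recording per breath-hold trial."""

    trials: list[GroupTrial]
    seed: int
    params: dict

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "onset_s": tr.onset_s,
                    "hold_s": tr.hold_s,
                }
                for tr in self.trials
            ]
        )

    def write(self, out_dir) -> Path:
        """Write all trials plus a manifest; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for tr in self.trials:
            stem = f"s{tr.subject_id:02d}_t{tr.trial_id}"
            paths = tr.sim.write(out_dir, stem)
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "onset_s": tr.onset_s,
                    "hold_s": tr.hold_s,
                    "raw_file": paths["raw"].name,
                }
            )
        manifest_path = out_dir / "manifest.csv"
        with manifest_path.open("w") as fh:
            fh.write(f"# seed={self.seed}\n")
            pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")
        (out_dir / "params.json").write_text(
            json.dumps(self.params, indent=1, default=str)
        )
        return manifest_path


def simulate_group(
    n_subjects: int = 19,
    trials_per_subject: int | list[int] | None = None,
    tissue: TissueModel = TissueModel(),
    scenario: BreathHoldScenario = BreathHoldScenario(),
    noise: NoiseModel = NoiseModel(),
    instrument: InstrumentModel = InstrumentModel(),
    variability: GroupVariability = GroupVariability(),
    mode: str = "diffusion",
    seed: int = 0,
) -> GroupDataset:
    """Simulate a cohort of breath-hold trials with between-subject spread.

    The default schedule gives every subject 3 trials except the last, who
    gets 2 — with 19 subjects that is the study's 56-trial layout.  Baseline
    StO₂/THb, response amplitudes and hold durations vary per subject (holds
    per trial) unless ``variability`` is zeroed, in which case all trials are
    identical up to their noise seeds.
    """
    if n_subjects < 1:
        raise ValidationError("need at least one subject")
    if trials_per_subject is None:
        schedule = [3] * (n_subjects - 1) + [2] if n_subjects > 1 else [3]
    elif isinstance(trials_per_subject, int):
        schedule = [trials_per_subject] * n_subjects
    else:
        schedule = list(trials_per_subject)
        if len(schedule) != n_subjects:
            raise ValidationError("trials_per_subject list length must equal n_subjects")

    rng = np.random.default_rng(seed)
    trials: list[GroupTrial] = []
    for subj in range(n_subjects):
        sto2_b = float(np.clip(
            rng.normal(tissue.baseline_sto2_pct, variability.sto2_baseline_sd_pct),
            55.0, 85.0,
        ))
        thb_b = float(np.clip(
            rng.normal(tissue.baseline_thb_um, variability.thb_sd_um), 30.0, 120.0
        ))
        amp_factor = float(np.exp(rng.normal(0.0, variability.amplitude_rel_sd)))
        subj_tissue = replace(
            tissue, baseline_sto2_pct=sto2_b, baseline_thb_um=thb_b
        )
        holds = sample_hold_durations(schedule[subj], rng, variability)
        for trial, hold in enumerate(holds, start=1):
            subj_scenario = replace(
                scenario,
                hold_duration_s=float(hold),
                hbo_dip_um=scenario.hbo_dip_um * amp_factor,
                hbo_peak_um=scenario.hbo_peak_um * amp_factor,
                sto2_dip_pct=scenario.sto2_dip_pct * amp_factor,
                sto2_peak_pct=scenario.sto2_peak_pct * amp_factor,
            )
            trial_noise = replace(noise, seed=int(rng.integers(2 ** 31)))
            sim = simulate_recording(
                subj_tissue, subj_scenario, trial_noise, instrument, mode=mode
            )
            trials.append(
                GroupTrial(
                    subject_id=subj + 1,
                    trial_id=trial,
                    onset_s=subj_scenario.t_onset_s,
                    hold_s=float(hold),
                    sim=sim,
                )
            )
    params = {
        "n_subjects": n_subjects,
        "schedule": schedule,
        "seed": seed,
        "mode": mode,
        "variability": asdict(variability),
        "scenario": asdict(scenario),
        "tissue": asdict(tissue),
        "noise": asdict(noise),
    }
    return GroupDataset(trials=trials, seed=seed, params=params)
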