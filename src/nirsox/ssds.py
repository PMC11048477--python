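"""Absolute StO₂ from a single source–detector separation (SSDS).

The estimator combines backscattered intensities at three wavelengths
(λ1 < λ2 < λ3, λ2 near the 800 nm isosbestic point) from **one** detector with
two calibration constants — the emitted-intensity ratios
k1 = I₀(λ1)/I₀(λ2) and k2 = I₀(λ3)/I₀(λ2) — into three pairwise attenuation
differences

    A12 = log10(k1·I(λ2)/I(λ1)),
    A32 = log10(k2·I(λ2)/I(λ3)),
    A31 = log10(k2·I(λ1)/(k1·I(λ3)))  =  A32 − A12,

and evaluates

            DPF3·A12·ε_Hb(λ3) − DPF1·A32·ε_Hb(λ1) + DPF2·A31·ε_Hb(λ2)
  StO₂ = ─────────────────────────────────────────────────────────────── · 100
          DPF1·A32·Δε(λ1) − DPF3·A12·Δε(λ3) − DPF2·A31·Δε(λ2)

with Δε = ε_HbO − ε_Hb.  Under the homogeneous equal-DPF Beer–Lambert model
I(λ) = I₀(λ)·10^(−DPF·d·μa(λ) − G) with wavelength-independent coupling loss
G, each A term equals DPF·d·(μa_i − μa_j); the Hb cross-terms cancel exactly
in the numerator and the HbO/Hb terms combine in the denominator so that the
ratio is *algebraically exact*: it equals HbO/(HbO+Hb) for every saturation,
total hemoglobin, coupling loss and separation.  DPF, d and G all cancel,
which is why a single separation suffices for an absolute estimate.

The ratio of log-term sums is also invariant to the logarithm base; base 10
is used, with an optional natural-log path for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingChannelError, ValidationError
from .io import Recording
from .optics import (
    ChromophoreState,
    DPFSet,
    ExtinctionTable,
    WavelengthTriple,
    default_extinction_table,
    mua_spectrum,
)
from .traces import StO2Trace

__all__ = [
    "SsdsCalibration",
    "SsdsResult",
    "pairwise_attenuation_differences",
    "ssds_sto2",
    "ssds_timeseries",
    "calibrate_k",
]

#: |denominator| below this (in log-OD·extinction units) → flagged, not a number
DEFAULT_DENOMINATOR_TOL = 1e-12


@dataclass(frozen=True)
class SsdsCalibration:
    """Emitted-intensity calibration ratios k1 = I₀(λ1)/I₀(λ2), k2 = I₀(λ3)/I₀(λ2)."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValidationError(f"calibration ratios must be > 0, got {self}")


@dataclass
class SsdsResult:
    """Unclamped StO₂ (%) with QC flags; scalar or per-sample arrays."""

    sto2: np.ndarray | float
    flags: dict[str, np.ndarray]


def _log(base10: bool):
    return np.log10 if base10 else np.log


def pairwise_attenuation_differences(
    i1, i2, i3, cal: SsdsCalibration, base10: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three log ratio terms (A12, A32, A31); A31 ≡ A32 − A12.

    The numerator's third term (A31) and the denominator's third term (−A31)
    are exact negatives — the log of a reciprocal.
    """
    i1, i2, i3 = (np.asarray(x, dtype=float) for x in (i1, i2, i3))
    if np.any(i1 <= 0) or np.any(i2 <= 0) or np.any(i3 <= 0):
        raise ValidationError("intensities must be > 0")
    log = _log(base10)
    a12 = log(cal.k1 * i2 / i1)
    a32 = log(cal.k2 * i2 / i3)
    a31 = log(cal.k2 * i1 / (cal.k1 * i3))
    return a12, a32, a31


def _ssds_from_terms(
    a12: np.ndarray,
    a32: np.ndarray,
    a31: np.ndarray,
    dpf: DPFSet,
    table: ExtinctionTable,
    wavelengths: WavelengthTriple,
    denominator_tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    e1 = table.row(wavelengths.lambda1)
    e2 = table.row(wavelengths.lambda2)
    e3 = table.row(wavelengths.lambda3)
    num = dpf.dpf3 * a12 * e3.eps_hb - dpf.dpf1 * a32 * e1.eps_hb + dpf.dpf2 * a31 * e2.eps_hb
    den = (
        dpf.dpf1 * a32 * (e1.eps_hbo - e1.eps_hb)
        - dpf.dpf3 * a12 * (e3.eps_hbo - e3.eps_hb)
        - dpf.dpf2 * a31 * (e2.eps_hbo - e2.eps_hb)
    )
    near_zero = np.abs(den) < denominator_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = 100.0 * num / np.where(near_zero, np.nan, den)
    return sto2, near_zero


def ssds_sto2(
    i1,
    i2,
    i3,
    cal: SsdsCalibration,
    dpf: DPFSet = DPFSet(),
    table: ExtinctionTable | None = None,
    wavelengths: WavelengthTriple = WavelengthTriple(),
    denominator_tol: float = DEFAULT_DENOMINATOR_TOL,
    base10: bool = True,
) -> SsdsResult:
    """Evaluate the SSDS estimator on intensities at the three wavelengths.

    Returns the raw, unclamped StO₂ in percent.  A denominator smaller than
    ``denominator_tol`` yields NaN with the ``denominator_near_zero`` flag —
    never a fabricated number.  Values outside [0, 100] raise
    ``out_of_physio_range``; they are reported as-is.
    """
    table = table or default_extinction_table()
    a12, a32, a31 = pairwise_attenuation_differences(i1, i2, i3, cal, base10=base10)
    sto2, near_zero = _ssds_from_terms(
        a12, a32, a31, dpf, table, wavelengths, denominator_tol
    )
    sto2_arr = np.asarray(sto2, dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = np.isfinite(sto2_arr) & ((sto2_arr < 0) | (sto2_arr > 100))
    return SsdsResult(
        sto2=sto2,
        flags={
            "denominator_near_zero": np.atleast_1d(near_zero),
            "out_of_physio_range": np.atleast_1d(out_of_range),
        },
    )


def ssds_timeseries(
    recording: Recording,
    cal: SsdsCalibration,
    separation_cm: float,
    dpf: DPFSet = DPFSet(),
    table: ExtinctionTable | None = None,
    denominator_tol: float = DEFAULT_DENOMINATOR_TOL,
    smooth_window_s: float | None = None,
) -> StO2Trace:
    """Per-sample SSDS StO₂ at one separation, with QC flags.

    Non-positive samples are flagged ``nonpositive_intensity`` and produce NaN
    at that sample only; neighbors are unaffected.  Optional moving-average
    smoothing (off by default) is applied to the *intensities*.
    """
    table = table or default_extinction_table()
    wavelengths = recording.wavelengths
    try:
        I = recording.intensities(separation_cm)
    except MissingChannelError:
        raise
    bad = (I <= 0) | ~np.isfinite(I)
    I_safe = np.where(bad, np.nan, I)

    if smooth_window_s:
        n = max(1, int(round(smooth_window_s * recording.fs)))
        kernel = np.ones(n) / n
        pad = n // 2
        I_safe = np.column_stack([
            np.convolve(np.pad(col, pad, mode="edge"), kernel, mode="same")[pad:pad + len(col)]
            for col in I_safe.T
        ])

    log = np.log10
    with np.errstate(invalid="ignore", divide="ignore"):
        a12 = log(cal.k1 * I_safe[:, 1] / I_safe[:, 0])
        a32 = log(cal.k2 * I_safe[:, 1] / I_safe[:, 2])
        a31 = a32 - a12
    sto2, near_zero = _ssds_from_terms(
        a12, a32, a31, dpf, table, wavelengths, denominator_tol
    )
    with np.errstate(invalid="ignore"):
        out_of_range = np.isfinite(sto2) & ((sto2 < 0) | (sto2 > 100))
    return StO2Trace(
        time=recording.time,
        sto2=sto2,
        method=f"ssds-{separation_cm:g}cm",
        flags={
            "nonpositive_intensity": bad.any(axis=1),
            "denominator_near_zero": near_zero & ~bad.any(axis=1),
            "out_of_physio_range": out_of_range,
        },
    )


def calibrate_k(
    recording: Recording,
    method: str = "source_spec",
    separation_cm: float | None = None,
    source_intensities: tuple[float, float, float] | None = None,
    baseline_epoch: tuple[float, float] | None = None,
    assumed_state: ChromophoreState | None = None,
    dpf: DPFSet = DPFSet(),
    table: ExtinctionTable | None = None,
    min_baseline_s: float = 1.0,
) -> SsdsCalibration:
    """Derive the calibration ratios k1, k2.

    ``source_spec``
        from declared emitted intensities I₀(λ) — the device's "initial
        intensity ratios".  Taken from ``source_intensities`` or from
        ``recording.meta['source_intensities']``.

    ``baseline_assumed_sto2``
        from the detected baseline-epoch means ī(λ) plus an assumed baseline
        chromophore state: under the homogeneous model,
        k1 = (ī1/ī2)·10^(DPF·d·(μa1−μa2)) and k2 = (ī3/ī2)·10^(DPF·d·(μa3−μa2)),
        so that the estimator reproduces the assumed StO₂ over the baseline.
        An assumed StO₂ different from the truth yields a systematic, monotone
        offset thereafter.
    """
    table = table or default_extinction_table()
    if method == "source_spec":
        i0 = source_intensities or recording.meta.get("source_intensities")
        if i0 is None:
            raise ValidationError(
                "source_spec calibration requires declared emitted intensities"
            )
        i0 = tuple(float(x) for x in i0)
        return SsdsCalibration(k1=i0[0] / i0[1], k2=i0[2] / i0[1])

    if method == "baseline_assumed_sto2":
        if baseline_epoch is None or assumed_state is None or separation_cm is None:
            raise ValidationError(
                "baseline calibration requires baseline_epoch, assumed_state "
                "and separation_cm"
            )
        if baseline_epoch[1] - baseline_epoch[0] < min_baseline_s:
            raise ValidationError(
                f"baseline epoch shorter than {min_baseline_s} s minimum"
            )
        t = recording.time
        mask = (t >= baseline_epoch[0]) & (t < baseline_epoch[1])
        if not np.any(mask):
            raise ValidationError(f"baseline epoch {baseline_epoch} has no samples")
        I = recording.intensities(separation_cm)[mask]
        ibar = I.mean(axis=0)
        if np.any(ibar <= 0):
            raise ValidationError("baseline mean intensities must be > 0")
        mua = mua_spectrum(assumed_state, table, recording.wavelengths)
        pl = separation_cm * dpf.as_array()
        k1 = (ibar[0] / ibar[1]) * 10.0 ** (pl[0] * mua[0] - pl[1] * mua[1])
        k2 = (ibar[2] / ibar[1]) * 10.0 ** (pl[2] * mua[2] - pl[1] * mua[1])
        return SsdsCalibration(k1=float(k1), k2=float(k2))

    raise ValidationError(f"unknown calibration method '{method}'")
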