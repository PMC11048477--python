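"""Spatially resolved spectroscopy (SRS) StO₂ from two source–detector separations.

In the diffusion asymptote of a semi-infinite medium the detected intensity
falls off as R(ρ) ∝ exp(−μeff·ρ)/ρ², so the spatial slope of the natural-log
attenuation across two separations,

    slope = ln(10)·(A(ρ2) − A(ρ1))/(ρ2 − ρ1),   A = −log10(I),

satisfies slope ≈ μeff + 2/ρ̄ with ρ̄ the mean separation.  Squaring the
corrected slope and dividing by 3μs′(λ) gives an absorption coefficient up to
a common scale,

    μa,rel(λ) = (slope(λ) − 2/ρ̄)² / (3·μs′(λ)),

and the two-chromophore inversion of the μa,rel spectrum yields StO₂ — the
unknown common scale cancels in the HbO/(HbO+Hb) ratio, as do source power
and any gain shared by both detectors.  A gain *mismatch* between the two
photodiodes biases the slope; an optional relative-gain constant (default 1.0,
i.e. matched detectors) corrects a known mismatch.

μs′ is assumed wavelength-independent by default (scalar), or supplied per
wavelength (e.g. a linear-in-λ model); only its *spectral shape* affects StO₂.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .io import Recording
from .optics import (
    ExtinctionTable,
    WavelengthTriple,
    default_extinction_table,
    solve_two_chromophores_traces,
)
from .traces import StO2Trace

__all__ = [
    "attenuation_slope",
    "srs_scaled_absorption",
    "srs_sto2",
    "srs_timeseries",
]

LN10 = float(np.log(10.0))


def attenuation_slope(a1, a2, rho1: float, rho2: float):
    """Spatial attenuation slope in ln-units per cm from OD at ρ1 < ρ2."""
    if rho2 <= rho1 or rho1 <= 0:
        raise ValidationError(f"need ρ2 > ρ1 > 0, got ({rho1}, {rho2})")
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    return LN10 * (a2 - a1) / (rho2 - rho1)


def srs_scaled_absorption(slope, mean_rho: float, musp):
    """Relative μa per wavelength: (slope − 2/ρ̄)²/(3μs′).

    Returns ``(mua_rel, valid)``; samples with slope ≤ 2/ρ̄ are outside the
    diffusion asymptote's validity and flagged invalid (NaN), not fabricated.
    """
    if mean_rho <= 0:
        raise ValidationError("mean separation must be > 0")
    slope = np.asarray(slope, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(musp <= 0):
        raise ValidationError("μs' must be > 0")
    excess = slope - 2.0 / mean_rho
    valid = excess > 0
    with np.errstate(invalid="ignore"):
        mua_rel = np.where(valid, excess, np.nan) ** 2 / (3.0 * musp)
    return mua_rel, valid


def srs_sto2(
    mua_rel: np.ndarray,
    table: ExtinctionTable | None = None,
    wavelengths: WavelengthTriple = WavelengthTriple(),
):
    """StO₂ (%) from a relative μa spectrum (scale factor cancels)."""
    table = table or default_extinction_table()
    mu = np.atleast_2d(np.asarray(mua_rel, dtype=float))
    c_hbo, c_hb = solve_two_chromophores_traces(mu, table, wavelengths)
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = 100.0 * c_hbo / (c_hbo + c_hb)
    return sto2[0] if np.asarray(mua_rel).ndim == 1 else sto2


def srs_timeseries(
    recording: Recording,
    musp=10.0,
    table: ExtinctionTable | None = None,
    mean_rho: float | None = None,
    detector_gain_ratio: float = 1.0,
    separations: tuple[float, float] | None = None,
) -> StO2Trace:
    """Per-sample SRS StO₂ from a two-separation recording.

    ``detector_gain_ratio`` is the far/near relative gain correction g: the far
    intensity is divided by g before the slope.  Invalid samples (non-positive
    intensity, or slope at/below 2/ρ̄ at any wavelength) are flagged, not
    interpolated.
    """
    table = table or default_extinction_table()
    if separations is None:
        uniq = sorted(set(recording.separations))
        if len(uniq) != 2:
            raise ValidationError(
                f"SRS requires exactly two separations, recording has {uniq}"
            )
        separations = (uniq[0], uniq[1])
    rho1, rho2 = separations
    rho_bar = mean_rho if mean_rho is not None else 0.5 * (rho1 + rho2)

    I_near = recording.intensities(rho1)
    I_far = recording.intensities(rho2) / detector_gain_ratio
    bad = (I_near <= 0) | (I_far <= 0) | ~np.isfinite(I_near) | ~np.isfinite(I_far)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_near = -np.log10(np.where(I_near > 0, I_near, np.nan))
        a_far = -np.log10(np.where(I_far > 0, I_far, np.nan))
    slope = attenuation_slope(a_near, a_far, rho1, rho2)  # (T, 3)

    musp_arr = np.broadcast_to(np.asarray(musp, dtype=float), (3,))
    mua_rel, valid = srs_scaled_absorption(slope, rho_bar, musp_arr)
    invalid_slope = ~valid.all(axis=1) & ~bad.any(axis=1)

    sto2 = srs_sto2(mua_rel, table, recording.wavelengths)
    with np.errstate(invalid="ignore"):
        out_of_range = np.isfinite(sto2) & ((sto2 < 0) | (sto2 > 100))
    return StO2Trace(
        time=recording.time,
        sto2=sto2,
        method="srs",
        flags={
            "nonpositive_intensity": bad.any(axis=1),
            "invalid_srs_slope": invalid_slope,
            "out_of_physio_range": out_of_range,
        },
    )
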