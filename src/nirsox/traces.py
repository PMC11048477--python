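"""Time-series containers shared by the StO₂ estimators and the MBLL pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["StO2Trace", "ConcentrationChangeTrace"]


def _check_time(time: np.ndarray, n: int) -> None:
    if time.ndim != 1 or time.size != n:
        raise ValidationError("time axis must be 1-D and match the data length")
    if time.size > 1 and not np.all(np.diff(time) > 0):
        raise ValidationError("time must be strictly increasing")


@dataclass
class StO2Trace:
    """A tissue-oxygen-saturation time series with QC flags.

    ``method`` tags the estimator: ``"srs"``, ``"ssds-3cm"`` or ``"ssds-4cm"``.
    ``flags`` maps flag names (e.g. ``denominator_near_zero``,
    ``out_of_physio_range``, ``nonpositive_intensity``, ``invalid_srs_slope``)
    to boolean per-sample arrays.  Flagged samples carry their raw (possibly
    non-finite, unclamped) value; clamping is a presentation choice only.
    """

    time: np.ndarray
    sto2: np.ndarray
    method: str
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sto2 = np.asarray(self.sto2, dtype=float)
        _check_time(self.time, self.sto2.size)
        for name, arr in self.flags.items():
            self.flags[name] = np.asarray(arr, dtype=bool)
            if self.flags[name].size != self.sto2.size:
                raise ValidationError(f"flag '{name}' length mismatch")

    @property
    def qc_any(self) -> np.ndarray:
        """True where any QC flag is raised."""
        out = np.zeros(self.sto2.size, dtype=bool)
        for arr in self.flags.values():
            out |= arr
        return out

    @property
    def valid(self) -> np.ndarray:
        return ~self.qc_any & np.isfinite(self.sto2)


@dataclass
class ConcentrationChangeTrace:
    """Baseline-relative hemoglobin concentration changes (µM) at one SDS."""

    time: np.ndarray
    d_hbo: np.ndarray
    d_hb: np.ndarray
    separation_cm: float = float("nan")
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.d_hbo = np.asarray(self.d_hbo, dtype=float)
        self.d_hb = np.asarray(self.d_hb, dtype=float)
        if self.d_hbo.size != self.d_hb.size:
            raise ValidationError("d_hbo and d_hb must have equal length")
        _check_time(self.time, self.d_hbo.size)
        for name, arr in self.flags.items():
            self.flags[name] = np.asarray(arr, dtype=bool)

    @property
    def d_thb(self) -> np.ndarray:
        """Total-hemoglobin change; the identity ΔTHb = ΔHbO + ΔHb by construction."""
        return self.d_hbo + self.d_hb
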