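"""Worksheet file formats, run configuration and the :class:`Recording` container.

The on-disk formats mirror a two-worksheet convention of wearable CW-NIRS
device apps:

* **raw worksheet** — ``time_s`` plus one intensity column per
  (wavelength, separation) channel, named ``i_{wavelength}nm_{separation}cm``
  (e.g. ``i_730nm_3cm``); arbitrary linear intensity units.
* **processed worksheet** — ``time_s``, MBLL concentration changes per SDS
  (``d_hbo_3cm`` …), and the three StO₂ estimates
  (``sto2_srs``, ``sto2_ssds_3cm``, ``sto2_ssds_4cm``).

Both are plain CSV with ``# key=value`` header comment lines carrying
metadata (sampling rate, seed, config hash, declared source intensities), so
every artifact is self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingChannelError, SchemaError, ValidationError
from .optics import DEFAULT_DPF, WavelengthTriple

__all__ = [
    "Recording",
    "RunConfig",
    "channel_name",
    "read_raw_worksheet",
    "write_raw_worksheet",
    "read_processed_worksheet",
    "write_processed_worksheet",
]

_CHANNEL_RE = re.compile(r"^i_(\d+(?:\.\d+)?)nm_(\d+(?:\.\d+)?)cm$")


def channel_name(wavelength_nm: float, separation_cm: float) -> str:
    """Raw-worksheet column name for one (wavelength, separation) channel."""
    return f"i_{wavelength_nm:g}nm_{separation_cm:g}cm"


@dataclass
class Recording:
    """An in-memory raw recording: intensity frames on a uniform time grid."""

    frame: pd.DataFrame
    fs: float
    wavelengths: WavelengthTriple
    separations: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time_s" not in self.frame.columns:
            raise SchemaError("recording frame must have a time_s column")
        t = self.frame["time_s"].to_numpy(dtype=float)
        if t.size == 0:
            raise ValidationError("recording is empty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("time_s must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy(dtype=float)

    def intensity(self, wavelength_nm: float, separation_cm: float) -> np.ndarray:
        col = channel_name(wavelength_nm, separation_cm)
        if col not in self.frame.columns:
            raise MissingChannelError(
                f"recording has no channel '{col}' "
                f"(columns: {[c for c in self.frame.columns if c != 'time_s']})"
            )
        return self.frame[col].to_numpy(dtype=float)

    def intensities(self, separation_cm: float) -> np.ndarray:
        """(T, 3) intensity matrix at one separation, wavelength-ordered."""
        return np.column_stack(
            [self.intensity(w, separation_cm) for w in self.wavelengths]
        )

    def has_separation(self, separation_cm: float) -> bool:
        try:
            self.intensities(separation_cm)
            return True
        except MissingChannelError:
            return False


# ---------------------------------------------------------------------------
# worksheet readers / writers
# ---------------------------------------------------------------------------

def _write_csv_with_meta(df: pd.DataFrame, path, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_meta(path) -> dict:
    meta: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_raw_worksheet(recording: Recording, path) -> None:
    """Write a raw worksheet CSV; metadata goes into ``#`` header comments."""
    meta = {"fs_hz": f"{recording.fs:g}", **{
        k: v for k, v in recording.meta.items() if isinstance(v, (str, int, float))
    }}
    if "source_intensities" in recording.meta:
        meta["source_intensities"] = ",".join(
            f"{x:.12g}" for x in recording.meta["source_intensities"]
        )
    _write_csv_with_meta(recording.frame, path, meta)


def read_raw_worksheet(path) -> Recording:
    """Read and validate a raw worksheet.

    Rows containing non-positive intensities are flagged (counted in
    ``meta['n_flagged_rows']`` with a warning), not silently dropped; QC and
    gap handling happen downstream.
    """
    path = Path(path)
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"raw worksheet {path} is empty") from None
    if df.shape[0] == 0:
        raise ValidationError(f"raw worksheet {path} contains no data rows")
    if "time_s" not in df.columns:
        raise SchemaError(f"raw worksheet {path} is missing required column time_s")

    wavelengths: set[float] = set()
    separations: set[float] = set()
    extra = []
    for col in df.columns:
        if col == "time_s":
            continue
        m = _CHANNEL_RE.match(col)
        if m is None:
            extra.append(col)
            continue
        wavelengths.add(float(m.group(1)))
        separations.add(float(m.group(2)))
    if extra:
        raise SchemaError(f"raw worksheet {path} has unrecognized columns: {extra}")
    if len(wavelengths) < 3:
        raise SchemaError(
            f"raw worksheet {path} must carry three wavelengths, found {sorted(wavelengths)}"
        )

    intensity_cols = [c for c in df.columns if c != "time_s"]
    bad_rows = (df[intensity_cols] <= 0).any(axis=1) | df[intensity_cols].isna().any(axis=1)
    n_flagged = int(bad_rows.sum())
    if n_flagged:
        lines = (df.index[bad_rows] + 2).tolist()[:10]  # +2: header + 1-based
        warnings.warn(
            f"{path.name}: {n_flagged} row(s) with non-positive or missing "
            f"intensity (first data lines: {lines})",
            stacklevel=2,
        )

    fs = float(meta.get("fs_hz", 0)) or _infer_fs(df["time_s"].to_numpy())
    rec_meta = dict(meta)
    rec_meta["n_flagged_rows"] = n_flagged
    if "source_intensities" in meta:
        rec_meta["source_intensities"] = tuple(
            float(x) for x in str(meta["source_intensities"]).split(",")
        )
    wl = sorted(wavelengths)
    return Recording(
        frame=df,
        fs=fs,
        wavelengths=WavelengthTriple(*wl[:3]),
        separations=tuple(sorted(separations)),
        meta=rec_meta,
    )


def _infer_fs(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValidationError("cannot infer sampling rate from a single sample")
    return 1.0 / float(np.median(np.diff(t)))


PROCESSED_COLUMNS = (
    "time_s",
    "d_hbo_3cm", "d_hb_3cm", "d_thb_3cm",
    "d_hbo_4cm", "d_hb_4cm", "d_thb_4cm",
    "sto2_srs", "sto2_ssds_3cm", "sto2_ssds_4cm",
)


def write_processed_worksheet(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_csv_with_meta(df, path, meta or {})


def read_processed_worksheet(path) -> tuple[pd.DataFrame, dict]:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise SchemaError(f"processed worksheet {path} is missing time_s")
    return df, meta


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration with paper-anchored defaults."""

    wavelengths: tuple[float, float, float] = (730.0, 800.0, 850.0)
    separations: tuple[float, float] = (3.0, 4.0)
    fs_hz: float = 120.0
    dpf: float = DEFAULT_DPF
    extinction_csv: str | None = None
    calibration_method: str = "source_spec"  # or "baseline_assumed_sto2"
    assumed_sto2_pct: float = 70.0
    assumed_thb_um: float = 60.0
    musp_cm1: float = 10.0
    window_s: float = 5.0
    analysis_range_s: tuple[float, float] = (-5.0, 45.0)
    snr_threshold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        WavelengthTriple(*self.wavelengths)
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be > 0")
        if self.calibration_method not in ("source_spec", "baseline_assumed_sto2"):
            raise ValidationError(
                f"unknown calibration method '{self.calibration_method}'"
            )
        if self.window_s <= 0:
            raise ValidationError("window_s must be > 0")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("wavelengths", "separations", "analysis_range_s"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        """Short stable hash of the configuration, embedded in artifacts."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
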