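"""Optical constants and two-chromophore absorption algebra.

Conventions used throughout the package (enforced at type boundaries):

* concentrations in µM, distances in cm,
* extinction coefficients in cm⁻¹·µM⁻¹ under the **base-10** (decadic)
  convention, so that attenuation A = −log10(I/I0) = ε·c·L for a single
  chromophore over pathlength L,
* tissue oxygen saturation StO₂ = 100·HbO/(HbO+Hb) in percent.

The shipped default extinction table is the Gratzer/Prahl hemoglobin-spectrum
compilation at 730/800/850 nm; any estimator accepts a user-supplied table.
Ratio-form estimators (SSDS, SRS → StO₂) are invariant to the logarithm base,
because the base cancels between numerator and denominator; the package still
fixes base 10 everywhere for definiteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np

from .errors import SingularSystemError, ValidationError

__all__ = [
    "WavelengthTriple",
    "ExtinctionRow",
    "ExtinctionTable",
    "DPFSet",
    "Geometry",
    "ChromophoreState",
    "default_extinction_table",
    "absorption_from_state",
    "mua_spectrum",
    "solve_two_chromophores",
    "solve_two_chromophores_traces",
]

#: Device wavelengths in nm: λ1 < λ2 < λ3, with λ2 near the isosbestic point.
DEFAULT_WAVELENGTHS_NM = (730.0, 800.0, 850.0)

#: Default adult-forehead differential pathlength factor (dimensionless).
DEFAULT_DPF = 6.0


@dataclass(frozen=True)
class WavelengthTriple:
    """Three operating wavelengths in nm, strictly increasing."""

    lambda1: float = DEFAULT_WAVELENGTHS_NM[0]
    lambda2: float = DEFAULT_WAVELENGTHS_NM[1]
    lambda3: float = DEFAULT_WAVELENGTHS_NM[2]

    def __post_init__(self) -> None:
        if not (0 < self.lambda1 < self.lambda2 < self.lambda3):
            raise ValidationError(
                f"wavelengths must be strictly increasing and positive, got "
                f"({self.lambda1}, {self.lambda2}, {self.lambda3})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3], dtype=float)

    def __iter__(self):
        return iter((self.lambda1, self.lambda2, self.lambda3))


class ExtinctionRow(NamedTuple):
    """Extinction pair (cm⁻¹·µM⁻¹, base-10) at one wavelength."""

    eps_hbo: float
    eps_hb: float


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength decadic extinction coefficients of HbO and Hb.

    Physiological sanity is enforced for tables that cover the device band:
    Hb dominates at 730 nm, HbO at 850 nm, and 800 nm is near-isosbestic.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hbo: tuple[float, ...]
    eps_hb: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        eo = np.asarray(self.eps_hbo, dtype=float)
        eh = np.asarray(self.eps_hb, dtype=float)
        if not (w.size == eo.size == eh.size) or w.size == 0:
            raise ValidationError("extinction table columns must be equal, nonzero length")
        if np.any(eo <= 0) or np.any(eh <= 0):
            raise ValidationError("extinction coefficients must be > 0")
        for nm, pred, msg in (
            (730.0, lambda o, h: h > o, "Hb must dominate at 730 nm"),
            (850.0, lambda o, h: o > h, "HbO must dominate at 850 nm"),
        ):
            if nm in self.wavelengths_nm:
                o, h = self.row(nm)
                if not pred(o, h):
                    raise ValidationError(msg)
        if 800.0 in self.wavelengths_nm:
            o, h = self.row(800.0)
            if abs(o - h) > 0.15 * o:
                raise ValidationError("800 nm row must be near-isosbestic (|εHbO−εHb| ≤ 0.15·εHbO)")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Load a table from CSV with columns wavelength_nm, eps_hbo, eps_hb.

        Lines starting with ``#`` are unit/provenance comments.
        """
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        missing = {"wavelength_nm", "eps_hbo", "eps_hb"} - set(df.columns)
        if missing:
            raise ValidationError(f"extinction CSV missing columns: {sorted(missing)}")
        return cls(
            tuple(df["wavelength_nm"].astype(float)),
            tuple(df["eps_hbo"].astype(float)),
            tuple(df["eps_hb"].astype(float)),
        )

    def row(self, wavelength_nm: float) -> ExtinctionRow:
        """Extinction pair at an exactly tabulated wavelength."""
        w = np.asarray(self.wavelengths_nm, dtype=float)
        idx = np.nonzero(np.isclose(w, float(wavelength_nm)))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength_nm} nm not in extinction table {tuple(w)}")
        i = int(idx[0])
        return ExtinctionRow(self.eps_hbo[i], self.eps_hb[i])

    def matrix(self, wavelengths: Sequence[float] | WavelengthTriple) -> np.ndarray:
        """(n_wavelengths, 2) matrix with columns (ε_HbO, ε_Hb)."""
        return np.array([self.row(w) for w in wavelengths], dtype=float)


def default_extinction_table() -> ExtinctionTable:
    """The packaged Gratzer/Prahl hemoglobin extinction table (730/800/850 nm)."""
    with resources.as_file(
        resources.files("nirsox.data").joinpath("extinction_gratzer.csv")
    ) as p:
        return ExtinctionTable.from_csv(p)


@dataclass(frozen=True)
class DPFSet:
    """Differential pathlength factors per wavelength (dimensionless)."""

    dpf1: float = DEFAULT_DPF
    dpf2: float = DEFAULT_DPF
    dpf3: float = DEFAULT_DPF

    def __post_init__(self) -> None:
        if min(self.dpf1, self.dpf2, self.dpf3) <= 0:
            raise ValidationError("DPF values must be > 0")

    @classmethod
    def equal(cls, value: float = DEFAULT_DPF) -> "DPFSet":
        """Equal-DPF constructor (the wavelength-independence assumption)."""
        return cls(value, value, value)

    def as_array(self) -> np.ndarray:
        return np.array([self.dpf1, self.dpf2, self.dpf3], dtype=float)


@dataclass(frozen=True)
class Geometry:
    """Source–detector separations in cm."""

    separations: tuple[float, ...] = (3.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.separations) == 0 or min(self.separations) <= 0:
            raise ValidationError("separations must be positive")

    def srs_pair(self) -> tuple[float, float]:
        """The (near, far) pair required by SRS: exactly two distinct values."""
        uniq = sorted(set(self.separations))
        if len(uniq) != 2:
            raise ValidationError(
                f"SRS requires exactly two distinct separations, got {self.separations}"
            )
        return uniq[0], uniq[1]


@dataclass(frozen=True)
class ChromophoreState:
    """Oxy/deoxy-hemoglobin concentrations (µM) with derived THb and StO₂."""

    c_hbo: float
    c_hb: float

    @property
    def thb(self) -> float:
        return self.c_hbo + self.c_hb

    @property
    def sto2(self) -> float:
        """Tissue oxygen saturation, 100·HbO/(HbO+Hb), in percent."""
        total = self.c_hbo + self.c_hb
        if total == 0:
            return float("nan")
        return 100.0 * self.c_hbo / total

    @classmethod
    def from_sto2(cls, sto2_pct: float, thb_um: float) -> "ChromophoreState":
        if not 0 <= sto2_pct <= 100:
            raise ValidationError(f"StO2 must lie in [0, 100] %, got {sto2_pct}")
        if thb_um <= 0:
            raise ValidationError(f"THb must be > 0 µM, got {thb_um}")
        return cls(thb_um * sto2_pct / 100.0, thb_um * (1 - sto2_pct / 100.0))


def absorption_from_state(state: ChromophoreState, row: ExtinctionRow) -> float:
    """Decadic absorption coefficient μa = ε_HbO·c_HbO + ε_Hb·c_Hb (cm⁻¹)."""
    if state.c_hbo < 0 or state.c_hb < 0:
        raise ValidationError(
            f"concentrations must be ≥ 0, got ({state.c_hbo}, {state.c_hb}) µM"
        )
    return row.eps_hbo * state.c_hbo + row.eps_hb * state.c_hb


def mua_spectrum(
    state: ChromophoreState,
    table: ExtinctionTable,
    wavelengths: WavelengthTriple | Sequence[float] = WavelengthTriple(),
) -> np.ndarray:
    """Absorption coefficient at each wavelength for one chromophore state."""
    return np.array([absorption_from_state(state, table.row(w)) for w in wavelengths])


#: condition-number ceiling above which the extinction system is rejected
DEFAULT_CONDITION_LIMIT = 1e8


def _extinction_matrix_checked(
    table: ExtinctionTable,
    wavelengths: Sequence[float],
    condition_limit: float,
) -> np.ndarray:
    E = table.matrix(wavelengths)
    if E.shape[0] < 2:
        raise ValidationError("at least two wavelengths are required to separate HbO and Hb")
    if np.linalg.cond(E) > condition_limit:
        raise SingularSystemError(
            f"extinction system condition number {np.linalg.cond(E):.3g} exceeds "
            f"limit {condition_limit:.3g}"
        )
    return E


def solve_two_chromophores(
    mu_a: Sequence[float] | np.ndarray,
    table: ExtinctionTable,
    wavelengths: WavelengthTriple | Sequence[float] = WavelengthTriple(),
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> ChromophoreState:
    """Invert μa = E·(c_HbO, c_Hb) by least squares.

    With exactly two wavelengths this equals the 2×2 closed-form solve; with
    three (the device case) it is the overdetermined least-squares solution.
    """
    mu = np.asarray(mu_a, dtype=float)
    wl = list(wavelengths)
    if mu.ndim != 1 or mu.size != len(wl):
        raise ValidationError(f"mu_a must be a vector of length {len(wl)}")
    E = _extinction_matrix_checked(table, wl, condition_limit)
    c, *_ = np.linalg.lstsq(E, mu, rcond=None)
    return ChromophoreState(float(c[0]), float(c[1]))


def solve_two_chromophores_traces(
    mu_a: np.ndarray,
    table: ExtinctionTable,
    wavelengths: WavelengthTriple | Sequence[float] = WavelengthTriple(),
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized least-squares inversion for a (T, n_wavelengths) μa array.

    Returns (c_hbo, c_hb) arrays of length T.  NaN rows propagate NaN.
    """
    mu = np.asarray(mu_a, dtype=float)
    wl = list(wavelengths)
    if mu.ndim != 2 or mu.shape[1] != len(wl):
        raise ValidationError(f"mu_a must have shape (T, {len(wl)})")
    E = _extinction_matrix_checked(table, wl, condition_limit)
    # normal-equation pseudoinverse is safe here: cond(E) is bounded above
    pinv = np.linalg.pinv(E)
    c = mu @ pinv.T
    return c[:, 0], c[:, 1]
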