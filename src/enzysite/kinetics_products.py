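"""Michaelis-Menten kinetics and PET depolymerization product accounting.

Initial-rate data (v0/[E] vs substrate concentration) are fitted to

    v0/[E] = kcat * [S] / (Km + [S])

by nonlinear least squares, with a Lineweaver-Burk linearisation providing
the starting point.  Catalytic-efficiency fold changes compare kcat/Km
values as given (no re-rounding).  PET conversion bookkeeping counts
aromatic products (BHET + MHET + TPA, one aromatic unit each) against the
theoretical monomer content of the loaded PET mass, using the repeat-unit
molar mass of ethylene terephthalate (192.17 g/mol).  DSC crystallinity is
(dH_m - dH_cc) / dH_m(100%) x 100 with the 100%-crystalline PET reference
enthalpy 140.1 J/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticMeasurement",
    "MMParameters",
    "ProductTimeCourse",
    "CrystallinityInput",
    "fit_michaelis_menten",
    "efficiency_fold",
    "pet_conversion",
    "crystallinity",
    "PET_REPEAT_UNIT_G_MOL",
    "DH_M_100_PET",
]

PET_REPEAT_UNIT_G_MOL = 192.17
DH_M_100_PET = 140.1


@dataclass
class KineticMeasurement:
    """One initial-rate observation: substrate (mM) and v0/[E] (1/s)."""

    substrate_mM: float
    v0_over_E: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.substrate_mM <= 0:
            raise ValueError("substrate concentration must be positive")
        if self.v0_over_E < 0:
            raise ValueError("initial rate must be non-negative")


@dataclass
class MMParameters:
    """Fitted kcat (1/s), Km (mM), their standard errors and kcat/Km."""

    kcat: float
    Km: float
    kcat_over_Km: float
    se_kcat: float = float("nan")
    se_Km: float = float("nan")

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.Km <= 0:
            raise ValueError("kcat and Km must be positive")
        if abs(self.kcat_over_Km - self.kcat / self.Km) > 1e-9 * max(1.0, self.kcat_over_Km):
            raise ValueError("kcat_over_Km must equal kcat / Km")

    @classmethod
    def from_kcat_km(cls, kcat: float, Km: float, se_kcat=float("nan"), se_Km=float("nan")):
        return cls(kcat=kcat, Km=Km, kcat_over_Km=kcat / Km, se_kcat=se_kcat, se_Km=se_Km)


def _mm(s, kcat, km):
    return kcat * s / (km + s)


def fit_michaelis_menten(data: list[KineticMeasurement]) -> MMParameters:
    """Nonlinear least-squares fit of the Michaelis-Menten equation.

    Requires at least three distinct substrate levels.  The starting point
    comes from a Lineweaver-Burk double-reciprocal regression (guarded to
    stay positive); standard errors from the fit covariance.  Replicate
    points enter individually with equal weights.
    """
    s = np.array([d.substrate_mM for d in data], dtype=float)
    v = np.array([d.v0_over_E for d in data], dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")

    # Lineweaver-Burk start: 1/v = (Km/kcat)(1/s) + 1/kcat
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[pos], 1.0 / v[pos], 1)
        kcat0 = 1.0 / intercept if intercept > 0 else float(np.max(v))
        km0 = slope * kcat0 if slope * kcat0 > 0 else float(np.median(s))
    else:
        kcat0, km0 = float(np.max(v) or 1.0), float(np.median(s))
    kcat0 = min(max(kcat0, 1e-6), 1e6)
    km0 = min(max(km0, 1e-6), 1e6)

    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=[kcat0, km0],
            bounds=([1e-9, 1e-9], [1e9, 1e9]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    badly_bracketed = km < float(np.min(s)) / 2 or km > 5 * float(np.max(s))
    if badly_bracketed or (np.isfinite(se[1]) and se[1] > 0.5 * km):
        warnings.warn(
            f"Km ({km:.3g} mM) is weakly identified by the sampled substrate "
            f"range (se {se[1]:.2g}); add points bracketing Km", stacklevel=2,
        )
    return MMParameters.from_kcat_km(kcat, km, se_kcat=float(se[0]), se_Km=float(se[1]))


def efficiency_fold(a, b) -> float:
    """Fold ratio of two catalytic efficiencies (or fitted parameter sets).

    Accepts floats (kcat/Km values as printed) or :class:`MMParameters`;
    values are used as given, without re-rounding.
    """
    va = a.kcat_over_Km if isinstance(a, MMParameters) else float(a)
    vb = b.kcat_over_Km if isinstance(b, MMParameters) else float(b)
    if va <= 0 or vb <= 0:
        raise ValueError("catalytic efficiencies must be positive")
    return va / vb


@dataclass
class ProductTimeCourse:
    """Cumulative released-product concentrations (mM) over time (h)."""

    times_h: np.ndarray
    conc_BHET_mM: np.ndarray
    conc_MHET_mM: np.ndarray
    conc_TPA_mM: np.ndarray
    pet_mass_g: float
    volume_L: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        for name in ("conc_BHET_mM", "conc_MHET_mM", "conc_TPA_mM"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times_h.shape:
                raise ValueError(f"{name} must match times_h in length")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative concentrations")
            setattr(self, name, arr)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pet_mass_g <= 0 or self.volume_L <= 0:
            raise ValueError("PET mass and volume must be positive")

    @classmethod
    def from_csv(cls, path, pet_mass_g: float, volume_L: float):
        df = pd.read_csv(path)
        return cls(
            times_h=df["time_h"].to_numpy(),
            conc_BHET_mM=df["BHET_mM"].to_numpy(),
            conc_MHET_mM=df["MHET_mM"].to_numpy(),
            conc_TPA_mM=df["TPA_mM"].to_numpy(),
            pet_mass_g=pet_mass_g,
            volume_L=volume_L,
        )


def pet_conversion(
    tc: ProductTimeCourse,
    repeat_unit_g_mol: float = PET_REPEAT_UNIT_G_MOL,
) -> pd.DataFrame:
    """Per-timepoint conversion, TPA yield and product composition.

    Conversion% counts every aromatic product (BHET, MHET, TPA - one
    aromatic unit each) against the theoretical monomer amount
    pet_mass / repeat_unit; TPA yield% counts TPA alone; composition% is
    each species' share of the summed products (absent, not zero, where no
    product has been released).
    """
    theoretical_mol = tc.pet_mass_g / repeat_unit_g_mol
    to_mol = tc.volume_L / 1000.0  # mM -> mol
    bhet = tc.conc_BHET_mM * to_mol
    mhet = tc.conc_MHET_mM * to_mol
    tpa = tc.conc_TPA_mM * to_mol
    total = bhet + mhet + tpa

    with np.errstate(invalid="ignore", divide="ignore"):
        comp_b = np.where(total > 0, bhet / total * 100.0, np.nan)
        comp_m = np.where(total > 0, mhet / total * 100.0, np.nan)
        comp_t = np.where(total > 0, tpa / total * 100.0, np.nan)
    return pd.DataFrame(
        {
            "time_h": tc.times_h,
            "conversion_pct": total / theoretical_mol * 100.0,
            "tpa_yield_pct": tpa / theoretical_mol * 100.0,
            "composition_BHET_pct": comp_b,
            "composition_MHET_pct": comp_m,
            "composition_TPA_pct": comp_t,
        }
    )


@dataclass
class CrystallinityInput:
    """DSC enthalpies (J/g): melting, cold crystallization, 100% reference."""

    dH_m: float
    dH_cc: float
    dH_m_100: float = DH_M_100_PET

    def __post_init__(self) -> None:
        for name in ("dH_m", "dH_cc", "dH_m_100"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.dH_m_100 <= 0:
            raise ValueError("reference melting enthalpy must be positive")


def crystallinity(x: CrystallinityInput) -> float:
    """Percent crystallinity: (dH_m - dH_cc) / dH_m(100%) x 100."""
    value = (x.dH_m - x.dH_cc) / x.dH_m_100 * 100.0
    if value < 0:
        warnings.warn(
            "cold-crystallization enthalpy exceeds melting enthalpy; "
            "negative crystallinity reported", stacklevel=2,
        )
    return value
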