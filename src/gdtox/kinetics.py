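"""Enzyme kinetics fits: Michaelis-Menten, 4PL inhibition (IC50), ligand KD.

Quantifies how added proteins modulate a partner enzyme's catalytic
parameters: kcat/KM shifts of PurH transformylase activity under increasing
DHFR, the fold-excess of DHFR needed to half-inhibit GlyA ternary-complex
formation, and apparent ligand dissociation constants from saturation
absorbance curves.  Modulation is reported relative to the enzyme alone; the
module quantifies but never mechanistically models these effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "RateDataset",
    "MMFit",
    "InhibitionCurve",
    "FourPLFit",
    "SaturationFit",
    "fit_michaelis_menten",
    "modulation_profile",
    "fit_ic50",
    "fit_saturation_kd",
]


@dataclass(frozen=True)
class RateDataset:
    """Initial-rate measurements at varying substrate for one enzyme/modulator mix.

    Duplicate substrate concentrations are allowed and treated as replicates.
    """

    substrate_conc: np.ndarray  # mol/L
    initial_rate: np.ndarray  # signal units/s or mol/L/s
    enzyme_conc: float  # mol/L
    modulator_name: str | None = None
    modulator_conc: float = 0.0  # mol/L

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate_conc", np.asarray(self.substrate_conc, float))
        object.__setattr__(self, "initial_rate", np.asarray(self.initial_rate, float))
        if self.substrate_conc.size != self.initial_rate.size:
            raise ValueError("substrate and rate lists must have equal length")
        if np.any(self.substrate_conc < 0) or np.any(self.initial_rate < 0):
            raise ValueError("concentrations and rates must be >= 0")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")


@dataclass(frozen=True)
class MMFit:
    vmax: float
    km: float  # mol/L
    kcat: float  # s^-1 (vmax / enzyme_conc, meaningful when rates are mol/L/s)
    efficiency: float  # kcat / km, M^-1 s^-1
    standard_errors: dict[str, float] = field(default_factory=dict)
    degenerate_span: bool = False  # substrate grid did not straddle KM

    def predict(self, s: "float | np.ndarray") -> np.ndarray:
        s = np.asarray(s, float)
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class InhibitionCurve:
    """Normalized activity versus modulator:enzyme fold excess."""

    fold_excess: np.ndarray
    normalized_signal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_excess", np.asarray(self.fold_excess, float))
        object.__setattr__(
            self, "normalized_signal", np.asarray(self.normalized_signal, float)
        )
        if self.fold_excess.size != self.normalized_signal.size:
            raise ValueError("fold_excess and signal must have equal length")
        if np.any(self.fold_excess < 0):
            raise ValueError("fold_excess must be >= 0")


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    ic50: float  # fold excess producing the half-way signal
    hill: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    def predict(self, x: "float | np.ndarray") -> np.ndarray:
        return _four_pl(np.asarray(x, float), self.bottom, self.top, self.ic50, self.hill)


@dataclass(frozen=True)
class SaturationFit:
    amax: float
    kd_ligand: float  # mol/L
    standard_errors: dict[str, float] = field(default_factory=dict)

    def predict(self, conc: "float | np.ndarray") -> np.ndarray:
        conc = np.asarray(conc, float)
        return self.amax * conc / (conc + self.kd_ligand)


def fit_michaelis_menten(data: RateDataset) -> MMFit:
    """Fit ``v = Vmax S / (KM + S)`` and derive kcat = Vmax / [E].

    The substrate grid should span both sides of KM; when it does not, the
    fit is still returned with ``degenerate_span`` set.
    """
    s, v = data.substrate_conc, data.initial_rate
    if np.unique(s).size < 4:
        warnings.warn("fewer than 4 distinct substrate concentrations")
    if not np.any(v > 0):
        raise ValueError("all rates are zero; nothing to fit")

    def mm(x, log_vmax, log_km):
        return np.exp(log_vmax) * x / (np.exp(log_km) + x)

    vmax0 = float(np.max(v))
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))]) or float(np.median(s[s > 0]))
    popt, pcov = curve_fit(mm, s, v, p0=[np.log(vmax0), np.log(km0)], maxfev=10000)
    vmax, km = float(np.exp(popt[0])), float(np.exp(popt[1]))
    perr = np.sqrt(np.diag(pcov))
    kcat = vmax / data.enzyme_conc
    degenerate = not (s.min() < km < s.max())
    se_vmax, se_km = vmax * float(perr[0]), km * float(perr[1])
    se_kcat = se_vmax / data.enzyme_conc
    eff = kcat / km
    se_eff = eff * float(np.hypot(perr[0], perr[1]))
    return MMFit(
        vmax=vmax,
        km=km,
        kcat=kcat,
        efficiency=eff,
        standard_errors={"vmax": se_vmax, "km": se_km, "kcat": se_kcat, "efficiency": se_eff},
        degenerate_span=degenerate,
    )


def modulation_profile(
    fits: "dict[float, MMFit] | Sequence[tuple[float, MMFit]]", reference: MMFit
) -> pd.DataFrame:
    """Normalize kcat, KM and kcat/KM of each fit by a no-modulator reference.

    ``fits`` maps modulator concentration (mol/L) to the MMFit obtained at
    that concentration.  Ratio standard errors are propagated assuming
    independent fits (first-order delta method).
    """
    items = sorted(dict(fits).items()) if not isinstance(fits, dict) else sorted(fits.items())
    rows = []
    for conc, f in items:
        row = {"modulator_conc": conc}
        for name in ("kcat", "km", "efficiency"):
            a, b = getattr(f, name), getattr(reference, name)
            ratio = a / b
            sa = f.standard_errors.get(name, 0.0)
            sb = reference.standard_errors.get(name, 0.0)
            row[f"{name}_ratio"] = ratio
            row[f"{name}_ratio_se"] = abs(ratio) * float(
                np.hypot(sa / a if a else 0.0, sb / b if b else 0.0)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _four_pl(x: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(curve: InhibitionCurve) -> FourPLFit:
    """Fit the 4-parameter logistic ``y = bottom + (top-bottom)/(1+(x/ic50)^hill)``.

    The Hill slope is free within (0, 10].  At ``x = ic50`` the fitted curve
    passes exactly through the midpoint ``(top + bottom) / 2``.
    """
    x, y = curve.fold_excess, curve.normalized_signal
    if x.size < 5:
        raise ValueError("need >= 5 points for a 4-parameter fit")
    span = float(np.max(y) - np.min(y))
    if span < 0.3 * max(abs(float(np.max(y))), 1e-12):
        warnings.warn("signal spans < 30% of its range; IC50 poorly constrained")

    top0, bot0 = float(np.max(y)), float(np.min(y))
    mid = (top0 + bot0) / 2.0
    pos = x[x > 0]
    ic0 = float(pos[np.argmin(np.abs(y[x > 0] - mid))]) if pos.size else 1.0
    popt, pcov = curve_fit(
        _four_pl,
        x,
        y,
        p0=[bot0, top0, ic0, 1.0],
        bounds=([-np.inf, -np.inf, 1e-12, 1e-6], [np.inf, np.inf, np.inf, 10.0]),
        maxfev=20000,
    )
    bottom, top, ic50, hill = (float(p) for p in popt)
    if top < bottom:  # reparameterize to the canonical orientation
        bottom, top, hill = top, bottom, -hill
    perr = np.sqrt(np.diag(pcov))
    return FourPLFit(
        bottom=bottom,
        top=top,
        ic50=ic50,
        hill=hill,
        standard_errors=dict(zip(("bottom", "top", "ic50", "hill"), map(float, perr))),
    )


def fit_saturation_kd(
    ligand_conc: Sequence[float], signal: Sequence[float]
) -> SaturationFit:
    """Fit ``A = Amax L / (KD + L)`` to a ligand-saturation absorbance series."""
    L = np.asarray(ligand_conc, float)
    A = np.asarray(signal, float)
    if np.unique(L).size < 3:
        raise ValueError("need >= 3 distinct ligand concentrations")
    if not np.any(A > 0):
        raise ValueError("all signals are <= 0; nothing to fit")

    def hyper(x, log_amax, log_kd):
        return np.exp(log_amax) * x / (np.exp(log_kd) + x)

    amax0 = float(np.max(A))
    kd0 = float(L[np.argmin(np.abs(A - amax0 / 2.0))]) or float(np.median(L[L > 0]))
    popt, pcov = curve_fit(hyper, L, A, p0=[np.log(amax0), np.log(kd0)], maxfev=10000)
    amax, kd = float(np.exp(popt[0])), float(np.exp(popt[1]))
    perr = np.sqrt(np.diag(pcov))
    return SaturationFit(
        amax=amax,
        kd_ligand=kd,
        standard_errors={"amax": amax * float(perr[0]), "kd": kd * float(perr[1])},
    )
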