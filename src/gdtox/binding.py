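"""SPR binding analysis: reference subtraction, equilibrium isotherms, off-rates.

Sensorgrams record response units (RU) versus time for an analyte flown over
an immobilised ligand.  After subtracting the negative-control flow cell, the
response read out at a fixed time after injection (100 s by convention here)
is fitted against analyte concentration with the 1:1 Langmuir isotherm
``RU = Rmax * c / (c + KD)``; dissociation tails are fitted globally with a
single shared off-rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "Sensorgram",
    "BindingIsotherm",
    "IsothermFit",
    "DissociationFit",
    "subtract_reference",
    "extract_readout",
    "fit_isotherm",
    "fit_dissociation",
]


@dataclass(frozen=True)
class Sensorgram:
    """Response-vs-time trace at a single analyte concentration."""

    analyte_conc: float  # mol/L
    time: np.ndarray  # seconds, strictly increasing
    response: np.ndarray  # RU

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.time.size < 2 or self.time.size != self.response.size:
            raise ValueError("need >= 2 (time, response) points of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class BindingIsotherm:
    """Equilibrium readout (RU) versus analyte concentration (mol/L)."""

    conc: np.ndarray
    response_at_readout: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        object.__setattr__(
            self, "response_at_readout", np.asarray(self.response_at_readout, dtype=float)
        )
        if self.conc.size != self.response_at_readout.size:
            raise ValueError("conc and response must have equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class IsothermFit:
    rmax: float  # RU
    kd: float  # mol/L
    residual_sum_sq: float  # RU^2
    standard_errors: dict[str, float]

    def predict(self, conc: "float | np.ndarray") -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.rmax * conc / (conc + self.kd)


@dataclass(frozen=True)
class DissociationFit:
    kd_off: float  # s^-1
    r0: tuple[float, ...]  # per-curve initial response, RU
    residual_sum_sq: float


def subtract_reference(sample: Sensorgram, control: Sensorgram) -> Sensorgram:
    """Subtract the negative-control flow cell from a sample sensorgram.

    The control is interpolated onto the sample's time grid; the grids must
    overlap over the whole sample range.
    """
    t0, t1 = sample.time[0], sample.time[-1]
    if control.time[0] > t0 + 1e-9 or control.time[-1] < t1 - 1e-9:
        raise ValueError("control does not cover the sample time range")
    ctrl = np.interp(sample.time, control.time, control.response)
    return Sensorgram(sample.analyte_conc, sample.time, sample.response - ctrl)


def extract_readout(gram: Sensorgram, readout_time: float = 100.0) -> float:
    """Response at the time point nearest ``readout_time`` (seconds)."""
    idx = int(np.argmin(np.abs(gram.time - readout_time)))
    return float(gram.response[idx])


def _langmuir(c: np.ndarray, log_rmax: float, log_kd: float) -> np.ndarray:
    rmax, kd = np.exp(log_rmax), np.exp(log_kd)
    return rmax * c / (c + kd)


def fit_isotherm(iso: BindingIsotherm, weights: Sequence[float] | None = None) -> IsothermFit:
    """Fit ``RU = Rmax c / (c + KD)`` by nonlinear least squares.

    Parameters are log-transformed internally so Rmax and KD stay positive;
    reported standard errors are back-transformed by the delta method.
    Initial values: Rmax = max response, KD = concentration nearest half-max.
    The objective is unweighted unless per-point ``weights`` (1/sigma) are given.
    """
    c, r = iso.conc, iso.response_at_readout
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if not np.any(r > 0):
        raise ValueError("all responses are <= 0; nothing to fit")

    rmax0 = float(np.max(r))
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2.0))])
    kd0 = kd0 if kd0 > 0 else float(np.median(c[c > 0]))
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    popt, pcov = curve_fit(
        _langmuir, c, r, p0=[np.log(rmax0), np.log(kd0)], sigma=sigma, maxfev=10000
    )
    rmax, kd = float(np.exp(popt[0])), float(np.exp(popt[1]))
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((r - _langmuir(c, *popt)) ** 2))
    return IsothermFit(
        rmax=rmax,
        kd=kd,
        residual_sum_sq=rss,
        standard_errors={"rmax": rmax * float(perr[0]), "kd": kd * float(perr[1])},
    )


def fit_dissociation(tails: "Sensorgram | Sequence[Sensorgram]") -> DissociationFit:
    """Globally fit single-exponential decay ``R(t) = R0 exp(-kd_off t)``.

    One shared off-rate across all supplied dissociation tails, one free R0
    per tail.  Time is re-zeroed at each tail's first point.  A flat tail
    yields ``kd_off = 0``.
    """
    if isinstance(tails, Sensorgram):
        tails = [tails]
    tails = list(tails)
    if any(t.time.size < 3 for t in tails):
        raise ValueError("each dissociation tail needs >= 3 time points")

    times = [t.time - t.time[0] for t in tails]
    resps = [t.response for t in tails]
    r0_init = [max(float(r[0]), 1e-12) for r in resps]
    # crude slope-based off-rate initial value
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = 0.0
        for t, r in zip(times, resps):
            pos = r > 0
            if pos.sum() >= 2:
                slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
                k0 = max(k0, -float(slope))
    k0 = max(k0, 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        k, r0s = theta[0], theta[1:]
        return np.concatenate(
            [r0 * np.exp(-k * t) - r for r0, t, r in zip(r0s, times, resps)]
        )

    res = least_squares(
        residuals,
        x0=np.array([k0] + r0_init),
        bounds=(np.zeros(1 + len(tails)), np.inf),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        warnings.warn("global dissociation fit did not report convergence")
    return DissociationFit(
        kd_off=float(res.x[0]),
        r0=tuple(float(v) for v in res.x[1:]),
        residual_sum_sq=float(np.sum(res.fun**2)),
    )
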