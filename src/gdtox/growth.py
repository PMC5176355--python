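"""Growth-rate extraction and abundance-fitness analysis.

OD600 time series are fitted with the modified Gompertz model (on the
log-relative scale ``y = ln(OD/OD0)``)::

    y(t) = A * exp(-exp(mu_max * e / A * (lag - t) + 1))

yielding the maximal specific growth rate ``mu_max`` (h^-1), lag time
(h) and amplitude ``A``.  Fitness (growth rate relative to a stated
reference culture) is then modelled as a function of relative protein
abundance: a saturating Michaelis-Menten-like branch for depletion and a
decreasing four-parameter logistic on the log10 abundance axis for
overexpression.  Ortholog fitness is compared to the overexpression curve
with an unpaired t-test, and co-expression rescue is summarized by an
interaction-corrected rescue factor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "FitnessPoint",
    "DepletionFit",
    "SigmoidFitnessFit",
    "RescueMeasurement",
    "fit_growth_curve",
    "relative_growth",
    "fit_depletion_branch",
    "fit_overexpression_branch",
    "ortholog_significance",
    "rescue_factor",
    "rank_correlation",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series; time in minutes."""

    time: np.ndarray  # minutes, monotone increasing
    od600: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "od600", np.asarray(self.od600, float))
        if self.time.size != self.od600.size:
            raise ValueError("time and od600 must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 must be >= 0")
        if self.time.size < 10 or (self.time[-1] - self.time[0]) < 120:
            warnings.warn("growth fits expect >= 10 points spanning >= 2 h")


@dataclass(frozen=True)
class GrowthParams:
    mu_max: float  # h^-1
    lag: float  # h
    amplitude: float  # ln(OD/OD0) units
    fit_rss: float
    flat: bool = False  # no measurable growth


@dataclass(frozen=True)
class FitnessPoint:
    """Relative abundance (fold over wild-type basal) vs normalized growth."""

    rel_abundance: float
    rel_growth: float
    sd: float = 0.03

    def __post_init__(self) -> None:
        if self.rel_abundance <= 0:
            raise ValueError("rel_abundance must be > 0")
        if self.rel_growth < 0:
            raise ValueError("rel_growth must be >= 0")


@dataclass(frozen=True)
class DepletionFit:
    """Saturating fitness-vs-abundance fit f(a) = F_max a / (a + K_f)."""

    f_max: float
    k_f: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    def predict(self, abundance: "float | np.ndarray") -> np.ndarray:
        a = np.asarray(abundance, float)
        return self.f_max * a / (a + self.k_f)


@dataclass(frozen=True)
class SigmoidFitnessFit:
    """Decreasing 4PL in log10 abundance:
    f(a) = bottom + (top - bottom) / (1 + 10^(hill (log10 a - log10_mid)))."""

    bottom: float
    top: float
    log10_mid: float
    hill: float
    abundance_range: tuple[float, float] = (0.0, math.inf)

    def predict(self, abundance: "float | np.ndarray") -> np.ndarray:
        la = np.log10(np.asarray(abundance, float))
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill * (la - self.log10_mid))
        )


@dataclass(frozen=True)
class RescueMeasurement:
    """Growth rates (h^-1) of the four strains in a dual-expression rescue assay."""

    mu_dhfr_x: float  # hub + candidate rescuer X
    mu_dhfr_empty: float  # hub + empty plasmid
    mu_x: float  # X alone
    mu_empty: float  # both plasmids empty


def _gompertz(t_h: np.ndarray, amplitude: float, mu: float, lag: float) -> np.ndarray:
    return amplitude * np.exp(-np.exp(mu * math.e / amplitude * (lag - t_h) + 1.0))


def fit_growth_curve(curve: GrowthCurve, blank: float | None = None) -> GrowthParams:
    """Fit the modified Gompertz model to a growth curve.

    ``blank`` (medium background OD) is subtracted if given; the fit then
    runs on ``y = ln(OD)`` with the inoculum level ``ln(OD0)`` estimated as
    a nuisance baseline (the model value need not be zero at the first
    sample, so anchoring on the first point would bias mu at slow growth).
    A flat series returns ``mu_max = 0`` with a warning rather than failing.
    """
    od = curve.od600 - (blank or 0.0)
    floor = max(np.min(od[od > 0], initial=1e-6) * 0.5, 1e-9)
    od = np.maximum(od, floor)
    y = np.log(od)
    t_h = (curve.time - curve.time[0]) / 60.0

    if float(np.ptp(y)) < 0.05:  # < 5% total change: no measurable growth
        warnings.warn(f"flat growth curve {curve.label!r}; mu_max set to 0")
        return GrowthParams(
            0.0, 0.0, max(float(np.ptp(y)), 1e-12), float(np.sum((y - y.mean()) ** 2)), flat=True
        )

    def model(t, amplitude, mu, lag, y0):
        return y0 + _gompertz(t, amplitude, mu, lag)

    a0 = float(np.ptp(y))
    dy = np.gradient(y, t_h)
    mu0 = max(float(np.max(dy)), 1e-3)
    lag0 = max(float(t_h[np.argmax(dy)]) - a0 / (2 * mu0), 0.0)
    popt, _ = curve_fit(
        model,
        t_h,
        y,
        p0=[a0, mu0, lag0, float(y[0])],
        bounds=([1e-9, 0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    rss = float(np.sum((y - model(t_h, *popt)) ** 2))
    return GrowthParams(
        mu_max=float(popt[1]), lag=float(popt[2]), amplitude=float(popt[0]), fit_rss=rss
    )


def relative_growth(mu: float, mu_ref: float) -> float:
    """Growth rate normalized by a reference culture's rate."""
    if mu_ref <= 0:
        raise ValueError("reference growth rate must be > 0")
    return mu / mu_ref


def _points_to_arrays(points: Sequence[FitnessPoint]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([p.rel_abundance for p in points])
    g = np.array([p.rel_growth for p in points])
    return a, g


def fit_depletion_branch(points: Sequence[FitnessPoint]) -> DepletionFit:
    """Fit the saturating (Michaelis-Menten-like) depletion branch."""
    if len(points) < 4:
        raise ValueError("need >= 4 points")
    a, g = _points_to_arrays(points)

    def f(x, log_fmax, log_kf):
        return np.exp(log_fmax) * x / (x + np.exp(log_kf))

    fmax0 = float(np.max(g))
    kf0 = float(a[np.argmin(np.abs(g - fmax0 / 2.0))]) or float(np.median(a))
    popt, pcov = curve_fit(f, a, g, p0=[np.log(fmax0), np.log(kf0)], maxfev=10000)
    fmax, kf = float(np.exp(popt[0])), float(np.exp(popt[1]))
    perr = np.sqrt(np.diag(pcov))
    return DepletionFit(
        f_max=fmax,
        k_f=kf,
        standard_errors={"f_max": fmax * float(perr[0]), "k_f": kf * float(perr[1])},
    )


def fit_overexpression_branch(points: Sequence[FitnessPoint]) -> SigmoidFitnessFit:
    """Fit the decreasing 4PL fitness curve on the log10 abundance axis."""
    if len(points) < 5:
        raise ValueError("need >= 5 points")
    a, g = _points_to_arrays(points)
    if stats.spearmanr(a, g).statistic > 0:
        warnings.warn("overexpression branch trends upward; check inputs")
    la = np.log10(a)

    def f(x, bottom, top, mid, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - mid)))

    bot0, top0 = float(np.min(g)), float(np.max(g))
    mid0 = float(la[np.argmin(np.abs(g - (bot0 + top0) / 2.0))])
    popt, _ = curve_fit(
        f,
        la,
        g,
        p0=[bot0, top0, mid0, 1.0],
        bounds=([-np.inf, -np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf, 50.0]),
        maxfev=20000,
    )
    return SigmoidFitnessFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log10_mid=float(popt[2]),
        hill=float(popt[3]),
        abundance_range=(float(np.min(a)), float(np.max(a))),
    )


def ortholog_significance(
    fit: SigmoidFitnessFit,
    ortholog_abundance: float,
    ortholog_growth_reps: Sequence[float],
    rel_sd: float = 0.03,
    n_expected: int = 3,
    rng: "np.random.Generator | int | None" = 0,
) -> float:
    """Two-sided p-value for an ortholog's fitness differing from the fitted curve.

    The expected growth at the ortholog's abundance is read off the fitted
    overexpression curve and assigned a relative standard deviation
    (``rel_sd``, default 3%).  ``n_expected`` pseudo-replicates are drawn
    from that expectation and compared to the observed replicates with an
    unpaired two-sample t-test (pooled variance), which is exactly
    calibrated when the observed replicates follow the same null.
    """
    reps = np.asarray(list(ortholog_growth_reps), float)
    if reps.size < 3:
        raise ValueError("need >= 3 ortholog replicates")
    lo, hi = fit.abundance_range
    if not (lo <= ortholog_abundance <= hi):
        warnings.warn("ortholog abundance outside fitted range; extrapolating")
    predicted = float(fit.predict(ortholog_abundance))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    expected = rng.normal(predicted, rel_sd * abs(predicted), size=n_expected)
    res = stats.ttest_ind(reps, expected, equal_var=True)
    return float(res.pvalue)


def rescue_factor(m: RescueMeasurement) -> float:
    """Interaction-corrected growth gain from co-expressing X with the hub:
    (mu(hub+X) - mu(hub+empty)) - (mu(X) - mu(empty))."""
    return (m.mu_dhfr_x - m.mu_dhfr_empty) - (m.mu_x - m.mu_empty)


def rank_correlation(
    points: "Sequence[FitnessPoint] | tuple[Sequence[float], Sequence[float]]",
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation of abundance vs growth with exact small-n p.

    For n <= ``exact_max_n`` the p-value is computed by full enumeration of
    rank permutations (two-sided: fraction of permutations with
    ``|rho| >= |rho_obs|``; 'less'/'greater' are the one-sided analogues).
    Larger n falls back to the t-approximation.  Ties get average ranks; a
    constant vector yields rho = 0 with a warning.
    """
    if isinstance(points, tuple):
        x = np.asarray(points[0], float)
        y = np.asarray(points[1], float)
    else:
        x, y = _points_to_arrays(points)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman rho undefined, returning 0")
        return 0.0, 1.0

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n > exact_max_n:
        res = stats.spearmanr(x, y, alternative=alternative)
        return rho, float(res.pvalue)

    rx_c = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry_c = ry - ry.mean()
    ry_c = ry_c / np.sqrt(np.sum(ry_c**2))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx_c[perms] * ry_c).sum(axis=1)
    eps = 1e-12
    if alternative == "two-sided":
        p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
    elif alternative == "less":
        p = float(np.mean(rhos <= rho + eps))
    elif alternative == "greater":
        p = float(np.mean(rhos >= rho - eps))
    else:
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    return rho, p
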