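"""Mass-action sequestration equilibria for a hub protein and its weak partners.

A hub enzyme (e.g. DHFR in *E. coli*) binds each of its partner enzymes
(PurH, GlyA, ...) in independent 1:1 complexes governed by per-pair
dissociation constants.  At basal abundance the complexes are transient;
when the hub is overexpressed far above its partners' concentrations the
partners become almost fully sequestered.  This module solves the coupled
conservation/mass-action equations exactly (closed form for one partner,
bisection for several) and exposes titration scans over hub overexpression
fold, plus copies-per-cell <-> molar conversion.

Concentrations are held in mol/L throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_CELL_VOLUME_L",
    "Species",
    "BindingPair",
    "EquilibriumSystem",
    "EquilibriumState",
    "solve_pairwise",
    "solve_competitive",
    "titration_scan",
    "copies_to_molar",
    "molar_to_copies",
    "percent",
]

#: Cytoplasmic volume (litres) for which 50 copies/cell corresponds to 5e-8 M.
DEFAULT_CELL_VOLUME_L = 1.66e-15


@dataclass(frozen=True)
class Species:
    """A protein species with a total (free + complexed) concentration."""

    name: str
    total_conc: float  # mol/L

    def __post_init__(self) -> None:
        if self.total_conc < 0:
            raise ValueError(f"total_conc of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class BindingPair:
    """A 1:1 hub-partner interaction with dissociation constant ``kd`` (mol/L)."""

    hub: str
    partner: str
    kd: float  # mol/L

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.hub == self.partner:
            raise ValueError("hub and partner must differ")


@dataclass(frozen=True)
class EquilibriumSystem:
    """One hub plus N partners, each bound through exactly one 1:1 pair.

    Partners are assumed independent: they do not compete for a shared hub
    surface and do not bind each other.
    """

    hub: Species
    partners: tuple[Species, ...]
    pairs: tuple[BindingPair, ...]

    def __post_init__(self) -> None:
        names = [self.hub.name] + [p.name for p in self.partners]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        by_partner = {q.partner: q for q in self.pairs}
        if set(by_partner) != {p.name for p in self.partners} or len(self.pairs) != len(
            self.partners
        ):
            raise ValueError("each partner needs exactly one pair with the hub")
        for q in self.pairs:
            if q.hub != self.hub.name:
                raise ValueError(f"pair {q} does not involve the hub")

    @classmethod
    def from_totals(
        cls,
        hub_name: str,
        hub_total: float,
        partner_totals: dict[str, float],
        kds: dict[str, float],
    ) -> "EquilibriumSystem":
        partners = tuple(Species(n, c) for n, c in partner_totals.items())
        pairs = tuple(BindingPair(hub_name, n, kds[n]) for n in partner_totals)
        return cls(Species(hub_name, hub_total), partners, pairs)


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium: free and complexed concentrations, bound fractions."""

    free_conc: dict[str, float]  # species name -> mol/L
    complex_conc: dict[tuple[str, str], float]  # (hub, partner) -> mol/L
    fraction_bound: dict[str, float]  # species name -> [0, 1]

    def fraction_free(self, name: str) -> float:
        return 1.0 - self.fraction_bound[name]


def _bound_fraction(total: float, complexed: float) -> float:
    return complexed / total if total > 0 else 0.0


def solve_pairwise(hub_total: float, partner_total: float, kd: float) -> EquilibriumState:
    """Solve the two-species 1:1 equilibrium in closed form.

    The conservation relations for hub total ``D``, partner total ``P`` and
    dissociation constant ``K`` give a quadratic in the complex concentration
    ``c``; the root lying in ``[0, min(D, P)]`` is::

        c = ((D + P + K) - sqrt((D + P + K)^2 - 4 D P)) / 2

    evaluated here in the cancellation-safe form ``2DP / (s + sqrt(s^2 - 4DP))``
    with ``s = D + P + K``, which stays accurate when ``4DP << s^2`` (weak,
    trace-level binding — the regime of interest).
    """
    if hub_total < 0 or partner_total < 0:
        raise ValueError("concentrations must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")

    hub, partner = "hub", "partner"
    if hub_total == 0 or partner_total == 0:
        c = 0.0
    else:
        s = hub_total + partner_total + kd
        disc = s * s - 4.0 * hub_total * partner_total
        # disc > 0 always for kd > 0; clamp defensively against roundoff
        c = 2.0 * hub_total * partner_total / (s + math.sqrt(max(disc, 0.0)))
    free_hub = hub_total - c
    free_partner = partner_total - c
    return EquilibriumState(
        free_conc={hub: free_hub, partner: free_partner},
        complex_conc={(hub, partner): c},
        fraction_bound={
            hub: _bound_fraction(hub_total, c),
            partner: _bound_fraction(partner_total, c),
        },
    )


def solve_competitive(
    system: EquilibriumSystem, rtol: float = 1e-12, maxiter: int = 200
) -> EquilibriumState:
    """Solve one hub against N independent partners by bisection on free hub.

    With free hub concentration ``h``, each partner ``i`` (total ``P_i``,
    constant ``K_i``) contributes complex ``h * P_i / (K_i + h)``, so ``h``
    solves::

        h + sum_i h * P_i / (K_i + h) = H_T

    The left side is strictly increasing in ``h``, so the root in
    ``[0, H_T]`` is unique; it is located with Brent's method to relative
    tolerance ``rtol``.  Partner frees follow as ``P_i * K_i / (K_i + h)``.
    """
    hub = system.hub
    kds = {q.partner: q.kd for q in system.pairs}
    if not system.partners or hub.total_conc == 0:
        free = {hub.name: hub.total_conc}
        free.update({p.name: p.total_conc for p in system.partners})
        return EquilibriumState(
            free_conc=free,
            complex_conc={(hub.name, p.name): 0.0 for p in system.partners},
            fraction_bound={n: 0.0 for n in free},
        )

    totals = np.array([p.total_conc for p in system.partners])
    ks = np.array([kds[p.name] for p in system.partners])

    def excess(h: float) -> float:
        return h + float(np.sum(h * totals / (ks + h))) - hub.total_conc

    h_hi = hub.total_conc
    if excess(h_hi) <= 0:  # partners bind nothing (all totals zero)
        h = h_hi
    else:
        h = brentq(
            excess,
            0.0,
            h_hi,
            xtol=hub.total_conc * 1e-16,  # absolute floor well below any root
            rtol=max(rtol, 4 * np.finfo(float).eps),
            maxiter=maxiter,
        )

    complexes = h * totals / (ks + h)
    free = {hub.name: h}
    cc: dict[tuple[str, str], float] = {}
    fb = {hub.name: _bound_fraction(hub.total_conc, float(complexes.sum()))}
    for p, c in zip(system.partners, complexes):
        free[p.name] = p.total_conc - float(c)
        cc[(hub.name, p.name)] = float(c)
        fb[p.name] = _bound_fraction(p.total_conc, float(c))
    return EquilibriumState(free_conc=free, complex_conc=cc, fraction_bound=fb)


def titration_scan(
    system: EquilibriumSystem, fold_factors: "list[float] | np.ndarray"
) -> pd.DataFrame:
    """Scale the hub total by each fold factor (partners fixed) and re-solve.

    Returns a tidy table with one row per fold factor and, for each species,
    columns ``free_<name>`` (mol/L) and ``fbound_<name>`` (dimensionless).
    Partner bound fractions are monotone nondecreasing in fold.
    """
    fold_factors = np.asarray(list(fold_factors), dtype=float)
    if np.any(fold_factors <= 0):
        raise ValueError("fold factors must be > 0")
    rows = []
    for f in fold_factors:
        scaled = EquilibriumSystem(
            Species(system.hub.name, system.hub.total_conc * f),
            system.partners,
            system.pairs,
        )
        st = solve_competitive(scaled)
        row: dict[str, float] = {"fold": f}
        for name in [system.hub.name] + [p.name for p in system.partners]:
            row[f"free_{name}"] = st.free_conc[name]
            row[f"fbound_{name}"] = st.fraction_bound[name]
        rows.append(row)
    return pd.DataFrame(rows)


def copies_to_molar(copies: float, cell_volume: float = DEFAULT_CELL_VOLUME_L) -> float:
    """Convert molecules per cell to mol/L for a given cell volume (litres)."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    return copies / (Avogadro * cell_volume)


def molar_to_copies(conc: float, cell_volume: float = DEFAULT_CELL_VOLUME_L) -> float:
    """Inverse of :func:`copies_to_molar`."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    return conc * Avogadro * cell_volume


def percent(fraction: float, ndigits: int = 0) -> float:
    """Fraction -> percentage, rounded half-up (2.5% -> 3%), mirroring how
    such numbers are conventionally printed.  Unrounded values remain
    available from the states themselves."""
    scaled = fraction * 100.0 * 10**ndigits
    return math.floor(scaled + 0.5) / 10**ndigits
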