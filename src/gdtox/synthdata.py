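"""Seeded synthetic-data generators with recorded ground truth.

Every input the analysis stages consume can be generated here with known
parameters, so each fitting/calling stage is testable end to end without any
external download.  Noise models: multiplicative Gaussian for continuous
signals (SPR responses, rates, OD), Poisson for spectral counts, log-normal
for metabolite peak areas.  Every generator takes an explicit seed (or
Generator); the same seed reproduces the same tables bit for bit.

Defaults mirror the study conditions: analyte grids of 1.5-48 µM (PurH) and
1-64 µM (GlyA) for SPR, substrate grids of 20 µM-1 mM (PurH transformylase)
and 0.1-16 µM (DHFR), OD600 sampled at 15-min intervals over 12 h, three
sample vs five control co-IP runs, three biological replicates for
metabolites, and 3% SD on fitness points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingIsotherm
from .growth import FitnessPoint, GrowthCurve
from .interactome import CONTROL, SAMPLE, PeptideCountTable
from .kinetics import RateDataset
from .metabolomics import MetaboliteMatrix

__all__ = [
    "GroundTruth",
    "PURH_SPR_GRID_M",
    "GLYA_SPR_GRID_M",
    "PURH_SUBSTRATE_GRID_M",
    "DHFR_SUBSTRATE_GRID_M",
    "gen_isotherm",
    "gen_mm_dataset",
    "gen_growth_curves",
    "gen_peptide_table",
    "gen_metabolite_matrix",
    "gen_fitness_curve",
]

#: SPR analyte concentration series (mol/L).
PURH_SPR_GRID_M = tuple(c * 1e-6 for c in (1.5, 3, 6, 12, 24, 48))
GLYA_SPR_GRID_M = tuple(c * 1e-6 for c in (1, 2, 4, 8, 16, 32, 48, 64))

#: Substrate grids (mol/L): 2-fold ladders spanning the stated ranges.
PURH_SUBSTRATE_GRID_M = tuple(c * 1e-6 for c in (20, 40, 80, 160, 320, 640, 1000))
DHFR_SUBSTRATE_GRID_M = tuple(c * 1e-6 for c in (0.1, 0.25, 0.5, 1, 2, 4, 8, 16))


@dataclass(frozen=True)
class GroundTruth:
    """True generator parameters serialized alongside every dataset."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: "int | None" = None

    def to_series(self) -> pd.Series:
        flat = {"generator": self.generator, "seed": self.seed}
        flat.update(self.params)
        return pd.Series(flat)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_isotherm(
    kd: float = 3e-6,
    rmax: float = 100.0,
    conc_grid: Sequence[float] = PURH_SPR_GRID_M,
    noise_cv: float = 0.02,
    seed: "int | np.random.Generator" = 0,
) -> tuple[BindingIsotherm, GroundTruth]:
    """Langmuir 1:1 responses with multiplicative Gaussian noise."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    conc = np.asarray(list(conc_grid), float)
    if conc.size == 0:
        raise ValueError("empty concentration grid")
    rng = _rng(seed)
    clean = rmax * conc / (conc + kd)
    resp = clean * (1.0 + noise_cv * rng.standard_normal(conc.size))
    gt = GroundTruth(
        "isotherm",
        {"kd": kd, "rmax": rmax, "noise_cv": noise_cv, "conc_grid": tuple(conc)},
        seed if isinstance(seed, int) else None,
    )
    return BindingIsotherm(conc, resp), gt


def gen_mm_dataset(
    kcat: float = 10.0,
    km: float = 1e-6,
    enzyme_conc: float = 1e-8,
    substrate_grid: Sequence[float] = DHFR_SUBSTRATE_GRID_M,
    noise_cv: float = 0.03,
    seed: "int | np.random.Generator" = 0,
    modulator_name: "str | None" = None,
    modulator_conc: float = 0.0,
) -> tuple[RateDataset, GroundTruth]:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    s = np.asarray(list(substrate_grid), float)
    if s.size == 0:
        raise ValueError("empty substrate grid")
    rng = _rng(seed)
    vmax = kcat * enzyme_conc
    clean = vmax * s / (km + s)
    rates = np.maximum(clean * (1.0 + noise_cv * rng.standard_normal(s.size)), 0.0)
    gt = GroundTruth(
        "mm_dataset",
        {
            "kcat": kcat,
            "km": km,
            "enzyme_conc": enzyme_conc,
            "vmax": vmax,
            "noise_cv": noise_cv,
        },
        seed if isinstance(seed, int) else None,
    )
    return (
        RateDataset(s, rates, enzyme_conc, modulator_name, modulator_conc),
        gt,
    )


def gen_growth_curves(
    mu: float = 0.6,
    lag: float = 1.0,
    amplitude: float = 2.0,
    duration_h: float = 12.0,
    sampling_min: float = 15.0,
    od0: float = 0.05,
    noise_cv: float = 0.01,
    seed: "int | np.random.Generator" = 0,
    label: str = "synthetic",
) -> tuple[GrowthCurve, GroundTruth]:
    """Modified-Gompertz OD600 curve sampled at fixed intervals.

    ``mu`` (h^-1), ``lag`` (h) and ``amplitude`` (ln-fold growth) are the
    ground-truth Gompertz parameters; multiplicative Gaussian noise is
    applied to the OD values.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    t_min = np.arange(0.0, duration_h * 60.0 + 0.5 * sampling_min, sampling_min)
    t_h = t_min / 60.0
    y = amplitude * np.exp(-np.exp(mu * np.e / amplitude * (lag - t_h) + 1.0))
    od = od0 * np.exp(y)
    od = od * (1.0 + noise_cv * rng.standard_normal(od.size))
    gt = GroundTruth(
        "growth_curve",
        {"mu": mu, "lag": lag, "amplitude": amplitude, "od0": od0, "noise_cv": noise_cv},
        seed if isinstance(seed, int) else None,
    )
    return GrowthCurve(t_min, np.maximum(od, 1e-6), label), gt


def gen_peptide_table(
    n_background: int = 300,
    n_enriched: int = 30,
    background_lambda: float = 5.0,
    enrichment_factor: float = 8.0,
    n_sample_runs: int = 3,
    n_control_runs: int = 5,
    seed: "int | np.random.Generator" = 0,
) -> tuple[PeptideCountTable, GroundTruth]:
    """Poisson spectral counts: a background set with equal rates in sample
    and control runs, plus an enriched set whose sample-run rate is scaled
    by ``enrichment_factor``.

    Per-protein baseline rates are drawn once (gamma with shape 2 and mean
    ``background_lambda``) and shared across runs, giving the positive
    between-run correlation seen in real replicate pull-downs while keeping
    essentially every protein detectable.
    """
    rng = _rng(seed)
    n = n_background + n_enriched
    base = rng.gamma(2.0, background_lambda / 2.0, size=n)
    enriched = np.zeros(n, dtype=bool)
    enriched[n_background:] = True
    sample_rates = np.where(enriched, base * enrichment_factor, base)

    cols = {}
    roles = {}
    for i in range(n_sample_runs):
        name = f"S{i + 1}"
        cols[name] = rng.poisson(sample_rates)
        roles[name] = SAMPLE
    for i in range(n_control_runs):
        name = f"C{i + 1}"
        cols[name] = rng.poisson(base)
        roles[name] = CONTROL
    proteins = [f"bg{i + 1}" for i in range(n_background)] + [
        f"enr{i + 1}" for i in range(n_enriched)
    ]
    counts = pd.DataFrame(cols, index=proteins)
    gt = GroundTruth(
        "peptide_table",
        {
            "background_lambda": background_lambda,
            "enrichment_factor": enrichment_factor,
            "enriched": tuple(p for p, e in zip(proteins, enriched) if e),
        },
        seed if isinstance(seed, int) else None,
    )
    return PeptideCountTable(counts, roles), gt


def gen_metabolite_matrix(
    effects: "dict[str, dict[str, float]] | None" = None,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    base_area: float = 1e6,
    control: str = "empty",
    seed: "int | np.random.Generator" = 0,
) -> tuple[MetaboliteMatrix, GroundTruth]:
    """Log-normal replicate peak areas with strain-specific fold effects.

    ``effects`` maps strain -> {metabolite -> fold change vs control}; the
    control strain itself always has fold 1.  ``noise_cv`` is the
    coefficient of variation of the log-normal replicate noise.
    """
    if effects is None:
        effects = {
            "DHFR_oe": {"AICAR": 8.0, "dUMP": 4.0, "IMP": 0.25, "dTTP": 0.25, "AMP": 0.5},
            "ADK_oe": {},
        }
    rng = _rng(seed)
    metabolites = sorted({m for fx in effects.values() for m in fx} | {"dTMP", "GMP"})
    strains = [control] + sorted(effects)
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    rows = []
    for met in metabolites:
        scale = base_area * np.exp(rng.normal(0.0, 1.0))  # per-metabolite ionization
        for strain in strains:
            fold = 1.0 if strain == control else effects[strain].get(met, 1.0)
            mu_log = np.log(scale * fold) - sigma**2 / 2.0
            areas = np.exp(rng.normal(mu_log, sigma, size=n_replicates))
            for rep, area in enumerate(areas, start=1):
                rows.append((met, strain, rep, float(area)))
    df = pd.DataFrame(rows, columns=["metabolite", "strain", "replicate", "area"])
    gt = GroundTruth(
        "metabolite_matrix",
        {"effects": effects, "noise_cv": noise_cv, "control": control},
        seed if isinstance(seed, int) else None,
    )
    return MetaboliteMatrix(df), gt


def gen_fitness_curve(
    branch: str = "overexpression",
    params: "dict[str, float] | None" = None,
    n_points: int = 6,
    sd: float = 0.03,
    seed: "int | np.random.Generator" = 0,
) -> tuple[list[FitnessPoint], GroundTruth]:
    """Abundance-fitness points on the depletion or overexpression branch.

    Depletion: ``f(a) = f_max a / (a + k_f)`` sampled on a log grid below
    basal abundance.  Overexpression: decreasing 4PL in log10 abundance
    sampled from ~5-fold to ~850-fold.  Gaussian noise with standard
    deviation ``sd`` (absolute, on normalized growth) is added.
    """
    rng = _rng(seed)
    if branch == "depletion":
        p = {"f_max": 1.0, "k_f": 0.05}
        if params:
            p.update(params)
        a = np.logspace(-2, 0, n_points)
        clean = p["f_max"] * a / (a + p["k_f"])
    elif branch == "overexpression":
        p = {"bottom": 0.27, "top": 1.0, "log10_mid": 1.7, "hill": 2.0}
        if params:
            p.update(params)
        a = np.logspace(np.log10(5.0), np.log10(850.0), n_points)
        la = np.log10(a)
        clean = p["bottom"] + (p["top"] - p["bottom"]) / (
            1.0 + 10.0 ** (p["hill"] * (la - p["log10_mid"]))
        )
    else:
        raise ValueError("branch must be 'depletion' or 'overexpression'")
    g = np.maximum(clean + sd * rng.standard_normal(a.size), 0.0)
    points = [FitnessPoint(float(ai), float(gi), sd) for ai, gi in zip(a, g)]
    gt = GroundTruth(
        "fitness_curve",
        {"branch": branch, **p, "sd": sd},
        seed if isinstance(seed, int) else None,
    )
    return points, gt
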