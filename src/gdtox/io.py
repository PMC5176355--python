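"""Validated table I/O, pipeline configuration, and the end-to-end runner.

Tables are plain CSV (comma) or TSV with a mandatory header, UTF-8, '.'
decimals; numeric output is written with 15 significant digits so that
write -> read round-trips are lossless for double precision in practice.
The pipeline runner executes selected analysis stages on seeded synthetic
inputs (or user-supplied files where given) and writes per-stage TSVs plus
a combined JSON summary; logs go to stderr, never into result files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import binding, equilibrium, growth, interactome, kinetics, metabolomics, synthdata

__all__ = [
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
    "get_logger",
]

_FLOAT_FORMAT = "%.15g"

logger = logging.getLogger("gdtox")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger writing to stderr (results stay on stdout/files)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


class SchemaError(ValueError):
    """A table did not match its expected schema."""


def read_table(
    path: "str | Path",
    schema: "Sequence[str] | Mapping[str, type] | None" = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited table, validating header and numeric columns.

    ``schema`` lists required columns; when given as a mapping, columns
    mapped to ``float`` or ``int`` are parsed as numbers and a malformed
    cell raises a parse error citing its (0-based data) row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty input file")
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] == 0 or (df.shape[0] == 0 and schema is None):
        raise SchemaError(f"{path}: no data rows")
    if schema is not None:
        cols = list(schema)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        if isinstance(schema, Mapping):
            for col, typ in schema.items():
                if typ in (float, int):
                    parsed = pd.to_numeric(df[col], errors="coerce")
                    bad = parsed.isna() & df[col].notna()
                    if bad.any():
                        row = int(np.flatnonzero(bad.to_numpy())[0])
                        raise SchemaError(
                            f"{path}: non-numeric value in column {col!r} at row {row}"
                        )
                    df[col] = parsed.astype(typ)
    return df


def write_table(df: pd.DataFrame, path: "str | Path", sep: str = ",") -> Path:
    """Write a table with full double precision; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FORMAT)
    return path


_KNOWN_STAGES = ("equilibrium", "binding", "kinetics", "growth", "interactome", "metabolomics")
_KNOWN_KEYS = {
    "stages",
    "seed",
    "output_dir",
    "inputs",
    "ttest_variant",
    "alternative",
    "hub_total_m",
    "partner_totals_m",
    "kds_m",
    "fold_factors",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration.

    ``inputs`` optionally maps a stage name to an input CSV path; stages
    without an input run on seeded synthetic data.  Unknown keys are
    rejected so typos fail fast.
    """

    stages: tuple[str, ...]
    seed: int = 0
    output_dir: Path = Path("gdtox_out")
    inputs: dict = field(default_factory=dict)
    ttest_variant: str = "welch"  # or "pooled"
    alternative: str = "two-sided"
    hub_total_m: float = 5e-8
    partner_totals_m: dict = field(default_factory=lambda: {"PurH": 2e-7})
    kds_m: dict = field(default_factory=lambda: {"PurH": 3e-6})
    fold_factors: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("no stages selected")
        unknown = set(self.stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.ttest_variant not in ("welch", "pooled"):
            raise ValueError("ttest_variant must be 'welch' or 'pooled'")
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "fold_factors", tuple(self.fold_factors))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a key-value mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _stage_equilibrium(cfg: PipelineConfig, outdir: Path) -> dict:
    system = equilibrium.EquilibriumSystem.from_totals(
        "hub", cfg.hub_total_m, dict(cfg.partner_totals_m), dict(cfg.kds_m)
    )
    scan = equilibrium.titration_scan(system, list(cfg.fold_factors))
    write_table(scan, outdir / "equilibrium_titration.tsv", sep="\t")
    basal = equilibrium.solve_competitive(system)
    return {
        "basal_fraction_bound": {k: v for k, v in basal.fraction_bound.items()},
        "titration_rows": len(scan),
    }


def _stage_binding(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> dict:
    iso, gt = synthdata.gen_isotherm(seed=rng)
    fit = binding.fit_isotherm(iso)
    df = pd.DataFrame(
        [{"rmax_RU": fit.rmax, "kd_M": fit.kd, "rss_RU2": fit.residual_sum_sq}]
    )
    write_table(df, outdir / "binding_isotherm_fit.tsv", sep="\t")
    return {"kd_fit_M": fit.kd, "kd_true_M": gt.params["kd"]}


def _stage_kinetics(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> dict:
    data, gt = synthdata.gen_mm_dataset(seed=rng)
    fit = kinetics.fit_michaelis_menten(data)
    df = pd.DataFrame(
        [{"kcat_per_s": fit.kcat, "km_M": fit.km, "efficiency_per_M_s": fit.efficiency}]
    )
    write_table(df, outdir / "kinetics_mm_fit.tsv", sep="\t")
    return {"km_fit_M": fit.km, "km_true_M": gt.params["km"]}


def _stage_growth(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> dict:
    curve, gt = synthdata.gen_growth_curves(seed=rng)
    params = growth.fit_growth_curve(curve)
    df = pd.DataFrame(
        [{"mu_per_h": params.mu_max, "lag_h": params.lag, "amplitude": params.amplitude}]
    )
    write_table(df, outdir / "growth_fit.tsv", sep="\t")
    return {"mu_fit_per_h": params.mu_max, "mu_true_per_h": gt.params["mu"]}


def _stage_interactome(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> dict:
    table, gt = synthdata.gen_peptide_table(seed=rng)
    hits = interactome.call_interactors(table)
    write_table(hits.table.reset_index(names="protein"), outdir / "ip_hits.tsv", sep="\t")
    p = interactome.dataset_shift_test(table)
    enriched = set(gt.params["enriched"])
    recall = len(enriched & set(hits.proteins)) / len(enriched)
    return {"n_hits": len(hits.proteins), "dataset_shift_p": p, "recall_enriched": recall}


def _stage_metabolomics(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> dict:
    m, gt = synthdata.gen_metabolite_matrix(seed=rng)
    fc = metabolomics.normalize_to_control(m, gt.params["control"])
    write_table(
        fc.log2fc.reset_index(names="metabolite"), outdir / "metabolite_log2fc.tsv", sep="\t"
    )
    return {"n_metabolites": len(fc.log2fc)}


_STAGE_FUNCS = {
    "equilibrium": _stage_equilibrium,
    "binding": _stage_binding,
    "kinetics": _stage_kinetics,
    "growth": _stage_growth,
    "interactome": _stage_interactome,
    "metabolomics": _stage_metabolomics,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages in declaration order; returns the summary dict.

    Per-stage tables land in ``config.output_dir``; the combined summary
    (including the mass-action sequestration table for the configured
    abundances) is written to ``summary.json``.  A stage failure halts the
    run with the stage named; earlier outputs are retained.
    """
    log = get_logger()
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    for stage in config.stages:
        rng = np.random.default_rng([config.seed, _KNOWN_STAGES.index(stage)])
        log.info("running stage %s", stage)
        try:
            if stage == "equilibrium":
                summary["stages"][stage] = _stage_equilibrium(config, outdir)
            else:
                summary["stages"][stage] = _STAGE_FUNCS[stage](config, outdir, rng)
        except Exception as exc:  # halt with stage name; keep partial outputs
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
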