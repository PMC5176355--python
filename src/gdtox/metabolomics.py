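"""Metabolite peak-area statistics: fold changes, significance stars, fitness links.

Replicate integrated peak areas (metabolite x strain x replicate) are turned
into log2 fold-change matrices against a control strain (empty-plasmid by
convention), annotated with the standard star scheme ('*' for p < 0.05,
'**' for p < 0.001, unpaired t-test per metabolite), and correlated with
per-strain relative growth (Pearson).  Zero/missing areas are floored at
half the smallest positive area of the metabolite before ratios are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteMatrix",
    "FoldChangeMatrix",
    "SignificanceAnnotation",
    "normalize_to_control",
    "annotate_significance",
    "star_label",
    "correlate_with_fitness",
]

_COLUMNS = ("metabolite", "strain", "replicate", "area")


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Long-format replicate peak areas with columns
    (metabolite, strain, replicate, area)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if np.any(self.data["area"].to_numpy(float) < 0):
            raise ValueError("areas must be >= 0")

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    def floored(self) -> pd.DataFrame:
        """Areas with zeros replaced by half the metabolite's minimum positive area."""
        df = self.data.copy()
        for met, grp in df.groupby("metabolite"):
            pos = grp.loc[grp["area"] > 0, "area"]
            if len(pos) == 0:
                continue
            df.loc[(df["metabolite"] == met) & (df["area"] <= 0), "area"] = pos.min() / 2.0
        return df

    def replicate_areas(self, metabolite: str, strain: str) -> np.ndarray:
        df = self.floored()
        sel = (df["metabolite"] == metabolite) & (df["strain"] == strain)
        return df.loc[sel, "area"].to_numpy(float)


@dataclass(frozen=True)
class FoldChangeMatrix:
    """log2 fold change per (metabolite, strain) against the control strain."""

    log2fc: pd.DataFrame  # index metabolites, columns strains
    control: str
    n_replicates: pd.DataFrame
    excluded: tuple[str, ...] = ()  # metabolites with unusable control means


@dataclass(frozen=True)
class SignificanceAnnotation:
    pvalues: pd.Series  # index metabolites
    stars: pd.Series

    def star(self, metabolite: str) -> str:
        return str(self.stars.loc[metabolite])


def star_label(p: float) -> str:
    """'**' iff p < 0.001, '*' iff 0.001 <= p < 0.05, '' otherwise."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def normalize_to_control(
    m: MetaboliteMatrix, control: str, estimator: str = "mean"
) -> FoldChangeMatrix:
    """Per metabolite, log2(strain mean area / control mean area).

    ``estimator`` is 'mean' (arithmetic, default) or 'gmean' (geometric).
    Metabolites undetected in the control (raw replicate mean zero or strain
    absent) are excluded and listed; sporadic zeros elsewhere are floored.
    """
    if control not in m.strains:
        raise ValueError(f"control strain {control!r} not present")
    agg = {"mean": np.mean, "gmean": stats.gmean}[estimator]
    raw_ctrl = (
        m.data[m.data["strain"] == control].groupby("metabolite")["area"].mean()
    )
    df = m.floored()
    means = df.groupby(["metabolite", "strain"])["area"].apply(lambda v: float(agg(v)))
    means = means.unstack("strain")
    counts = df.groupby(["metabolite", "strain"])["area"].size().unstack("strain")

    raw_ctrl = raw_ctrl.reindex(means.index)
    bad = means.index[raw_ctrl.isna() | (raw_ctrl <= 0)]
    usable = means.drop(index=bad)
    log2fc = np.log2(usable.div(usable[control], axis=0))
    return FoldChangeMatrix(
        log2fc=log2fc,
        control=control,
        n_replicates=counts.drop(index=bad),
        excluded=tuple(bad),
    )


def annotate_significance(
    m: MetaboliteMatrix,
    test_strain: str,
    reference_strain: str,
    equal_var: bool = False,
) -> SignificanceAnnotation:
    """Per-metabolite unpaired t-test (Welch by default) between two strains.

    Degenerate case: identical replicate sets on both sides -> p = 1.  No
    multiple-testing correction is applied, matching the figure-legend
    convention; apply e.g. Benjamini-Hochberg downstream if desired.
    """
    pvals = {}
    for met in m.metabolites:
        a = m.replicate_areas(met, test_strain)
        b = m.replicate_areas(met, reference_strain)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"need >= 2 replicates per side for {met!r}")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            pvals[met] = 1.0 if a[0] == b[0] else 0.0
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        pvals[met] = float(res.pvalue)
    p = pd.Series(pvals).sort_index()
    return SignificanceAnnotation(pvalues=p, stars=p.map(star_label))


def correlate_with_fitness(
    levels: "pd.Series | dict[str, float]", growth: "pd.Series | dict[str, float]"
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-strain metabolite level vs
    relative growth, matched on strain identifiers."""
    levels = pd.Series(levels)
    growth = pd.Series(growth)
    common = levels.index.intersection(growth.index)
    if len(common) < 4:
        raise ValueError("need >= 4 strains with both measurements")
    x = levels.loc[common].to_numpy(float)
    y = growth.loc[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Pearson correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
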