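"""Co-IP interactor calling from peptide spectral-count tables.

A pull-down experiment yields, for every protein observed in any run, the
number of peptide spectra assigned to it in each sample run (bait pulled
down) and each control run (no bait, or a non-reactive bait).  A protein is
called an interactor when its mean count over sample runs strictly exceeds
its mean over (pooled) control runs; dataset-level enrichment is assessed
with a paired t-test across proteins, and reproducibility with pairwise
Pearson correlations among sample runs.  A protein missing from a run
contributes a count of zero.  No multiple-testing correction is applied to
the hit caller by default; an optional Benjamini-Hochberg layer on
per-protein Poisson-rate tests is available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeptideCountTable",
    "HitList",
    "EnrichmentSummary",
    "call_interactors",
    "dataset_shift_test",
    "replicate_agreement",
    "compare_interactomes",
]

SAMPLE = "sample"
CONTROL = "control"


@dataclass(frozen=True)
class PeptideCountTable:
    """Protein x run spectral counts with sample/control run labels."""

    counts: pd.DataFrame  # index = proteins, columns = run labels
    run_roles: dict[str, str]  # run label -> "sample" | "control"

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.run_roles):
            raise ValueError("run_roles must label exactly the table's columns")
        roles = set(self.run_roles.values())
        if not roles <= {SAMPLE, CONTROL}:
            raise ValueError(f"run roles must be '{SAMPLE}' or '{CONTROL}'")
        if SAMPLE not in roles or CONTROL not in roles:
            raise ValueError("need at least one sample and one control run")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be nonnegative integers")

    @property
    def sample_runs(self) -> list[str]:
        return [r for r in self.counts.columns if self.run_roles[r] == SAMPLE]

    @property
    def control_runs(self) -> list[str]:
        return [r for r in self.counts.columns if self.run_roles[r] == CONTROL]

    @classmethod
    def from_frame(cls, counts: pd.DataFrame) -> "PeptideCountTable":
        """Build from a frame whose column names carry 'sample:'/'control:' prefixes."""
        roles, renames = {}, {}
        for col in counts.columns:
            prefix, _, rest = str(col).partition(":")
            if prefix not in (SAMPLE, CONTROL) or not rest:
                raise ValueError(f"column {col!r} lacks a sample:/control: prefix")
            roles[rest] = prefix
            renames[col] = rest
        return cls(counts.rename(columns=renames), roles)


@dataclass(frozen=True)
class HitList:
    """Called interactors with their per-condition mean counts."""

    table: pd.DataFrame  # index = proteins; columns mean_sample, mean_control

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class EnrichmentSummary:
    paired_t_p: float
    replicate_correlations: dict[tuple[str, str], float]
    mean_correlation: float
    correlation_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate_pairs: tuple[tuple[str, str], ...] = ()


def _condition_means(table: PeptideCountTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean_sample": table.counts[table.sample_runs].mean(axis=1),
            "mean_control": table.counts[table.control_runs].mean(axis=1),
        }
    )


def call_interactors(table: PeptideCountTable) -> HitList:
    """Retain proteins whose sample mean strictly exceeds the control mean.

    Proteins absent from every run (all-zero rows) are excluded outright.
    The returned table is sorted by protein identifier, so run and protein
    ordering of the input are immaterial.
    """
    means = _condition_means(table)
    observed = table.counts.sum(axis=1) > 0
    hits = means[observed & (means["mean_sample"] > means["mean_control"])]
    return HitList(hits.sort_index())


def dataset_shift_test(table: PeptideCountTable, alternative: str = "two-sided") -> float:
    """Paired t-test, across proteins, of sample vs control mean counts.

    Returns the p-value.  Degenerate cases: identical means -> p = 1; a
    constant nonzero shift (zero variance of differences) -> p = 0.0 with a
    warning, rather than NaN.
    """
    means = _condition_means(table)
    if len(means) < 2:
        raise ValueError("need >= 2 proteins")
    diff = means["mean_sample"] - means["mean_control"]
    if np.allclose(diff, 0):
        return 1.0
    if np.ptp(diff.to_numpy()) == 0:
        warnings.warn("constant nonzero shift: paired t-test degenerate, p -> 0")
        return 0.0
    res = stats.ttest_rel(means["mean_sample"], means["mean_control"], alternative=alternative)
    return float(res.pvalue)


def replicate_agreement(table: PeptideCountTable) -> EnrichmentSummary:
    """Pairwise Pearson correlations of per-protein counts among sample runs."""
    runs = table.sample_runs
    if len(runs) < 2:
        raise ValueError("need >= 2 sample runs")
    corrs: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    degenerate: list[tuple[str, str]] = []
    for a, b in itertools.combinations(runs, 2):
        xa = table.counts[a].to_numpy(float)
        xb = table.counts[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            degenerate.append((a, b))
            continue
        r, p = stats.pearsonr(xa, xb)
        corrs[(a, b)] = float(r)
        pvals[(a, b)] = float(p)
    mean_r = float(np.mean(list(corrs.values()))) if corrs else float("nan")
    return EnrichmentSummary(
        paired_t_p=dataset_shift_test(table),
        replicate_correlations=corrs,
        mean_correlation=mean_r,
        correlation_pvalues=pvals,
        degenerate_pairs=tuple(degenerate),
    )


def compare_interactomes(a: HitList, b: HitList) -> dict:
    """Set overlap of two hit lists: shared, a-only, b-only, Jaccard index."""
    sa, sb = set(a.proteins), set(b.proteins)
    union = sa | sb
    return {
        "shared": sorted(sa & sb),
        "a_only": sorted(sa - sb),
        "b_only": sorted(sb - sa),
        "jaccard": (len(sa & sb) / len(union)) if union else 1.0,
    }
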