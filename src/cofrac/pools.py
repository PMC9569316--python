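"""Protein-bound vs free metabolite pool analytics.

The first ``boundary_fraction`` fractions (default 40 of 60) hold protein
complexes; intensity summed there is the bound pool, the remainder the free
pool. Totals, bound/free ratios and their phase comparisons are computed on
replicate profiles and summarized on replicate means.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .profiles import ElutionProfile

__all__ = ["summarize_pools", "differential_totals", "compare_ratio_distributions"]


def summarize_pools(
    profiles: Iterable[ElutionProfile],
    boundary_fraction: int = 40,
) -> pd.DataFrame:
    """Per-(metabolite, phase) pool summary on replicate-mean profiles.

    Returns columns metabolite_id, phase, n_replicates, total, bound, free,
    ratio, ratio_degenerate. ``ratio`` is bound/free; when free is zero it
    falls back to bound/eps with eps the smallest positive free sum in the
    dataset, and the row is flagged degenerate.
    """
    profs = list(profiles)
    if not profs:
        raise ParameterError("no profiles given")
    n = profs[0].n_fractions
    if not 0 < boundary_fraction < n:
        raise ParameterError("boundary_fraction must lie inside the fraction range")

    rows = []
    for p in profs:
        v = p.intensities
        bound = float(v[:boundary_fraction].sum())
        free = float(v[boundary_fraction:].sum())
        rows.append((p.molecule_id, p.phase, p.replicate, bound + free, bound, free))
    rep = pd.DataFrame(rows, columns=["metabolite_id", "phase", "replicate", "total", "bound", "free"])

    agg = (
        rep.groupby(["metabolite_id", "phase"], sort=True)
        .agg(n_replicates=("replicate", "size"), total=("total", "mean"), bound=("bound", "mean"), free=("free", "mean"))
        .reset_index()
    )
    positive_free = agg.loc[agg["free"] > 0, "free"]
    eps = float(positive_free.min()) if not positive_free.empty else np.nan
    degenerate = agg["free"] <= 0
    denom = np.where(degenerate, eps, agg["free"])
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["ratio"] = agg["bound"] / denom
    agg["ratio_degenerate"] = degenerate
    return agg


def totals_matrix(profiles: Iterable[ElutionProfile], phase: str) -> pd.DataFrame:
    """Metabolites x replicates table of summed profile intensities."""
    rows = [
        (p.molecule_id, p.replicate, float(p.intensities.sum()))
        for p in profiles
        if p.phase == phase
    ]
    df = pd.DataFrame(rows, columns=["metabolite_id", "replicate", "total"])
    return df.pivot_table(index="metabolite_id", columns="replicate", values="total", aggfunc="first")


def differential_totals(
    profiles: Iterable[ElutionProfile],
    phase_a: str,
    phase_b: str,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Differential total-abundance calls between phases on per-replicate sums."""
    from .abundance import pairwise_calls

    profs = list(profiles)
    a = totals_matrix(profs, phase_a)
    b = totals_matrix(profs, phase_b)
    shared = a.index.intersection(b.index)
    return pairwise_calls(
        a.loc[shared],
        b.loc[shared],
        comparison=f"{phase_a}_vs_{phase_b}",
        fdr_threshold=fdr_threshold,
        fc_threshold=fc_threshold,
    )


def compare_ratio_distributions(summaries: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-phase median bound/free ratio and pairwise paired location tests.

    The test is a two-sided Wilcoxon signed-rank on paired log2 ratios of
    metabolites measured in both phases; unpaired metabolites are dropped
    from the test (their count is reported).
    """
    medians = summaries.groupby("phase")["ratio"].median()
    phases = list(medians.index)
    wide = summaries.pivot_table(index="metabolite_id", columns="phase", values="ratio", aggfunc="first")
    rows = []
    for i, pa in enumerate(phases):
        for pb in phases[i + 1 :]:
            paired = wide[[pa, pb]].dropna()
            paired = paired[(paired[pa] > 0) & (paired[pb] > 0)]
            n_dropped = len(wide) - len(paired)
            if len(paired) < 3:
                raise ParameterError(f"fewer than 3 paired metabolites for {pa} vs {pb}")
            diff = np.log2(paired[pa]) - np.log2(paired[pb])
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
            rows.append((pa, pb, len(paired), n_dropped, p))
    tests = pd.DataFrame(rows, columns=["phase_a", "phase_b", "n_paired", "n_dropped", "p_value"])
    return medians, tests
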