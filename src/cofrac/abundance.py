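"""Median normalization and pairwise differential testing of intensity tables.

The same machinery (two-sided t-test on log2 intensities + Benjamini–Hochberg
FDR + fold-change gate) backs protein abundance, thermal-stability and
metabolite-total comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NormalizationError, ParameterError, ShapeError

__all__ = ["AbundanceMatrix", "median_normalize", "differential_abundance", "pairwise_calls"]

CALL_COLUMNS = [
    "feature_id",
    "comparison",
    "log2_fc",
    "p_value",
    "q_value",
    "significant",
    "n_a",
    "n_b",
    "tested",
]


@dataclass
class AbundanceMatrix:
    """Features x samples intensity table with per-sample metadata.

    ``values``: DataFrame indexed by feature id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns phase, replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ShapeError(f"samples sheet missing entries for {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ShapeError("negative intensities in abundance matrix")

    def phase_columns(self, phase: str) -> list[str]:
        cols = [s for s in self.values.columns if self.samples.loc[s, "phase"] == phase]
        if not cols:
            raise ParameterError(f"no samples for phase {phase!r}")
        return cols


def _sample_medians(values: pd.DataFrame) -> pd.Series:
    """Per-sample median over detected (positive) intensities."""
    masked = values.where(values > 0)
    return masked.median(axis=0)


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Equalize sample medians to the global median (median of sample medians).

    Each sample is scaled by global_median / sample_median so that after
    normalization every sample's median detected intensity equals the global
    median.
    """
    med = _sample_medians(matrix.values)
    if med.isna().any() or (med <= 0).any():
        bad = list(med.index[med.isna() | (med <= 0)])
        raise NormalizationError(f"samples with non-positive median: {bad}")
    global_median = float(med.median())
    scaled = matrix.values * (global_median / med)
    return AbundanceMatrix(values=scaled, samples=matrix.samples.copy())


def pairwise_calls(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    comparison: str,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential calls between two replicate tables sharing a feature index.

    Zeros are treated as missing. Features with fewer than 2 usable
    replicates in either group are reported untestable and excluded from the
    BH adjustment. The fold change is the ratio of group means of the
    (normalized) intensities; the t-test runs on log2 intensities.
    """
    if not group_a.index.equals(group_b.index):
        group_b = group_b.reindex(group_a.index)
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    a = np.where(a > 0, a, np.nan)
    b = np.where(b > 0, b, np.nan)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nanmean(np.where(testable[:, None], a, np.nan), axis=1)
        mean_b = np.nanmean(np.where(testable[:, None], b, np.nan), axis=1)
        log2_fc = np.log2(mean_a / mean_b)
        res = stats.ttest_ind(np.log2(a), np.log2(b), axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(testable, p, np.nan)

    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    significant = testable & (q < fdr_threshold) & (np.abs(log2_fc) > np.log2(fc_threshold))

    return pd.DataFrame(
        {
            "feature_id": group_a.index,
            "comparison": comparison,
            "log2_fc": np.where(testable, log2_fc, np.nan),
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "n_a": n_a,
            "n_b": n_b,
            "tested": testable,
        }
    ).reset_index(drop=True)


def differential_abundance(
    matrix: AbundanceMatrix,
    phase_a: str,
    phase_b: str,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    equal_var: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Median-normalize then test phase A vs phase B feature-wise."""
    mat = median_normalize(matrix) if normalize else matrix
    cols_a = mat.phase_columns(phase_a)
    cols_b = mat.phase_columns(phase_b)
    return pairwise_calls(
        mat.values[cols_a],
        mat.values[cols_b],
        comparison=f"{phase_a}_vs_{phase_b}",
        fdr_threshold=fdr_threshold,
        fc_threshold=fc_threshold,
        equal_var=equal_var,
    )
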