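"""Cross-experiment integration: overlap sets and scalar correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

__all__ = ["OverlapReport", "overlap_sets", "correlate_scalars", "compare_group_lengths"]


@dataclass(frozen=True)
class OverlapReport:
    label_a: str
    label_b: str
    both: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    neither: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            f"{self.label_a}_only": len(self.only_a),
            f"{self.label_b}_only": len(self.only_b),
            "neither": len(self.neither),
        }


def overlap_sets(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapReport:
    """Two-set overlap report restricted to a shared universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValidationError("sets must be subsets of the universe")
    return OverlapReport(
        label_a=label_a,
        label_b=label_b,
        both=frozenset(a & b),
        only_a=frozenset(a - b),
        only_b=frozenset(b - a),
        neither=frozenset(u - a - b),
    )


def correlate_scalars(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p between paired per-protein scalars.

    Returns (nan, nan) if either vector has zero variance (undefined).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ParameterError("x and y must be 1-D and paired")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ParameterError("need at least 3 paired values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def compare_group_lengths(
    group_assignment: Mapping[str, str],
    lengths_aa: Mapping[str, float],
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group median chain length plus pairwise two-sided Mann-Whitney U.

    Proteins without a length and empty groups are excluded (reported via
    the group sizes). Returns (medians, pairwise test table).
    """
    by_group: dict[str, list[float]] = {}
    for pid, grp in group_assignment.items():
        if pid in lengths_aa and not np.isnan(lengths_aa[pid]):
            by_group.setdefault(grp, []).append(float(lengths_aa[pid]))
    by_group = {g: v for g, v in by_group.items() if v}
    if len(by_group) < 2:
        raise ParameterError("need at least 2 non-empty groups")
    medians = pd.Series({g: float(np.median(v)) for g, v in sorted(by_group.items())}, name="median_length_aa")
    groups = sorted(by_group)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            u = stats.mannwhitneyu(by_group[ga], by_group[gb], alternative="two-sided")
            rows.append((ga, gb, len(by_group[ga]), len(by_group[gb]), float(u.pvalue)))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value"])
    return medians, tests
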