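"""Elution-profile primitives: normalization, peak deconvolution, MW calibration.

Fractions are 1-based, ordered by decreasing molecular size (earlier
fraction = larger assembly). All profile vectors are dense over fractions
``1..n_fractions``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, DegenerateProfileError, ShapeError, ValidationError

__all__ = [
    "ElutionProfile",
    "Peak",
    "PeakSet",
    "MWCalibration",
    "normalize_to_max",
    "aggregate_replicates",
    "deconvolve_peaks",
    "fit_mw_calibration",
    "fraction_to_mass",
    "mass_to_fraction",
]


@dataclass(frozen=True)
class ElutionProfile:
    """Intensity vector of one molecule over ordered SEC fractions."""

    molecule_id: str
    molecule_class: str  # "protein" or "metabolite"
    phase: str
    replicate: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", v)
        if v.ndim != 1:
            raise ShapeError(f"{self.molecule_id}: intensities must be 1-D")
        if np.any(v < 0):
            raise ValidationError(f"{self.molecule_id}: negative intensity")
        if self.replicate < 1:
            raise ValidationError(f"{self.molecule_id}: replicate must be >= 1")

    @property
    def n_fractions(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class Peak:
    """One deconvolved peak.

    ``apex_fraction``, ``left_bound`` and ``right_bound`` are 1-based and
    inclusive; ``height`` is relative to the main peak of the same profile;
    ``subprofile`` is a full-length vector that is zero outside the bounds.
    """

    apex_fraction: int
    left_bound: int
    right_bound: int
    height: float
    subprofile: np.ndarray

    def __post_init__(self) -> None:
        if not (self.left_bound <= self.apex_fraction <= self.right_bound):
            raise ValidationError("peak apex outside its bounds")
        if not (0.0 < self.height <= 1.0):
            raise ValidationError("peak height must lie in (0, 1]")


@dataclass(frozen=True)
class PeakSet:
    molecule_id: str
    phase: str
    peaks: tuple[Peak, ...]
    molecule_class: str = "protein"

    def __post_init__(self) -> None:
        prev_right = 0
        for p in sorted(self.peaks, key=lambda q: q.apex_fraction):
            if p.left_bound <= prev_right:
                raise ValidationError(f"{self.molecule_id}: overlapping peak bounds")
            prev_right = p.right_bound


@dataclass(frozen=True)
class MWCalibration:
    """Linear map fraction -> log10(mass in kDa); slope < 0 by convention."""

    intercept: float
    slope: float
    standards: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError("calibration slope must be negative")

    def mass_at(self, fraction: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * fraction))

    def fraction_at(self, mass_kda: float) -> float:
        if mass_kda <= 0:
            raise CalibrationError("mass must be positive")
        return float((np.log10(mass_kda) - self.intercept) / self.slope)


def normalize_to_max(profile: ElutionProfile) -> ElutionProfile:
    """Scale a profile so its maximum equals 1. Shape is preserved."""
    m = float(profile.intensities.max(initial=0.0))
    if m <= 0:
        raise DegenerateProfileError(f"{profile.molecule_id}: all-zero profile")
    return replace(profile, intensities=profile.intensities / m)


def aggregate_replicates(profiles: Sequence[ElutionProfile]) -> ElutionProfile:
    """Fraction-wise mean over replicates of one molecule/phase."""
    if len(profiles) == 0:
        raise ShapeError("no replicates to aggregate")
    n = profiles[0].n_fractions
    if any(p.n_fractions != n for p in profiles):
        raise ShapeError("replicate profiles differ in length")
    mean = np.mean([p.intensities for p in profiles], axis=0)
    return replace(profiles[0], intensities=mean, replicate=1)


def _plateau_local_maxima(values: np.ndarray) -> list[int]:
    """0-based indices of positive local maxima; plateaus report their leftmost
    fraction. Profile ends count as maxima when the signal falls away from them."""
    n = values.shape[0]
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        rises_left = i == 0 or values[i - 1] < values[i]
        falls_right = j == n - 1 or values[j + 1] < values[i]
        if rises_left and falls_right and values[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def _enforce_min_separation(values: np.ndarray, maxima: list[int], min_separation: int) -> list[int]:
    """Greedily drop maxima closer than ``min_separation`` fractions to a
    taller accepted one (ties resolved towards the leftmost)."""
    order = sorted(maxima, key=lambda i: (-values[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - a) >= min_separation for a in accepted):
            accepted.append(i)
    return sorted(accepted)


def deconvolve_peaks(
    profile: ElutionProfile,
    min_rel_height: float = 0.10,
    min_separation: int = 2,
    smooth: bool = False,
) -> PeakSet:
    """Split an elution profile into single peaks.

    Local maxima are detected on the raw (optionally window-3 smoothed)
    signal; maxima closer than ``min_separation`` fractions to a taller one
    are treated as jitter; maxima below ``min_rel_height`` of the main
    maximum are discarded. Boundaries sit at the deepest minimum between
    adjacent retained apexes; the region of a discarded sub-threshold peak
    is excluded from the retained subprofiles.
    """
    raw = profile.intensities
    if raw.max(initial=0.0) <= 0:
        raise DegenerateProfileError(f"{profile.molecule_id}: all-zero profile")
    v = raw
    if smooth:
        kernel = np.ones(3) / 3.0
        v = np.convolve(raw, kernel, mode="same")

    candidates = _enforce_min_separation(v, _plateau_local_maxima(v), min_separation)
    # region per candidate: split at the deepest minimum between neighbours
    # (ties -> leftmost); the minimum fraction goes to the left region
    cuts: list[int] = []
    for a, b in zip(candidates[:-1], candidates[1:]):
        between = v[a + 1 : b]
        cuts.append(a + 1 + int(np.argmin(between)))
    lefts = [0] + [c + 1 for c in cuts]
    rights = cuts + [v.shape[0] - 1]

    main_height = max(v[i] for i in candidates)
    peaks: list[Peak] = []
    for apex, lo, hi in zip(candidates, lefts, rights):
        rel = v[apex] / main_height
        if rel < min_rel_height:
            continue
        sub = np.zeros_like(raw)
        sub[lo : hi + 1] = raw[lo : hi + 1]
        peaks.append(
            Peak(
                apex_fraction=apex + 1,
                left_bound=lo + 1,
                right_bound=hi + 1,
                height=float(rel),
                subprofile=sub,
            )
        )
    return PeakSet(
        molecule_id=profile.molecule_id,
        phase=profile.phase,
        peaks=tuple(peaks),
        molecule_class=profile.molecule_class,
    )


def fit_mw_calibration(standards: Sequence[tuple[float, float]]) -> MWCalibration:
    """Least-squares line on (fraction, log10 mass) over reference standards."""
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards")
    fr = np.asarray([s[0] for s in standards], dtype=float)
    mass = np.asarray([s[1] for s in standards], dtype=float)
    if np.any(mass <= 0):
        raise CalibrationError("standard masses must be positive")
    if np.unique(fr).shape[0] < 2:
        raise CalibrationError("standards must span at least 2 distinct fractions")
    slope, intercept = np.polyfit(fr, np.log10(mass), 1)
    return MWCalibration(
        intercept=float(intercept),
        slope=float(slope),
        standards=tuple((float(f), float(m)) for f, m in standards),
    )


def fraction_to_mass(cal: MWCalibration, fraction: float) -> float:
    return cal.mass_at(fraction)


def mass_to_fraction(cal: MWCalibration, mass_kda: float) -> float:
    return cal.fraction_at(mass_kda)
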