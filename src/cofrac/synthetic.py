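"""Synthetic CF-MS and thermal-shift data with programmed ground truth.

Generates size-exclusion elution profiles (proteins as mixtures of Gaussian
peaks per oligomeric state, metabolites split into a protein-bound pool under
the partner's peaks and a free low-molecular-weight pool), single-temperature
thermal-shift intensities driven by sigmoid melting, and replicate protein
abundance tables. All randomness flows from explicit seeds; a fixed
(config, seed) pair reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .profiles import ElutionProfile, MWCalibration

__all__ = [
    "RT_LABEL",
    "RT_CELSIUS",
    "SimConfig",
    "OligomerState",
    "ProteinSpec",
    "MetaboliteSpec",
    "MeltParams",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_sec_profiles",
    "simulate_itsa",
    "simulate_abundance",
    "melting_sigmoid",
    "temperature_celsius",
]

RT_LABEL = "RT"
RT_CELSIUS = 22.0  # internal numeric stand-in; only the label is exposed

# default calibration: fraction 1 ~ 5000 kDa, fraction 40 ~ 20 kDa (log-linear)
_DEFAULT_SLOPE = (math.log10(20.0) - math.log10(5000.0)) / 39.0
_DEFAULT_INTERCEPT = math.log10(5000.0) - _DEFAULT_SLOPE * 1.0


def temperature_celsius(label: str | float) -> float:
    """Numeric temperature for a condition label; ``"RT"`` maps to 22 °C."""
    if isinstance(label, str) and label.upper() == RT_LABEL:
        return RT_CELSIUS
    return float(label)


@dataclass(frozen=True)
class SimConfig:
    n_fractions: int = 60
    protein_fraction_count: int = 40
    phases: tuple[str, ...] = ("glucose", "ethanol", "early_stationary")
    temperatures: tuple[str, ...] = ("RT", "48", "52", "56")
    metabolite_replicates: int = 3
    protein_profile_replicates: int = 1
    itsa_replicates: int = 5
    abundance_replicates: int = 5
    noise_sigma: float = 0.1
    peak_width_fractions: float = 2.0
    free_pool_center: float = 50.0
    free_pool_width: float = 2.5
    detection_limit: float = 0.0
    mw_calibration: tuple[float, float] = (_DEFAULT_INTERCEPT, _DEFAULT_SLOPE)

    def __post_init__(self) -> None:
        # accept YAML/JSON lists for sequence-valued fields
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "temperatures", tuple(str(t) for t in self.temperatures))
        object.__setattr__(self, "mw_calibration", tuple(self.mw_calibration))
        if self.protein_fraction_count >= self.n_fractions:
            raise ParameterError("protein_fraction_count must be < n_fractions")
        if min(
            self.metabolite_replicates,
            self.protein_profile_replicates,
            self.itsa_replicates,
            self.abundance_replicates,
        ) < 1:
            raise ParameterError("replicate counts must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.peak_width_fractions <= 0:
            raise ParameterError("peak_width_fractions must be > 0")
        if RT_LABEL not in [t.upper() if isinstance(t, str) else t for t in self.temperatures]:
            raise ParameterError("temperatures must include RT")

    @property
    def calibration(self) -> MWCalibration:
        return MWCalibration(intercept=self.mw_calibration[0], slope=self.mw_calibration[1])

    @property
    def elevated_temperatures(self) -> tuple[str, ...]:
        return tuple(t for t in self.temperatures if str(t).upper() != RT_LABEL)


@dataclass(frozen=True)
class OligomerState:
    mass_kda: float
    mixing_fraction: float


@dataclass(frozen=True)
class ProteinSpec:
    protein_id: str
    length_aa: int
    abundance: Mapping[str, float]  # phase -> amount
    states: Mapping[str, tuple[OligomerState, ...]]  # phase -> oligomeric states


@dataclass(frozen=True)
class MetaboliteSpec:
    metabolite_id: str
    class_tag: str  # e.g. "dipeptide", "nucleotide"
    total: Mapping[str, float]  # phase -> amount
    bound_fraction: Mapping[str, float]  # phase -> fraction in [0, 1]
    partner: str | None


@dataclass(frozen=True)
class MeltParams:
    midpoint_c: float
    slope_c: float  # sigmoid scale in °C; larger = shallower transition


@dataclass(frozen=True)
class GroundTruth:
    proteins: tuple[ProteinSpec, ...]
    metabolites: tuple[MetaboliteSpec, ...]
    melt: Mapping[str, Mapping[str, MeltParams]]  # protein -> phase -> params
    rewired_fractionation: frozenset[str]
    rewired_stability: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        ids = {p.protein_id for p in self.proteins}
        if not self.rewired_fractionation <= ids or not self.rewired_stability <= ids:
            raise ConsistencyError("rewired sets must be subsets of protein ids")
        for p in self.proteins:
            for phase, states in p.states.items():
                s = sum(st.mixing_fraction for st in states)
                if abs(s - 1.0) > 1e-9:
                    raise ConsistencyError(f"{p.protein_id}/{phase}: mixing fractions sum to {s}")
            if any(a <= 0 for a in p.abundance.values()):
                raise ConsistencyError(f"{p.protein_id}: abundance must be > 0")
        for m in self.metabolites:
            for phase, bf in m.bound_fraction.items():
                if not 0.0 <= bf <= 1.0:
                    raise ConsistencyError(f"{m.metabolite_id}/{phase}: bound_fraction outside [0,1]")
                if bf > 0 and m.partner is None:
                    raise ConsistencyError(f"{m.metabolite_id}: bound fraction without a partner")
            if any(t <= 0 for t in m.total.values()):
                raise ConsistencyError(f"{m.metabolite_id}: total must be > 0")
            if m.partner is not None and m.partner not in ids:
                raise ConsistencyError(f"{m.metabolite_id}: unknown partner {m.partner}")

    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def metabolite_ids(self) -> list[str]:
        return [m.metabolite_id for m in self.metabolites]


def _draw_state_centers(rng: np.random.Generator, k: int, lo: float, hi: float, min_sep: float) -> list[float]:
    """Rejection-sample k peak centers in [lo, hi] at least min_sep apart."""
    for _ in range(1000):
        centers = sorted(rng.uniform(lo, hi, size=k))
        if all(b - a >= min_sep for a, b in zip(centers[:-1], centers[1:])):
            return centers
    raise ParameterError("cannot place oligomer peaks with requested separation")


def generate_ground_truth(
    config: SimConfig,
    n_proteins: int,
    n_metabolites: int,
    rewire_rate: float,
    seed: int,
) -> GroundTruth:
    """Draw a random but fully specified ground truth.

    Each protein is assigned 1–2 oligomeric states shared by the first two
    phases. Proteins sampled into ``rewired_fractionation`` (independent
    Bernoulli draws at ``rewire_rate``) have their assembly masses shifted in
    the last phase; proteins in ``rewired_stability`` have their melting
    midpoint shifted there by ±4 °C.
    """
    if n_proteins < 1 or n_metabolites < 1:
        raise ParameterError("need at least one protein and one metabolite")
    if not 0.0 <= rewire_rate <= 1.0:
        raise ParameterError("rewire_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cal = config.calibration
    phases = config.phases
    first, last = phases[0], phases[-1]
    lo_f, hi_f = 3.0, config.protein_fraction_count - 2.0

    proteins: list[ProteinSpec] = []
    melt: dict[str, dict[str, MeltParams]] = {}
    rewired_frac: set[str] = set()
    rewired_stab: set[str] = set()

    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        length = int(max(50, rng.lognormal(math.log(400.0), 0.35)))
        base_abund = rng.lognormal(math.log(1e6), 0.5)
        abundance = {ph: base_abund * rng.lognormal(0.0, 0.25) for ph in phases}

        k = 1 + int(rng.random() < 0.4)
        centers = _draw_state_centers(rng, k, lo_f, hi_f, min_sep=8.0)
        # keep both states above the downstream 10%-of-main-peak rule
        if k > 1:
            w = float(rng.uniform(0.25, 0.75))
            mix = np.array([w, 1.0 - w])
        else:
            mix = np.array([1.0])
        base_states = tuple(
            OligomerState(mass_kda=cal.mass_at(c), mixing_fraction=float(w))
            for c, w in zip(centers, mix)
        )
        states: dict[str, tuple[OligomerState, ...]] = {ph: base_states for ph in phases}

        frac_rewired = rng.random() < rewire_rate
        if frac_rewired:
            rewired_frac.add(pid)
            shifted = []
            for c, w in zip(centers, mix):
                nc = c + 10.0 if c <= (lo_f + hi_f) / 2 else c - 10.0
                shifted.append(OligomerState(mass_kda=cal.mass_at(nc), mixing_fraction=float(w)))
            states = dict(states)
            states[last] = tuple(shifted)

        base_mid = float(rng.normal(52.0, 2.0))
        melt_slope = float(rng.uniform(1.0, 2.0))
        midpoints = {ph: base_mid for ph in phases}
        stab_rewired = rng.random() < rewire_rate
        if stab_rewired:
            rewired_stab.add(pid)
            midpoints[last] = base_mid + float(rng.choice([-4.0, 4.0]))
        melt[pid] = {ph: MeltParams(midpoint_c=midpoints[ph], slope_c=melt_slope) for ph in phases}

        proteins.append(
            ProteinSpec(protein_id=pid, length_aa=length, abundance=abundance, states=states)
        )

    class_tags = ("dipeptide", "nucleotide", "amino_acid", "cofactor")
    class_p = (0.5, 0.2, 0.15, 0.15)
    metabolites: list[MetaboliteSpec] = []
    for j in range(n_metabolites):
        mid = f"M{j + 1:04d}"
        tag = str(rng.choice(class_tags, p=class_p))
        base_total = rng.lognormal(math.log(1e5), 0.6)
        total = {ph: base_total * rng.lognormal(0.0, 0.25) for ph in phases}
        has_partner = rng.random() < 0.7
        partner = proteins[int(rng.integers(n_proteins))].protein_id if has_partner else None
        if partner is None:
            bound = {ph: 0.0 for ph in phases}
        else:
            bound = {ph: float(rng.beta(2.0, 5.0)) for ph in phases}
        metabolites.append(
            MetaboliteSpec(
                metabolite_id=mid, class_tag=tag, total=total, bound_fraction=bound, partner=partner
            )
        )

    _ = first  # phases anchor the rewiring convention: first vs last
    return GroundTruth(
        proteins=tuple(proteins),
        metabolites=tuple(metabolites),
        melt=melt,
        rewired_fractionation=frozenset(rewired_frac),
        rewired_stability=frozenset(rewired_stab),
        seed=seed,
    )


def _gaussian_shape(fractions: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((fractions - center) / width) ** 2)


def _restricted_unit_shape(fractions: np.ndarray, center: float, width: float, mask: np.ndarray) -> np.ndarray:
    shape = _gaussian_shape(fractions, center, width) * mask
    s = shape.sum()
    if s <= 0:
        raise ParameterError("peak falls entirely outside its allowed region")
    return shape / s


def _apply_noise(rng: np.random.Generator, values: np.ndarray, sigma: float, limit: float) -> np.ndarray:
    out = values if sigma == 0 else values * rng.lognormal(0.0, sigma, size=values.shape)
    if limit > 0:
        out = np.where(out < limit, 0.0, out)
    return out


def simulate_sec_profiles(truth: GroundTruth, config: SimConfig) -> list[ElutionProfile]:
    """Noisy elution profiles for every molecule, phase and replicate.

    With zero noise a metabolite profile sums exactly to its programmed
    total, of which ``bound_fraction`` lies in the protein-containing
    fractions under the partner's peaks.
    """
    rng = np.random.default_rng([truth.seed, 1])
    cal = config.calibration
    fr = np.arange(1, config.n_fractions + 1, dtype=float)
    bound_mask = (fr <= config.protein_fraction_count).astype(float)
    free_mask = 1.0 - bound_mask
    by_id = {p.protein_id: p for p in truth.proteins}
    out: list[ElutionProfile] = []

    for p in truth.proteins:
        for phase in config.phases:
            base = np.zeros_like(fr)
            for st in p.states[phase]:
                center = cal.fraction_at(st.mass_kda)
                shape = _gaussian_shape(fr, center, config.peak_width_fractions)
                base += st.mixing_fraction * p.abundance[phase] * shape / shape.sum()
            for rep in range(1, config.protein_profile_replicates + 1):
                noisy = _apply_noise(rng, base, config.noise_sigma, config.detection_limit)
                out.append(ElutionProfile(p.protein_id, "protein", phase, rep, noisy))

    for m in truth.metabolites:
        if m.partner is not None and m.partner not in by_id:
            raise ConsistencyError(f"{m.metabolite_id}: partner {m.partner} not simulated")
        for phase in config.phases:
            bf = m.bound_fraction[phase]
            base = np.zeros_like(fr)
            if bf > 0:
                partner = by_id[m.partner]
                shape = np.zeros_like(fr)
                for st in partner.states[phase]:
                    center = cal.fraction_at(st.mass_kda)
                    shape += st.mixing_fraction * _restricted_unit_shape(
                        fr, center, config.peak_width_fractions, bound_mask
                    )
                base += bf * m.total[phase] * shape / shape.sum()
            if bf < 1:
                free_shape = _restricted_unit_shape(
                    fr, config.free_pool_center, config.free_pool_width, free_mask
                )
                base += (1.0 - bf) * m.total[phase] * free_shape
            for rep in range(1, config.metabolite_replicates + 1):
                noisy = _apply_noise(rng, base, config.noise_sigma, config.detection_limit)
                out.append(ElutionProfile(m.metabolite_id, "metabolite", phase, rep, noisy))
    return out


def melting_sigmoid(temperature_c: float, params: MeltParams) -> float:
    """Soluble fraction remaining at a temperature; 0.5 at the midpoint."""
    return 1.0 / (1.0 + math.exp((temperature_c - params.midpoint_c) / params.slope_c))


def simulate_itsa(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Long table of soluble intensities: protein, phase, temperature, replicate.

    Intensity at an elevated temperature is abundance x sigmoid(melt, T) x
    multiplicative noise; at RT the sigmoid factor is 1.
    """
    rng = np.random.default_rng([truth.seed, 2])
    rows: list[tuple[str, str, str, int, float]] = []
    for p in truth.proteins:
        for phase in config.phases:
            for t_label in config.temperatures:
                params = truth.melt[p.protein_id][phase]
                if str(t_label).upper() == RT_LABEL:
                    frac = 1.0
                else:
                    frac = melting_sigmoid(temperature_celsius(t_label), params)
                mean = p.abundance[phase] * frac
                for rep in range(1, config.itsa_replicates + 1):
                    noise = 1.0 if config.noise_sigma == 0 else float(rng.lognormal(0.0, config.noise_sigma))
                    val = mean * noise
                    if config.detection_limit > 0 and val < config.detection_limit:
                        val = 0.0
                    rows.append((p.protein_id, phase, str(t_label), rep, val))
    return pd.DataFrame(rows, columns=["protein_id", "phase", "temperature", "replicate", "intensity"])


def simulate_abundance(truth: GroundTruth, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide protein-abundance matrix plus its sample sheet.

    Returns ``(values, samples)`` where ``values`` is proteins x sample ids
    and ``samples`` maps sample id -> (phase, replicate).
    """
    rng = np.random.default_rng([truth.seed, 3])
    sample_ids: list[str] = []
    meta: list[tuple[str, int]] = []
    cols: dict[str, np.ndarray] = {}
    base = np.array([[p.abundance[ph] for ph in config.phases] for p in truth.proteins])
    for j, phase in enumerate(config.phases):
        for rep in range(1, config.abundance_replicates + 1):
            sid = f"{phase}_r{rep}"
            noise = (
                np.ones(len(truth.proteins))
                if config.noise_sigma == 0
                else rng.lognormal(0.0, config.noise_sigma, size=len(truth.proteins))
            )
            cols[sid] = base[:, j] * noise
            sample_ids.append(sid)
            meta.append((phase, rep))
    values = pd.DataFrame(cols, index=truth.protein_ids())
    values.index.name = "protein_id"
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"), columns=["phase", "replicate"])
    return values, samples
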