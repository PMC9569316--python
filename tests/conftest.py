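import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cofrac.synthetic import (
    GroundTruth,
    MeltParams,
    MetaboliteSpec,
    OligomerState,
    ProteinSpec,
    SimConfig,
)

PHASES = ("glucose", "ethanol", "early_stationary")


@pytest.fixture
def zero_noise_config() -> SimConfig:
    return SimConfig(noise_sigma=0.0)


@pytest.fixture
def noisy_config() -> SimConfig:
    return SimConfig(noise_sigma=0.1)


def make_protein(pid: str, mass_kda: float, abundance: float = 1e6, length: int = 400,
                 states_by_phase=None) -> ProteinSpec:
    states = states_by_phase or {ph: (OligomerState(mass_kda, 1.0),) for ph in PHASES}
    return ProteinSpec(pid, length, {ph: abundance for ph in PHASES}, states)


def make_metabolite(mid: str, partner: str | None, bound: float, total: float = 1e4,
                    tag: str = "dipeptide", bound_by_phase=None) -> MetaboliteSpec:
    bf = bound_by_phase or {ph: bound for ph in PHASES}
    return MetaboliteSpec(mid, tag, {ph: total for ph in PHASES}, bf, partner)


def make_truth(proteins, metabolites, seed: int = 0, rewired_frac=(), rewired_stab=(),
               midpoint: float = 52.0, slope: float = 1.0) -> GroundTruth:
    melt = {
        p.protein_id: {ph: MeltParams(midpoint, slope) for ph in PHASES} for p in proteins
    }
    return GroundTruth(
        proteins=tuple(proteins),
        metabolites=tuple(metabolites),
        melt=melt,
        rewired_fractionation=frozenset(rewired_frac),
        rewired_stability=frozenset(rewired_stab),
        seed=seed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
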