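"""Pipeline configuration: one validated document drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .synthetic import SimConfig


@dataclass
class PipelineConfig:
    """Thresholds, labels and seeds for an end-to-end run.

    Defaults mirror the documented analysis: abundance and stability calls
    at FDR 0.01 with fold change 2, metabolite totals at FDR 0.05, the
    Manhattan factor 1.5, peak retention at 10% of the main maximum, PCC
    edges at 0.7, Ward cut height 1.6.
    """

    outdir: str = "cofrac_out"
    simulate: bool = True
    n_proteins: int = 200
    n_metabolites: int = 60
    rewire_rate: float = 0.2
    seed: int = 0
    phases: tuple[str, ...] = ("glucose", "ethanol", "early_stationary")
    boundary_fraction: int = 40
    fdr_abundance: float = 0.01
    fdr_stability: float = 0.01
    fdr_totals: float = 0.05
    fc_threshold: float = 2.0
    md_factor: float = 1.5
    min_rel_height: float = 0.10
    min_separation: int = 2
    pcc_threshold: float = 0.7
    cut_height: float = 1.6
    n_permutations: int = 200
    sim: SimConfig = field(default_factory=SimConfig)
    profiles_path: str | None = None
    itsa_path: str | None = None
    abundance_path: str | None = None
    samples_path: str | None = None

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("fdr_abundance", self.fdr_abundance, 0.0, 1.0),
            ("fdr_stability", self.fdr_stability, 0.0, 1.0),
            ("fdr_totals", self.fdr_totals, 0.0, 1.0),
            ("min_rel_height", self.min_rel_height, 0.0, 1.0),
            ("rewire_rate", self.rewire_rate, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise ParameterError(f"{name}={value} outside [{lo}, {hi}]")
        if self.fc_threshold < 1:
            raise ParameterError("fc_threshold must be >= 1")
        if self.md_factor < 0:
            raise ParameterError("md_factor must be >= 0")
        if not -1.0 < self.pcc_threshold <= 1.0:
            raise ParameterError("pcc_threshold must lie in (-1, 1]")
        if not self.simulate and self.profiles_path is None:
            raise ParameterError("without simulate=true, profiles_path is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**doc.pop("sim", {}))
        if "phases" in doc:
            doc["phases"] = tuple(doc["phases"])
        return cls(sim=sim, **doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["phases"] = list(self.phases)
        doc["sim"] = asdict(self.sim)
        doc["sim"]["phases"] = list(self.sim.phases)
        doc["sim"]["temperatures"] = list(self.sim.temperatures)
        doc["sim"]["mw_calibration"] = list(self.sim.mw_calibration)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
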