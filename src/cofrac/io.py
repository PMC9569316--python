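"""Readers and writers for the package's plain-text dialects.

Profile dialect: long TSV with header
``molecule_id  molecule_class  phase  replicate  fraction  intensity``
(1-based integer fractions). iTSA dialect: long TSV with header
``protein_id  phase  temperature  replicate  intensity``. Abundance
matrices are wide TSVs (rows features, columns sample ids) with a
sample-sheet CSV (sample_id, phase, replicate). Ground truth round-trips
through a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .errors import ValidationError
from .itsa import ITSA_COLUMNS
from .profiles import ElutionProfile
from . import synthetic as syn

PROFILE_COLUMNS = ["molecule_id", "molecule_class", "phase", "replicate", "fraction", "intensity"]


def write_profiles(profiles: Iterable[ElutionProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for f, v in enumerate(p.intensities, start=1):
            rows.append((p.molecule_id, p.molecule_class, p.phase, p.replicate, f, v))
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    # canonical row order so write -> read -> write is byte-identical
    df = df.sort_values(["molecule_id", "molecule_class", "phase", "replicate", "fraction"])
    df.to_csv(path, sep="\t", index=False)


def read_profiles(
    path: str | Path,
    n_fractions: int | None = None,
    known_phases: Sequence[str] | None = None,
) -> list[ElutionProfile]:
    """Parse and validate the long profile TSV into typed profiles."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["molecule_id", "phase", "replicate", "fraction"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:5]  # +2: header and 1-based lines
        raise ValidationError(f"{path}: duplicate rows at lines {lines}")
    if (df["intensity"] < 0).any():
        lines = (df.index[df["intensity"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"{path}: negative intensity at lines {lines}")
    if known_phases is not None:
        unknown = set(df["phase"]) - set(known_phases)
        if unknown:
            raise ValidationError(f"{path}: unknown phase labels {sorted(unknown)}")

    out: list[ElutionProfile] = []
    for (mid, mclass, phase, rep), sub in df.groupby(
        ["molecule_id", "molecule_class", "phase", "replicate"], sort=True
    ):
        sub = sub.sort_values("fraction")
        fr = sub["fraction"].to_numpy()
        n = n_fractions or int(df["fraction"].max())
        if not np.array_equal(fr, np.arange(1, n + 1)):
            raise ValidationError(f"{path}: {mid}/{phase}/r{rep} does not cover fractions 1..{n}")
        out.append(ElutionProfile(str(mid), str(mclass), str(phase), int(rep), sub["intensity"].to_numpy()))
    return out


def write_itsa(records: pd.DataFrame, path: str | Path) -> None:
    records[ITSA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_itsa(path: str | Path, known_phases: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"temperature": str}, float_precision="round_trip")
    missing = set(ITSA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if (df["intensity"] < 0).any():
        lines = (df.index[df["intensity"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"{path}: negative intensity at lines {lines}")
    if known_phases is not None:
        unknown = set(df["phase"]) - set(known_phases)
        if unknown:
            raise ValidationError(f"{path}: unknown phase labels {sorted(unknown)}")
    dup = df.duplicated(subset=["protein_id", "phase", "temperature", "replicate"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:5]
        raise ValidationError(f"{path}: duplicate rows at lines {lines}")
    return df


def write_abundance(matrix: AbundanceMatrix, matrix_path: str | Path, samples_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    matrix.samples.to_csv(samples_path)


def read_abundance(matrix_path: str | Path, samples_path: str | Path) -> AbundanceMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    samples = pd.read_csv(samples_path, index_col=0)
    if "phase" not in samples.columns or "replicate" not in samples.columns:
        raise ValidationError(f"{samples_path}: sample sheet needs phase and replicate columns")
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"{matrix_path}: negative intensities")
    return AbundanceMatrix(values=values, samples=samples)


def read_calibration_standards(path: str | Path) -> list[tuple[float, float]]:
    """Two-column CSV (fraction, mass_kDa) of reference standards."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns fraction, mass_kDa")
    return [(float(r.iloc[0]), float(r.iloc[1])) for _, r in df.iterrows()]


# -- ground truth JSON sidecar -------------------------------------------------


def truth_to_json(truth: syn.GroundTruth, path: str | Path) -> None:
    doc = {
        "seed": truth.seed,
        "rewired_fractionation": sorted(truth.rewired_fractionation),
        "rewired_stability": sorted(truth.rewired_stability),
        "proteins": [
            {
                "protein_id": p.protein_id,
                "length_aa": p.length_aa,
                "abundance": dict(p.abundance),
                "states": {
                    ph: [[st.mass_kda, st.mixing_fraction] for st in sts]
                    for ph, sts in p.states.items()
                },
            }
            for p in truth.proteins
        ],
        "metabolites": [
            {
                "metabolite_id": m.metabolite_id,
                "class_tag": m.class_tag,
                "total": dict(m.total),
                "bound_fraction": dict(m.bound_fraction),
                "partner": m.partner,
            }
            for m in truth.metabolites
        ],
        "melt": {
            pid: {ph: [mp.midpoint_c, mp.slope_c] for ph, mp in by_phase.items()}
            for pid, by_phase in truth.melt.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def truth_from_json(path: str | Path) -> syn.GroundTruth:
    doc = json.loads(Path(path).read_text())
    proteins = tuple(
        syn.ProteinSpec(
            protein_id=p["protein_id"],
            length_aa=int(p["length_aa"]),
            abundance=dict(p["abundance"]),
            states={
                ph: tuple(syn.OligomerState(mass_kda=m, mixing_fraction=w) for m, w in sts)
                for ph, sts in p["states"].items()
            },
        )
        for p in doc["proteins"]
    )
    metabolites = tuple(
        syn.MetaboliteSpec(
            metabolite_id=m["metabolite_id"],
            class_tag=m["class_tag"],
            total=dict(m["total"]),
            bound_fraction=dict(m["bound_fraction"]),
            partner=m["partner"],
        )
        for m in doc["metabolites"]
    )
    melt = {
        pid: {ph: syn.MeltParams(midpoint_c=v[0], slope_c=v[1]) for ph, v in by_phase.items()}
        for pid, by_phase in doc["melt"].items()
    }
    return syn.GroundTruth(
        proteins=proteins,
        metabolites=metabolites,
        melt=melt,
        rewired_fractionation=frozenset(doc["rewired_fractionation"]),
        rewired_stability=frozenset(doc["rewired_stability"]),
        seed=int(doc["seed"]),
    )
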