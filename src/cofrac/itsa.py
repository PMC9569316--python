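"""Isothermal shift assay processing.

Soluble-protein intensities measured after a fixed-temperature treatment are
median-normalized within each temperature group, scaled to the room
temperature (RT) abundance of the same protein/phase/replicate, and compared
between growth phases per temperature. The union of per-temperature
significant sets is the differential-thermal-stability set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, median_normalize, pairwise_calls
from .errors import ParameterError, ValidationError
from .synthetic import RT_LABEL

__all__ = ["normalize_thermal", "differential_stability", "stability_matrix"]

ITSA_COLUMNS = ["protein_id", "phase", "temperature", "replicate", "intensity"]


def _check_long(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(ITSA_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"iTSA table missing columns: {sorted(missing)}")
    df = records.copy()
    df["temperature"] = df["temperature"].astype(str).str.upper().str.replace("RT", RT_LABEL)
    dup = df.duplicated(subset=["protein_id", "phase", "temperature", "replicate"])
    if dup.any():
        raise ValidationError(f"duplicate iTSA rows at positions {list(df.index[dup])[:5]}")
    if (df["intensity"] < 0).any():
        raise ValidationError("negative iTSA intensity")
    return df


def normalize_thermal(records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein thermal stability values.

    Within each temperature group (all phases and replicates measured at
    that temperature) sample medians are equalized; stability is then the
    normalized intensity divided by the normalized RT intensity of the same
    protein, phase and replicate. RT stability is 1 by construction.
    Proteins with zero RT intensity are flagged unscalable (stability NaN).
    """
    df = _check_long(records)
    if RT_LABEL not in set(df["temperature"]):
        raise ParameterError("iTSA records must include RT measurements")

    normalized = []
    for temp, sub in df.groupby("temperature", sort=False):
        wide = sub.pivot_table(
            index="protein_id", columns=["phase", "replicate"], values="intensity", aggfunc="first"
        )
        samples = pd.DataFrame(
            [(p, r) for p, r in wide.columns],
            index=pd.Index([f"{p}~{r}" for p, r in wide.columns], name="sample_id"),
            columns=["phase", "replicate"],
        )
        wide.columns = samples.index
        norm = median_normalize(AbundanceMatrix(values=wide.fillna(0.0), samples=samples)).values
        long = norm.reset_index().melt(id_vars="protein_id", var_name="sample_id", value_name="norm_intensity")
        long[["phase", "replicate"]] = long["sample_id"].str.rsplit("~", n=1, expand=True)
        long["replicate"] = long["replicate"].astype(int)
        long["temperature"] = temp
        normalized.append(long.drop(columns="sample_id"))
    norm_df = pd.concat(normalized, ignore_index=True)

    rt = norm_df[norm_df["temperature"] == RT_LABEL][
        ["protein_id", "phase", "replicate", "norm_intensity"]
    ].rename(columns={"norm_intensity": "rt_intensity"})
    out = norm_df.merge(rt, on=["protein_id", "phase", "replicate"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["stability"] = np.where(out["rt_intensity"] > 0, out["norm_intensity"] / out["rt_intensity"], np.nan)
    out["scalable"] = out["rt_intensity"] > 0
    return out[["protein_id", "phase", "temperature", "replicate", "stability", "scalable"]]


def stability_matrix(stabilities: pd.DataFrame, temperature: str, phase: str) -> pd.DataFrame:
    """Proteins x replicates table of stability values at one condition."""
    sub = stabilities[
        (stabilities["temperature"] == str(temperature)) & (stabilities["phase"] == phase)
    ]
    return sub.pivot_table(index="protein_id", columns="replicate", values="stability", aggfunc="first")


def differential_stability(
    stabilities: pd.DataFrame,
    phase_a: str,
    phase_b: str,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    temperatures: tuple[str, ...] | None = None,
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Per-temperature differential calls plus the union significant set.

    Calls are computed independently at each elevated temperature with the
    shared t-test/BH machinery on stability values; a protein belongs to the
    differential-thermal-stability set if it is significant at any
    temperature.
    """
    if temperatures is None:
        temperatures = tuple(
            sorted(t for t in stabilities["temperature"].unique() if t != RT_LABEL)
        )
    calls: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    for temp in temperatures:
        a = stability_matrix(stabilities, temp, phase_a)
        b = stability_matrix(stabilities, temp, phase_b)
        shared = a.index.intersection(b.index)
        df = pairwise_calls(
            a.loc[shared],
            b.loc[shared],
            comparison=f"{phase_a}_vs_{phase_b}@{temp}",
            fdr_threshold=fdr_threshold,
            fc_threshold=fc_threshold,
        )
        calls[str(temp)] = df
        union |= set(df.loc[df["significant"], "feature_id"])
    return calls, union
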