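"""End-to-end orchestration of the analysis stages.

Every stage is a pure function of its inputs plus seeds from the config, so
a full run is reproducible and equals the composition of the stages run
individually. Outputs are TSV/JSON under ``config.outdir``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .abundance import AbundanceMatrix, differential_abundance
from .config import PipelineConfig
from .errors import ValidationError
from .fractionation import manhattan_differential
from .integration import compare_group_lengths, correlate_scalars, overlap_sets
from .itsa import differential_stability, normalize_thermal, stability_matrix
from .networks import build_network, detect_communities, peak_correlations, rate_matrix
from .pools import compare_ratio_distributions, differential_totals, summarize_pools
from .profiles import ElutionProfile, aggregate_replicates, deconvolve_peaks, normalize_to_max
from .synthetic import generate_ground_truth, simulate_abundance, simulate_itsa, simulate_sec_profiles

PATHWAYS = ("Gly/Glu", "TCA", "PPP")


def _aggregated_profiles(profiles: list[ElutionProfile]) -> dict[tuple[str, str], ElutionProfile]:
    """Replicate-mean profile per (molecule, phase)."""
    grouped: dict[tuple[str, str], list[ElutionProfile]] = {}
    for p in profiles:
        grouped.setdefault((p.molecule_id, p.phase), []).append(p)
    return {key: aggregate_replicates(reps) for key, reps in grouped.items()}


def stage_fractionation(
    aggregated: dict[tuple[str, str], ElutionProfile],
    phase_a: str,
    phase_b: str,
    molecule_class: str,
    md_factor: float,
) -> pd.DataFrame:
    prof_a = {
        mid: p.intensities
        for (mid, ph), p in aggregated.items()
        if ph == phase_a and p.molecule_class == molecule_class and p.intensities.sum() > 0
    }
    prof_b = {
        mid: p.intensities
        for (mid, ph), p in aggregated.items()
        if ph == phase_b and p.molecule_class == molecule_class and p.intensities.sum() > 0
    }
    return manhattan_differential(prof_a, prof_b, factor=md_factor)


def stage_networks(
    aggregated: dict[tuple[str, str], ElutionProfile],
    phase: str,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, nx.Graph, dict[str, int], float]:
    met_peaks, prot_peaks = [], []
    for (mid, ph), prof in aggregated.items():
        if ph != phase or prof.intensities.max(initial=0.0) <= 0:
            continue
        ps = deconvolve_peaks(
            normalize_to_max(prof),
            min_rel_height=cfg.min_rel_height,
            min_separation=cfg.min_separation,
        )
        (met_peaks if prof.molecule_class == "metabolite" else prot_peaks).append(ps)
    corr = peak_correlations(met_peaks, prot_peaks)
    graph = build_network(corr, threshold=cfg.pcc_threshold)
    partition, modularity = detect_communities(graph, seed=cfg.seed)
    return corr, graph, partition, modularity


def _demo_pathway_assignment(protein_ids: list[str]) -> dict[str, tuple[str, ...]]:
    """Deterministic stand-in pathway labels for simulated proteins."""
    return {pid: (PATHWAYS[i % len(PATHWAYS)],) for i, pid in enumerate(sorted(protein_ids))}


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ------------------------------------------------------------------ inputs
    if config.simulate:
        truth = generate_ground_truth(
            config.sim, config.n_proteins, config.n_metabolites, config.rewire_rate, config.seed
        )
        profiles = simulate_sec_profiles(truth, config.sim)
        itsa_records = simulate_itsa(truth, config.sim)
        ab_values, ab_samples = simulate_abundance(truth, config.sim)
        matrix = AbundanceMatrix(values=ab_values, samples=ab_samples)
        cio.truth_to_json(truth, out / "ground_truth.json")
        cio.write_profiles(profiles, out / "profiles.tsv")
        cio.write_itsa(itsa_records, out / "itsa.tsv")
        cio.write_abundance(matrix, out / "abundance.tsv", out / "samples.csv")
        results["truth"] = truth
    else:
        profiles = cio.read_profiles(config.profiles_path, known_phases=config.phases)
        if not profiles:
            raise ValidationError("no profiles in input")
        itsa_records = cio.read_itsa(config.itsa_path, known_phases=config.phases) if config.itsa_path else None
        matrix = (
            cio.read_abundance(config.abundance_path, config.samples_path)
            if config.abundance_path
            else None
        )

    phases = list(config.phases)
    first, last = phases[0], phases[-1]
    pairs = [(a, b) for i, a in enumerate(phases) for b in phases[i + 1 :]]

    # --------------------------------------------------------------- abundance
    if matrix is not None:
        ab_calls = {}
        for a, b in pairs:
            calls = differential_abundance(
                matrix, a, b, fdr_threshold=config.fdr_abundance, fc_threshold=config.fc_threshold
            )
            calls.to_csv(out / f"abundance_calls_{a}_vs_{b}.tsv", sep="\t", index=False)
            ab_calls[(a, b)] = calls
        results["abundance_calls"] = ab_calls

    # -------------------------------------------------------------------- itsa
    stab = None
    stability_union: set[str] = set()
    if itsa_records is not None:
        stab = normalize_thermal(itsa_records)
        stab.to_csv(out / "stability_values.tsv", sep="\t", index=False)
        per_temp, stability_union = differential_stability(
            stab, first, last, fdr_threshold=config.fdr_stability, fc_threshold=config.fc_threshold
        )
        for temp, calls in per_temp.items():
            calls.to_csv(out / f"stability_calls_{first}_vs_{last}_{temp}.tsv", sep="\t", index=False)
        pd.Series(sorted(stability_union), name="protein_id").to_csv(
            out / f"stability_union_{first}_vs_{last}.tsv", sep="\t", index=False
        )
        results["stability_calls"] = per_temp
        results["stability_union"] = stability_union

    # ----------------------------------------------------------- fractionation
    aggregated = _aggregated_profiles(profiles)
    frac_calls = {}
    for a, b in pairs:
        for mclass in ("protein", "metabolite"):
            df = stage_fractionation(aggregated, a, b, mclass, config.md_factor)
            df.to_csv(out / f"fractionation_{mclass}_{a}_vs_{b}.tsv", sep="\t", index=False)
            frac_calls[(a, b, mclass)] = df
    results["fractionation"] = frac_calls

    # ------------------------------------------------------------------- pools
    met_profiles = [p for p in profiles if p.molecule_class == "metabolite"]
    if met_profiles:
        summaries = summarize_pools(met_profiles, boundary_fraction=config.boundary_fraction)
        summaries.to_csv(out / "pool_summaries.tsv", sep="\t", index=False)
        totals = differential_totals(
            met_profiles, last, first, fdr_threshold=config.fdr_totals, fc_threshold=config.fc_threshold
        )
        totals.to_csv(out / f"total_calls_{last}_vs_{first}.tsv", sep="\t", index=False)
        medians, ratio_tests = compare_ratio_distributions(summaries)
        ratio_tests.to_csv(out / "ratio_tests.tsv", sep="\t", index=False)
        results["pool_summaries"] = summaries
        results["pool_medians"] = medians
        results["total_calls"] = totals

    # ---------------------------------------------------------------- networks
    networks = {}
    for phase in phases:
        corr, graph, partition, modularity = stage_networks(aggregated, phase, config)
        corr.to_csv(out / f"correlations_{phase}.tsv", sep="\t", index=False)
        nx.write_graphml(graph, out / f"network_{phase}.graphml")
        pd.Series(partition, name="community").rename_axis("node").to_csv(
            out / f"communities_{phase}.tsv", sep="\t"
        )
        networks[phase] = {"graph": graph, "partition": partition, "modularity": modularity, "correlations": corr}
    results["networks"] = networks

    protein_ids = sorted({p.molecule_id for p in profiles if p.molecule_class == "protein"})
    dipeptide_groups = {
        m.molecule_id: "dipeptide"
        for m in met_profiles
        if config.simulate and m.molecule_id in _dipeptide_ids(results.get("truth"))
    } if config.simulate else {}
    if dipeptide_groups:
        pathway_groups = _demo_pathway_assignment(protein_ids)
        phase_rates = []
        for phase in phases:
            met_peaks, prot_peaks = _phase_peaksets(aggregated, phase, config)
            rm = rate_matrix(
                met_peaks, prot_peaks, networks[phase]["correlations"], dipeptide_groups,
                pathway_groups, threshold=config.pcc_threshold,
            )
            rm.insert(0, "phase", phase)
            phase_rates.append(rm)
        rates = pd.concat(phase_rates, ignore_index=True)
        rates.to_csv(out / "interaction_rates.tsv", sep="\t", index=False)
        results["interaction_rates"] = rates

    # ------------------------------------------------------------- integration
    if stab is not None:
        frac_df = frac_calls[(first, last, "protein")]
        frac_set = set(frac_df.loc[frac_df["differential_by_md"], "molecule_id"])
        universe = set(frac_df["molecule_id"]) | stability_union | set(protein_ids)
        report = overlap_sets(
            stability_union & universe, frac_set & universe, universe,
            label_a="thermal_stability", label_b="fractionation",
        )
        results["overlap"] = report
        overlap_rows = [
            {"section": k, "count": v} for k, v in report.counts.items()
        ]
        pd.DataFrame(overlap_rows).to_csv(out / "overlap_report.tsv", sep="\t", index=False)

        if config.simulate:
            lengths = {p.protein_id: float(p.length_aa) for p in results["truth"].proteins}
            assignment = {pid: "fractionation_only" for pid in report.only_b}
            assignment.update({pid: "stability_only" for pid in report.only_a})
            if len({v for v in assignment.values()}) >= 2:
                medians, tests = compare_group_lengths(assignment, lengths)
                results["length_comparison"] = (medians, tests)
                tests.to_csv(out / "length_tests.tsv", sep="\t", index=False)

        # abundance at RT vs stability at the highest elevated temperature
        top_temp = sorted(config.sim.elevated_temperatures)[-1]
        stab_last = stability_matrix(stab, top_temp, last).mean(axis=1)
        if matrix is not None:
            mean_ab = matrix.values[[c for c in matrix.values.columns
                                     if matrix.samples.loc[c, "phase"] == last]].mean(axis=1)
            shared = stab_last.index.intersection(mean_ab.index)
            if len(shared) >= 3:
                r, p = correlate_scalars(np.log2(mean_ab.loc[shared]), stab_last.loc[shared])
                results["abundance_stability_correlation"] = (r, p)

    # ----------------------------------------------------------------- summary
    summary = {
        "phases": phases,
        "n_profiles": len(profiles),
        "thresholds": {
            "fdr_abundance": config.fdr_abundance,
            "fdr_stability": config.fdr_stability,
            "fdr_totals": config.fdr_totals,
            "fc_threshold": config.fc_threshold,
            "md_factor": config.md_factor,
            "min_rel_height": config.min_rel_height,
            "pcc_threshold": config.pcc_threshold,
        },
        "counts": {},
    }
    if "abundance_calls" in results:
        summary["counts"]["differential_abundance"] = {
            f"{a}_vs_{b}": int(calls["significant"].sum()) for (a, b), calls in results["abundance_calls"].items()
        }
    if stab is not None:
        summary["counts"]["differential_stability_union"] = len(stability_union)
    summary["counts"]["differential_fractionation"] = {
        f"{a}_vs_{b}_{mc}": int(df["differential_by_md"].sum())
        for (a, b, mc), df in frac_calls.items()
    }
    if "total_calls" in results:
        tc = results["total_calls"]
        summary["counts"]["metabolite_totals"] = {
            "increased": int((tc["significant"] & (tc["log2_fc"] > 0)).sum()),
            "decreased": int((tc["significant"] & (tc["log2_fc"] < 0)).sum()),
        }
    if "pool_medians" in results:
        summary["median_bound_free_ratio"] = {k: float(v) for k, v in results["pool_medians"].items()}
    if "networks" in results:
        summary["counts"]["communities"] = {
            phase: int(len(set(info["partition"].values()))) for phase, info in networks.items()
        }
    if "overlap" in results:
        summary["counts"]["overlap"] = results["overlap"].counts
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    results["summary"] = summary
    return results


def _dipeptide_ids(truth) -> set[str]:
    if truth is None:
        return set()
    return {m.metabolite_id for m in truth.metabolites if m.class_tag == "dipeptide"}


def _phase_peaksets(aggregated, phase, cfg: PipelineConfig):
    met, prot = [], []
    for (mid, ph), prof in aggregated.items():
        if ph != phase or prof.intensities.max(initial=0.0) <= 0:
            continue
        ps = deconvolve_peaks(
            normalize_to_max(prof), min_rel_height=cfg.min_rel_height, min_separation=cfg.min_separation
        )
        (met if prof.molecule_class == "metabolite" else prot).append(ps)
    return met, prot
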