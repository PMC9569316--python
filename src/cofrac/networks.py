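"""Co-fractionation correlation networks and interaction-rate matrices.

Peaks (post-deconvolution subprofiles) are correlated pairwise; edges at or
above the PCC threshold form the network. Communities come from seeded
Louvain; dipeptide-group x pathway interaction rates follow the percentage
formula rate = 100 * n_interactions / (n_dipeptide_peaks * n_protein_peaks).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ParameterError, UndefinedRateError, ValidationError
from .profiles import PeakSet

__all__ = [
    "peak_correlations",
    "build_network",
    "detect_communities",
    "interaction_rate",
    "rate_matrix",
    "ward_group",
]


def _node_name(ps: PeakSet, peak_index: int) -> str:
    return f"{ps.molecule_id}#{peak_index}"


def peak_correlations(peaks_a: Sequence[PeakSet], peaks_b: Sequence[PeakSet]) -> pd.DataFrame:
    """Pearson correlation between every cross pair of deconvolved peaks.

    The correlation is computed over the union of the two peaks' fraction
    ranges (subprofiles are zero outside their own bounds). Pairs where
    either windowed subprofile is constant are skipped.
    """
    rows = []
    for psa in peaks_a:
        for i, pa in enumerate(psa.peaks):
            for psb in peaks_b:
                if psb.molecule_id == psa.molecule_id:
                    continue
                for j, pb in enumerate(psb.peaks):
                    lo = min(pa.left_bound, pb.left_bound) - 1
                    hi = max(pa.right_bound, pb.right_bound)
                    x = pa.subprofile[lo:hi]
                    y = pb.subprofile[lo:hi]
                    if np.ptp(x) == 0 or np.ptp(y) == 0:
                        continue
                    pcc = float(np.corrcoef(x, y)[0, 1])
                    rows.append(
                        (
                            _node_name(psa, i),
                            _node_name(psb, j),
                            psa.molecule_id,
                            psb.molecule_id,
                            psa.molecule_class,
                            psb.molecule_class,
                            pcc,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["node_a", "node_b", "molecule_a", "molecule_b", "class_a", "class_b", "pcc"],
    )


def build_network(
    correlations: pd.DataFrame,
    threshold: float = 0.7,
    nodes: Iterable[tuple[str, dict]] | None = None,
) -> nx.Graph:
    """Graph of peak nodes with edges at PCC >= threshold.

    Nodes supplied via ``nodes`` are retained even when isolated (flagged
    with ``isolated=True``).
    """
    if not -1.0 < threshold <= 1.0:
        raise ParameterError("threshold must lie in (-1, 1]")
    g = nx.Graph(threshold=threshold)
    if nodes is not None:
        for name, attrs in sorted(nodes):
            g.add_node(name, **attrs)
    kept = correlations[correlations["pcc"] >= threshold]
    for row in kept.itertuples(index=False):
        if row.node_a == row.node_b:
            continue
        g.add_edge(row.node_a, row.node_b, weight=float(row.pcc))
    for n in g.nodes:
        g.nodes[n]["isolated"] = g.degree(n) == 0
    return g


def detect_communities(
    network: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> tuple[dict[str, int], float]:
    """Seeded Louvain partition plus its modularity.

    Node order is canonicalized (sorted) before clustering so the result
    depends only on the graph, the seed and the resolution. Communities are
    numbered by decreasing size, ties broken by smallest member.
    """
    if network.number_of_nodes() == 0:
        return {}, float("nan")
    canon = nx.Graph()
    canon.add_nodes_from(sorted(network.nodes))
    canon.add_edges_from(
        (u, v, d) for u, v, d in sorted(network.edges(data=True), key=lambda e: (e[0], e[1]))
    )
    comms = nx.community.louvain_communities(canon, weight="weight", seed=seed, resolution=resolution)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    partition = {node: idx for idx, comm in enumerate(ordered) for node in comm}
    if canon.number_of_edges() == 0:
        modularity = float("nan")
    else:
        modularity = float(nx.community.modularity(canon, ordered, weight="weight"))
    return partition, modularity


def interaction_rate(n_interactions: int, n_dipeptide_peaks: int, n_protein_peaks: int) -> float:
    """Percentage of observed interactions among all possible peak pairs."""
    if n_dipeptide_peaks < 1 or n_protein_peaks < 1:
        raise UndefinedRateError("peak counts must be >= 1")
    possible = n_dipeptide_peaks * n_protein_peaks
    if not 0 <= n_interactions <= possible:
        raise ParameterError("n_interactions outside [0, possible interactions]")
    return 100.0 * n_interactions / possible


def rate_matrix(
    metabolite_peaks: Sequence[PeakSet],
    protein_peaks: Sequence[PeakSet],
    correlations: pd.DataFrame,
    dipeptide_groups: Mapping[str, str],
    pathway_groups: Mapping[str, Iterable[str]],
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Group x pathway interaction rates from a peak correlation table.

    Every dipeptide belongs to exactly one group; a protein may sit in
    several pathways and then contributes its peaks (and interactions) to
    each of them independently. An interaction is a metabolite-protein peak
    pair with PCC >= threshold.
    """
    met_peak_count: dict[str, int] = {}
    for ps in metabolite_peaks:
        if ps.molecule_id in dipeptide_groups:
            met_peak_count[ps.molecule_id] = len(ps.peaks)
    prot_peak_count = {ps.molecule_id: len(ps.peaks) for ps in protein_peaks}

    group_peaks: dict[str, int] = {}
    for mid, grp in dipeptide_groups.items():
        group_peaks[grp] = group_peaks.get(grp, 0) + met_peak_count.get(mid, 0)
    pathway_peaks: dict[str, int] = {}
    for pid, pws in pathway_groups.items():
        for pw in pws:
            pathway_peaks[pw] = pathway_peaks.get(pw, 0) + prot_peak_count.get(pid, 0)

    hits = correlations[correlations["pcc"] >= threshold]
    counts: dict[tuple[str, str], int] = {}
    for row in hits.itertuples(index=False):
        met, prot = None, None
        if row.class_a == "metabolite" and row.class_b == "protein":
            met, prot = row.molecule_a, row.molecule_b
        elif row.class_a == "protein" and row.class_b == "metabolite":
            met, prot = row.molecule_b, row.molecule_a
        if met is None or met not in dipeptide_groups:
            continue
        grp = dipeptide_groups[met]
        for pw in pathway_groups.get(prot, ()):
            counts[(grp, pw)] = counts.get((grp, pw), 0) + 1

    rows = []
    for grp in sorted(group_peaks):
        for pw in sorted(pathway_peaks):
            n_dp, n_pp = group_peaks[grp], pathway_peaks[pw]
            n_int = counts.get((grp, pw), 0)
            if n_dp == 0 or n_pp == 0:
                rows.append((grp, pw, n_int, n_dp, n_pp, np.nan))
                continue
            rows.append((grp, pw, n_int, n_dp, n_pp, interaction_rate(n_int, n_dp, n_pp)))
    return pd.DataFrame(
        rows,
        columns=["dipeptide_group", "pathway", "n_interactions", "n_dipeptide_peaks", "n_protein_peaks", "rate"],
    )


def ward_group(distance_matrix: pd.DataFrame | np.ndarray, cut_height: float = 1.6) -> pd.Series:
    """Ward agglomeration of a precomputed distance matrix cut at a height.

    Returns integer group labels (1-based) indexed by item name.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    return pd.Series(flat, index=labels, name="group")
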