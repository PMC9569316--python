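import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cofrac.errors import ParameterError, UndefinedRateError, ValidationError
from cofrac.networks import (
    build_network,
    detect_communities,
    interaction_rate,
    peak_correlations,
    rate_matrix,
    ward_group,
)
from cofrac.profiles import ElutionProfile, deconvolve_peaks, normalize_to_max
from oracles import pearson_from_covariance, ward_linkage_heights, weighted_modularity


def peakset(values, mid, mclass="protein", phase="glucose"):
    prof = ElutionProfile(mid, mclass, phase, 1, np.asarray(values, dtype=float))
    return deconvolve_peaks(normalize_to_max(prof))


def gaussian(n, center, width=2.0, height=1.0):
    f = np.arange(1, n + 1, dtype=float)
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


class TestPeakCorrelations:
    def test_identical_subprofiles_pcc_one(self):
        v = gaussian(40, 15)
        corr = peak_correlations([peakset(v, "A", "metabolite")], [peakset(v, "B")])
        assert corr["pcc"].iloc[0] == pytest.approx(1.0)

    def test_mirror_subprofiles_pcc_minus_one(self):
        from cofrac.profiles import Peak, PeakSet

        a = np.array([0.0, 1, 2, 3, 2, 1, 0])
        b = 3.0 - a
        psa = PeakSet("A", "glucose", (Peak(4, 1, 7, 1.0, a),), "metabolite")
        psb = PeakSet("B", "glucose", (Peak(1, 1, 7, 1.0, b),), "protein")
        corr = peak_correlations([psa], [psb])
        assert corr["pcc"].iloc[0] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_covariance_oracle(self, rng):
        for _ in range(25):
            a = rng.uniform(0.05, 1, 30)
            b = rng.uniform(0.05, 1, 30)
            pa = peakset(a, "A", "metabolite")
            pb = peakset(b, "B")
            corr = peak_correlations([pa], [pb])
            for row in corr.itertuples(index=False):
                i = int(row.node_a.split("#")[1])
                j = int(row.node_b.split("#")[1])
                lo = min(pa.peaks[i].left_bound, pb.peaks[j].left_bound) - 1
                hi = max(pa.peaks[i].right_bound, pb.peaks[j].right_bound)
                expected = pearson_from_covariance(
                    pa.peaks[i].subprofile[lo:hi], pb.peaks[j].subprofile[lo:hi]
                )
                assert row.pcc == pytest.approx(expected, abs=1e-12)

    def test_same_molecule_not_paired(self):
        v = gaussian(40, 15)
        corr = peak_correlations([peakset(v, "A")], [peakset(v, "A")])
        assert corr.empty


class TestBuildNetwork:
    def make_corr(self, rng, n=30):
        rows = [
            (f"a{i}#0", f"b{i}#0", f"a{i}", f"b{i}", "metabolite", "protein", rng.uniform(-1, 1))
            for i in range(n)
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "molecule_a", "molecule_b", "class_a", "class_b", "pcc"]
        )

    def test_threshold_one_keeps_only_perfect(self, rng):
        corr = self.make_corr(rng)
        corr.loc[0, "pcc"] = 1.0
        g = build_network(corr, threshold=1.0)
        assert g.number_of_edges() == 1

    def test_edge_count_matches_brute_force(self, rng):
        corr = self.make_corr(rng, n=100)
        for thr in (-0.5, 0.0, 0.7, 0.95):
            g = build_network(corr, threshold=thr)
            assert g.number_of_edges() == int((corr["pcc"] >= thr).sum())

    def test_isolated_nodes_retained_and_flagged(self, rng):
        corr = self.make_corr(rng, n=5)
        corr["pcc"] = 0.2
        g = build_network(corr, threshold=0.9, nodes=[("lonely#0", {"molecule_class": "protein"})])
        assert "lonely#0" in g
        assert g.nodes["lonely#0"]["isolated"]

    def test_invalid_threshold(self, rng):
        with pytest.raises(ParameterError):
            build_network(self.make_corr(rng), threshold=-1.0)


class TestDetectCommunities:
    def test_two_disconnected_cliques(self):
        g = nx.Graph()
        for offset in (0, 5):
            for u, v in itertools.combinations(range(offset, offset + 5), 2):
                g.add_edge(f"n{u}", f"n{v}", weight=1.0)
        partition, modularity = detect_communities(g, seed=0)
        communities = {frozenset(n for n, c in partition.items() if c == k) for k in set(partition.values())}
        expected = {frozenset(f"n{i}" for i in range(5)), frozenset(f"n{i}" for i in range(5, 10))}
        assert communities == expected
        assert modularity == pytest.approx(0.5)

    def test_singletons_each_own_community(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        partition, _ = detect_communities(g, seed=0)
        assert len(set(partition.values())) == 3

    def test_partition_covers_all_nodes_once(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=5)
        nx.set_edge_attributes(g, 1.0, "weight")
        partition, _ = detect_communities(g, seed=1)
        assert set(partition) == set(g.nodes)

    def test_modularity_reported_matches_oracle_and_beats_trivial(self):
        g = nx.Graph()
        for offset in (0, 6):
            for u, v in itertools.combinations(range(offset, offset + 6), 2):
                g.add_edge(u, v, weight=0.8)
        g.add_edge(0, 6, weight=0.8)
        partition, modularity = detect_communities(g, seed=0)
        edges = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
        oracle = weighted_modularity(edges, partition, list(g.nodes))
        assert modularity == pytest.approx(oracle, abs=1e-12)
        trivial = weighted_modularity(edges, {n: 0 for n in g.nodes}, list(g.nodes))
        assert modularity >= trivial

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.1, seed=9)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert detect_communities(g, seed=3) == detect_communities(g, seed=3)

    def test_empty_graph(self):
        partition, q = detect_communities(nx.Graph(), seed=0)
        assert partition == {}


class TestInteractionRate:
    @pytest.mark.parametrize(
        "n_int,n_dp,n_pp,expected",
        [(0, 3, 4, 0.0), (12, 3, 4, 100.0), (6, 3, 4, 50.0)],
    )
    def test_printed_formula(self, n_int, n_dp, n_pp, expected):
        assert interaction_rate(n_int, n_dp, n_pp) == expected

    def test_zero_peaks_undefined(self):
        with pytest.raises(UndefinedRateError):
            interaction_rate(0, 0, 4)

    def test_too_many_interactions(self):
        with pytest.raises(ParameterError):
            interaction_rate(13, 3, 4)


def _toy_rate_inputs():
    # two dipeptides in one group; three proteins in two pathways
    m1 = peakset(gaussian(40, 10), "D1", "metabolite")   # 1 peak
    m2 = peakset(gaussian(40, 10) + gaussian(40, 25, height=0.5), "D2", "metabolite")  # 2 peaks
    p1 = peakset(gaussian(40, 10), "E1")
    p2 = peakset(gaussian(40, 25), "E2")
    p3 = peakset(gaussian(40, 33), "E3")
    groups = {"D1": "G", "D2": "G"}
    pathways = {"E1": ("glycolysis",), "E2": ("glycolysis", "tca"), "E3": ("tca",)}
    corr = peak_correlations([m1, m2], [p1, p2, p3])
    return [m1, m2], [p1, p2, p3], corr, groups, pathways


class TestRateMatrix:
    def test_hand_counted_rates(self):
        mets, prots, corr, groups, pathways = _toy_rate_inputs()
        rm = rate_matrix(mets, prots, corr, groups, pathways).set_index(["dipeptide_group", "pathway"])
        # brute-force enumeration of qualifying pairs per pathway
        hits = corr[corr["pcc"] >= 0.7]
        for pw, members in (("glycolysis", {"E1", "E2"}), ("tca", {"E2", "E3"})):
            n_int = int(hits["molecule_b"].isin(members).sum())
            n_pp = sum(len(p.peaks) for p in prots if p.molecule_id in members)
            expected = 100.0 * n_int / (3 * n_pp)  # group G has 3 dipeptide peaks
            assert rm.loc[("G", pw), "rate"] == pytest.approx(expected)

    def test_relabeling_invariance(self):
        mets, prots, corr, groups, pathways = _toy_rate_inputs()
        base = rate_matrix(mets, prots, corr, groups, pathways)
        mapping = {"D1": "Z9", "D2": "Z8", "E1": "Q1", "E2": "Q2", "E3": "Q3"}
        corr2 = corr.copy()
        for col in ("molecule_a", "molecule_b"):
            corr2[col] = corr2[col].map(lambda x: mapping.get(x, x))
        for col in ("node_a", "node_b"):
            corr2[col] = corr2[col].map(lambda s: mapping[s.split("#")[0]] + "#" + s.split("#")[1])
        import dataclasses
        mets2 = [dataclasses.replace(ps, molecule_id=mapping[ps.molecule_id]) for ps in mets]
        prots2 = [dataclasses.replace(ps, molecule_id=mapping[ps.molecule_id]) for ps in prots]
        groups2 = {mapping[k]: v for k, v in groups.items()}
        pathways2 = {mapping[k]: v for k, v in pathways.items()}
        renamed = rate_matrix(mets2, prots2, corr2, groups2, pathways2)
        pd.testing.assert_frame_equal(
            base.sort_values(["dipeptide_group", "pathway"]).reset_index(drop=True),
            renamed.sort_values(["dipeptide_group", "pathway"]).reset_index(drop=True),
        )

    def test_raising_threshold_never_increases_rates(self):
        mets, prots, corr, groups, pathways = _toy_rate_inputs()
        prev = None
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9, 0.99):
            rm = rate_matrix(mets, prots, corr, groups, pathways, threshold=thr)
            rates = rm.set_index(["dipeptide_group", "pathway"])["rate"]
            if prev is not None:
                assert (rates <= prev + 1e-12).all()
            prev = rates

    def test_no_edges_all_rates_zero(self):
        mets, prots, corr, groups, pathways = _toy_rate_inputs()
        rm = rate_matrix(mets, prots, corr.iloc[0:0], groups, pathways)
        assert (rm["rate"].dropna() == 0.0).all()


class TestWardGroup:
    def make_two_blobs(self):
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        d = np.abs(pts - pts.T)
        return pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))

    def test_two_far_sets_two_groups(self):
        labels = ward_group(self.make_two_blobs(), cut_height=5.0)
        assert labels.nunique() == 2
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]

    def test_cut_zero_all_singletons(self):
        labels = ward_group(self.make_two_blobs(), cut_height=0.0)
        assert labels.nunique() == 6

    def test_linkage_heights_match_brute_force(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 5, size=(6, 2))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            from scipy.cluster import hierarchy
            from scipy.spatial.distance import squareform

            z = hierarchy.linkage(squareform(d, checks=False), method="ward")
            np.testing.assert_allclose(sorted(z[:, 2]), sorted(ward_linkage_heights(d)), rtol=1e-9)

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            ward_group(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            ward_group(np.array([[1.0, 1.0], [1.0, 0.0]]))
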