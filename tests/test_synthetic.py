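import numpy as np
import pytest

from conftest import make_metabolite, make_protein, make_truth
from cofrac.errors import ConsistencyError, ParameterError
from cofrac.profiles import deconvolve_peaks, normalize_to_max
from cofrac.synthetic import (
    MeltParams,
    SimConfig,
    generate_ground_truth,
    melting_sigmoid,
    simulate_abundance,
    simulate_itsa,
    simulate_sec_profiles,
    temperature_celsius,
)


def by_key(profiles):
    return {(p.molecule_id, p.phase, p.replicate): p for p in profiles}


class TestGenerateGroundTruth:
    def test_zero_rewire_rate_empty_sets(self, zero_noise_config):
        t = generate_ground_truth(zero_noise_config, 20, 5, 0.0, 3)
        assert t.rewired_fractionation == frozenset()
        assert t.rewired_stability == frozenset()

    def test_same_seed_identical(self, zero_noise_config):
        a = generate_ground_truth(zero_noise_config, 15, 6, 0.3, 42)
        b = generate_ground_truth(zero_noise_config, 15, 6, 0.3, 42)
        assert a == b

    def test_rewired_set_size_in_binomial_band(self, zero_noise_config):
        sizes = [
            len(generate_ground_truth(zero_noise_config, 100, 1, 0.2, s).rewired_fractionation)
            for s in range(50)
        ]
        mean = np.mean(sizes)
        # mean of 50 Binomial(100, 0.2) draws: 99% band is 20 +- 2.576*sqrt(16/50)
        half = 2.576 * np.sqrt(100 * 0.2 * 0.8 / 50)
        assert 20 - half <= mean <= 20 + half

    def test_invalid_parameters(self, zero_noise_config):
        with pytest.raises(ParameterError):
            generate_ground_truth(zero_noise_config, 0, 5, 0.2, 1)
        with pytest.raises(ParameterError):
            generate_ground_truth(zero_noise_config, 5, 5, 1.2, 1)

    def test_partners_exist(self, zero_noise_config):
        t = generate_ground_truth(zero_noise_config, 30, 40, 0.2, 9)
        ids = set(t.protein_ids())
        for m in t.metabolites:
            if any(bf > 0 for bf in m.bound_fraction.values()):
                assert m.partner in ids

    def test_mixing_fractions_sum_to_one(self, zero_noise_config):
        t = generate_ground_truth(zero_noise_config, 30, 5, 0.2, 9)
        for p in t.proteins:
            for states in p.states.values():
                assert sum(s.mixing_fraction for s in states) == pytest.approx(1.0)


class TestSimulateSecProfiles:
    def test_noiseless_apex_at_mapped_fraction(self, zero_noise_config):
        mass = zero_noise_config.calibration.mass_at(17)
        truth = make_truth([make_protein("P1", mass)], [make_metabolite("M1", None, 0.0)])
        profs = by_key(simulate_sec_profiles(truth, zero_noise_config))
        v = profs[("P1", "glucose", 1)].intensities
        assert int(v.argmax()) + 1 == 17

    def test_unbound_metabolite_all_in_free_region(self, zero_noise_config):
        truth = make_truth(
            [make_protein("P1", 100.0)], [make_metabolite("M1", None, 0.0)]
        )
        profs = by_key(simulate_sec_profiles(truth, zero_noise_config))
        v = profs[("M1", "glucose", 1)].intensities
        assert v[:40].sum() == 0.0
        assert v[40:].sum() > 0.0

    def test_bound_fraction_recovered_exactly(self, zero_noise_config):
        truth = make_truth(
            [make_protein("P1", 100.0)], [make_metabolite("M1", "P1", 0.6)]
        )
        profs = by_key(simulate_sec_profiles(truth, zero_noise_config))
        v = profs[("M1", "glucose", 1)].intensities
        assert v[:40].sum() / v.sum() == pytest.approx(0.6, rel=1e-12)

    def test_conservation_zero_noise(self, zero_noise_config):
        truth = generate_ground_truth(zero_noise_config, 10, 8, 0.2, 5)
        totals = {m.metabolite_id: m.total for m in truth.metabolites}
        for p in simulate_sec_profiles(truth, zero_noise_config):
            if p.molecule_class == "metabolite":
                assert p.intensities.sum() == pytest.approx(totals[p.molecule_id][p.phase], rel=1e-9)

    def test_determinism_bit_identical(self, noisy_config):
        t = generate_ground_truth(noisy_config, 12, 6, 0.2, 77)
        a = simulate_sec_profiles(t, noisy_config)
        b = simulate_sec_profiles(t, noisy_config)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.intensities, pb.intensities)

    def test_apexes_map_back_to_programmed_masses(self, zero_noise_config):
        truth = generate_ground_truth(zero_noise_config, 25, 1, 0.0, 13)
        cal = zero_noise_config.calibration
        profs = simulate_sec_profiles(truth, zero_noise_config)
        specs = {p.protein_id: p for p in truth.proteins}
        for prof in profs:
            if prof.molecule_class != "protein":
                continue
            states = specs[prof.molecule_id].states[prof.phase]
            ps = deconvolve_peaks(normalize_to_max(prof))
            programmed = sorted(cal.fraction_at(s.mass_kda) for s in states)
            apexes = sorted(p.apex_fraction for p in ps.peaks)
            assert len(apexes) == len(programmed)
            for apex, f in zip(apexes, programmed):
                assert abs(apex - f) <= 0.5

    def test_missing_partner_raises(self, zero_noise_config):
        with pytest.raises(ConsistencyError):
            make_truth([make_protein("P1", 100.0)], [make_metabolite("M1", "P9", 0.5)])

    def test_nonnegative_with_noise(self, noisy_config):
        t = generate_ground_truth(noisy_config, 8, 5, 0.2, 21)
        for p in simulate_sec_profiles(t, noisy_config):
            assert (p.intensities >= 0).all()

    def test_detection_limit_zeroes_small_values(self):
        cfg = SimConfig(noise_sigma=0.0, detection_limit=1.0)
        truth = make_truth([make_protein("P1", 100.0, abundance=100.0)], [make_metabolite("M1", None, 0.0)])
        for p in simulate_sec_profiles(truth, cfg):
            assert ((p.intensities == 0) | (p.intensities >= 1.0)).all()


class TestSimulateItsa:
    def test_ratio_half_at_midpoint(self, zero_noise_config):
        truth = make_truth(
            [make_protein("P1", 100.0)], [make_metabolite("M1", None, 0.0)], midpoint=52.0
        )
        df = simulate_itsa(truth, zero_noise_config)
        sub = df[(df.phase == "glucose") & (df.replicate == 1)].set_index("temperature")
        assert sub.loc["52", "intensity"] / sub.loc["RT", "intensity"] == pytest.approx(0.5)

    def test_midpoint_shift_raises_soluble_fraction(self):
        base = MeltParams(50.0, 1.0)
        shifted = MeltParams(54.0, 1.0)
        for t in (48.0, 52.0, 56.0):
            assert melting_sigmoid(t, shifted) > melting_sigmoid(t, base)

    def test_monte_carlo_replicate_means_near_noiseless(self, noisy_config, zero_noise_config):
        truth = generate_ground_truth(noisy_config, 1000, 1, 0.0, 99)
        noisy = simulate_itsa(truth, noisy_config)
        clean = simulate_itsa(truth, zero_noise_config)

        def ratios(df):
            wide = df.pivot_table(
                index=["protein_id", "phase", "replicate"], columns="temperature", values="intensity"
            )
            return (wide["52"] / wide["RT"]).groupby(["protein_id", "phase"])

        noisy_groups = ratios(noisy)
        clean_ratio = ratios(clean).mean()
        mean = noisy_groups.mean()
        sem = noisy_groups.sem()
        within = (np.abs(mean - clean_ratio) <= 3 * sem)
        # with n=5 the 3-SEM band is a t(4) interval (~96% coverage)
        assert within.mean() >= 0.93

    def test_rt_label_and_celsius(self):
        assert temperature_celsius("RT") == 22.0
        assert temperature_celsius("56") == 56.0


class TestSimulateAbundance:
    def test_shape_and_determinism(self, noisy_config):
        t = generate_ground_truth(noisy_config, 9, 2, 0.1, 8)
        v1, s1 = simulate_abundance(t, noisy_config)
        v2, _ = simulate_abundance(t, noisy_config)
        assert v1.shape == (9, 15)
        assert (s1["phase"].value_counts() == 5).all()
        assert v1.equals(v2)

    def test_zero_noise_matches_programmed_abundance(self, zero_noise_config):
        t = make_truth([make_protein("P1", 100.0, abundance=123.0)], [make_metabolite("M1", None, 0.0)])
        v, s = simulate_abundance(t, zero_noise_config)
        assert (v.loc["P1"] == 123.0).all()


class TestConfigValidation:
    def test_bad_boundary(self):
        with pytest.raises(ParameterError):
            SimConfig(n_fractions=60, protein_fraction_count=60)

    def test_negative_noise(self):
        with pytest.raises(ParameterError):
            SimConfig(noise_sigma=-0.1)

    def test_rt_required(self):
        with pytest.raises(ParameterError):
            SimConfig(temperatures=("48", "52"))

    def test_bound_fraction_range_enforced(self):
        with pytest.raises(ConsistencyError):
            make_truth([make_protein("P1", 100.0)], [make_metabolite("M1", "P1", 1.2)])
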