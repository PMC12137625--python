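"""Virtual-ecologist generator: contracts, determinism, and bias structure."""

import numpy as np
import pytest
from scipy import stats

import surveygap as sg
from surveygap.occurrences import assign_to_grid
from surveygap.synthetic import (effort_weights_from_bias, simulate_visits,
                                 species_from_coefficients)

from conftest import morans_i


class TestGenerateLandscape:
    def test_shape_and_group_contract(self, landscape):
        assert len(landscape.env_layers) == 4
        assert len(landscape.driver_layers) == 6
        groups = list(landscape.driver_groups.values())
        assert sorted(set(groups)) == ["accessibility", "attractiveness", "safety"]
        assert all(groups.count(g) == 2 for g in set(groups))
        for layer in {**landscape.env_layers, **landscape.driver_layers}.values():
            assert layer.shape == (20, 20)
            assert np.all(np.isfinite(layer))

    def test_deterministic_given_seed(self):
        a = sg.generate_landscape(10, 10, 3, 1, smoothness=2, seed=42)
        b = sg.generate_landscape(10, 10, 3, 1, smoothness=2, seed=42)
        for name in a.env_layers:
            np.testing.assert_array_equal(a.env_layers[name], b.env_layers[name])
        for name in a.driver_layers:
            np.testing.assert_array_equal(a.driver_layers[name], b.driver_layers[name])

    def test_smoothing_raises_spatial_autocorrelation(self):
        smooth = sg.generate_landscape(20, 20, 2, 1, smoothness=3, seed=5)
        rough = sg.generate_landscape(20, 20, 2, 1, smoothness=0, seed=5)
        assert morans_i(smooth.env_layers["env_1"]) > morans_i(rough.env_layers["env_1"])

    @pytest.mark.parametrize("bad", [(3, 10), (10, 3)])
    def test_rejects_tiny_grids(self, bad):
        with pytest.raises(ValueError):
            sg.generate_landscape(*bad, n_env=2, n_drivers_per_group=1, seed=0)


class TestGenerateSpecies:
    def test_zero_coefficients_give_half_suitability(self, landscape):
        sp = species_from_coefficients(landscape, "flat", np.zeros(4), 0.0, seed=0)
        np.testing.assert_allclose(sp.true_suitability, 0.5)

    def test_prevalence_contract(self, landscape):
        spp = sg.generate_species(landscape, 50, beta_scale=1.0, seed=7)
        assert len(spp) == 50
        prevs = [s.prevalence for s in spp]
        assert all(0 < p < 1 for p in prevs)
        assert 0.05 <= float(np.median(prevs)) <= 0.5
        for s in spp[:5]:
            assert s.prevalence == s.true_presence.mean()

    def test_strong_beta_ties_suitability_to_layer(self, landscape):
        # moderate slope keeps the logistic link in its near-linear range,
        # so the Pearson correlation with the driving layer stays high
        sp = species_from_coefficients(landscape, "strong", np.array([2.0, 0, 0, 0]),
                                       0.0, seed=0)
        r = np.corrcoef(sp.true_suitability.ravel(),
                        landscape.env_layers["env_1"].ravel())[0, 1]
        assert r > 0.9

    def test_rejects_empty_request(self, landscape):
        with pytest.raises(ValueError):
            sg.generate_species(landscape, 0, seed=0)


class TestSampling:
    def test_unbiased_effort_is_uniform(self, landscape):
        # chi-square GOF of visit counts vs uniform, alpha = 0.01, 20 seeds
        n_ok = 0
        for seed in range(20):
            design = sg.SamplingDesign(total_effort=4000, seed=seed)
            visits = simulate_visits(design, landscape, driver_bias=None)
            _, p = stats.chisquare(visits.ravel())
            if p > 0.01:
                n_ok += 1
        assert n_ok >= 19

    def test_census_recovers_true_richness(self, landscape, species):
        design = sg.SamplingDesign(total_effort=1, detection_prob=1.0, seed=0,
                                   exhaustive=True)
        occ = sg.sample_occurrences(species, design, None, landscape)
        recorded = assign_to_grid(occ, landscape.grid)
        for sp in species:
            assert recorded.get(sp.species_id, set()) == sp.presence_cells()

    def test_negative_safety_bias_repels_effort(self, landscape):
        design = sg.SamplingDesign(total_effort=4000, seed=3)
        visits = simulate_visits(design, landscape, {"safety_1": -2.0})
        rho = stats.spearmanr(visits.ravel(),
                              landscape.driver_layers["safety_1"].ravel()).statistic
        assert rho < -0.5

    @pytest.mark.parametrize("bias", [-1.0, 1.0])
    def test_bias_sign_recovered_in_visit_ranks(self, landscape, bias):
        design = sg.SamplingDesign(total_effort=2000, seed=11)
        visits = simulate_visits(design, landscape, {"accessibility_1": bias})
        rho = stats.spearmanr(visits.ravel(),
                              landscape.driver_layers["accessibility_1"].ravel()).statistic
        assert abs(rho) > 0.3 and np.sign(rho) == np.sign(bias)

    def test_conservation_and_truthfulness(self, landscape, species):
        design = sg.SamplingDesign(total_effort=500, detection_prob=0.7, seed=9)
        occ = sg.sample_occurrences(species, design, None, landscape)
        assert len(occ) <= design.total_effort * len(species)
        truth = {sp.species_id: sp.presence_cells() for sp in species}
        recorded = assign_to_grid(occ, landscape.grid)
        for sp_id, cells in recorded.items():
            assert cells <= truth[sp_id]  # never record where truly absent

    def test_effort_weights_normalised_and_uniform_without_bias(self, landscape):
        w = effort_weights_from_bias(landscape, None)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, w.flat[0])

    def test_empty_species_list_rejected(self, landscape):
        design = sg.SamplingDesign(total_effort=10, seed=0)
        with pytest.raises(ValueError):
            sg.sample_occurrences([], design, None, landscape)

    def test_same_seed_same_records(self, landscape, species):
        design = sg.SamplingDesign(total_effort=300, detection_prob=0.5, seed=21)
        a = sg.sample_occurrences(species, design, {"safety_2": -1.0}, landscape)
        b = sg.sample_occurrences(species, design, {"safety_2": -1.0}, landscape)
        assert a.equals(b)


class TestQaStack:
    def test_no_clouds_means_all_valid(self):
        valid, water = sg.generate_qa_stack(8, 8, 50, np.full((8, 8), 0.2),
                                            cloud_prob=0.0, seed=0)
        assert np.all(valid == 50)
        assert np.all(water <= valid)

    def test_certain_water_fills_valid(self):
        valid, water = sg.generate_qa_stack(8, 8, 50, np.ones((8, 8)),
                                            cloud_prob=0.3, seed=1)
        np.testing.assert_array_equal(water, valid)

    def test_half_probability_recovered(self):
        valid, water = sg.generate_qa_stack(30, 30, 200, np.full((30, 30), 0.5),
                                            cloud_prob=0.2, seed=2)
        freq = water / valid
        assert 0.45 <= freq.mean() <= 0.55

    def test_rejects_bad_cloud_prob(self):
        with pytest.raises(ValueError):
            sg.generate_qa_stack(4, 4, 10, np.zeros((4, 4)), cloud_prob=1.0, seed=0)
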