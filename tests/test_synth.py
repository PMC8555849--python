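"""Generator behaviour: determinism, bias recovery, heterogeneity decay."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from benthoscape.grids import DepthGrid, PredictorStack
from benthoscape.synth import (
    CLASS_CODES,
    CODE_TO_CLASS,
    SamplerScheme,
    SeafloorParams,
    TruthParams,
    bayes_rule,
    classify_index,
    measure_bathymetry,
    sample_observations,
    simulate_bathymetry,
    simulate_truth,
)
from benthoscape.obsprep import assign_zone


def _small_params(**kw) -> SeafloorParams:
    return SeafloorParams(shape=(120, 120), cell=25.0, **kw)


def _energy_stack(bathy: DepthGrid, seed: int = 0) -> PredictorStack:
    """Minimal fetch/tide/slope stack for truth generation."""
    from benthoscape.evalx import synthesize_energy
    from benthoscape.terrain import BpiSpec, FetchSpec, build_stack

    tide, circ = synthesize_energy(bathy, seed)
    return build_stack(
        bathy, tide=tide, circulation=circ,
        bpi_specs=(BpiSpec(0, 3, "fine"), BpiSpec(0, 6, "medium"), BpiSpec(0, 12, "broad")),
        fetch_spec=FetchSpec(bearings=16, cap=3000.0),
        resolution_class="regional",
    )


class TestBathymetry:
    def test_same_seed_bit_identical(self):
        p = _small_params(seed=42)
        a, b = simulate_bathymetry(p), simulate_bathymetry(p)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        a = simulate_bathymetry(_small_params(seed=1))
        b = simulate_bathymetry(_small_params(seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_zero_amplitudes_monotone_seaward(self):
        p = _small_params(ridge_amplitude=0.0, noise_amplitude=0.0, seed=5)
        g = simulate_bathymetry(p)
        assert (np.diff(g.values, axis=0) >= 0).all()

    def test_land_fraction_tracks_target_across_seeds(self):
        target = 0.15
        hits = 0
        for seed in range(50):
            g = simulate_bathymetry(_small_params(seed=seed))
            if abs(g.land.mean() - target) <= 0.05:
                hits += 1
        assert hits >= 45

    def test_landmass_is_connected_and_carries_elevations(self):
        from scipy import ndimage

        g = simulate_bathymetry(_small_params(seed=9))
        land = g.land
        _, n_components = ndimage.label(land)
        assert n_components == 1
        assert np.isfinite(g.values[land]).all()  # elevations, not nodata
        assert (g.values[land] <= 0).all()

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            SeafloorParams(shape=(8, 8))

    def test_survey_artefacts_touch_only_marine_cells(self):
        g = simulate_bathymetry(_small_params(seed=3))
        m = measure_bathymetry(g, amplitude=1.0, seed=1)
        assert np.array_equal(m.values[g.land], g.values[g.land])
        assert not np.array_equal(m.values[g.marine], g.values[g.marine])
        assert measure_bathymetry(g, amplitude=0.0, seed=1) is g


@pytest.fixture(scope="module")
def truth_scene():
    bathy = simulate_bathymetry(_small_params(seed=7))
    return bathy, _energy_stack(bathy)


@pytest.fixture(scope="module")
def sampler_scene():
    bathy = simulate_bathymetry(_small_params(seed=13))
    stack = _energy_stack(bathy, 13)
    truth = simulate_truth(
        bathy, TruthParams(label_noise=0.0, seed=13), stack, decay_scale=30.0
    )
    return bathy, truth


class TestTruth:

    def test_determinism_without_noise_and_with(self, truth_scene):
        bathy, stack = truth_scene
        tp = TruthParams(noise_sd=0.0, label_noise=0.0, seed=3)
        assert np.array_equal(
            simulate_truth(bathy, tp, stack), simulate_truth(bathy, tp, stack)
        )
        tp2 = TruthParams(seed=3)
        assert np.array_equal(
            simulate_truth(bathy, tp2, stack), simulate_truth(bathy, tp2, stack)
        )

    def test_unreachable_thresholds_give_all_mud(self, truth_scene):
        bathy, stack = truth_scene
        tp = TruthParams(thresholds=(50.0, 60.0, 70.0), noise_sd=0.0, label_noise=0.0)
        truth = simulate_truth(bathy, tp, stack)
        assert (truth[bathy.marine] == CLASS_CODES["Mud"]).all()

    def test_missing_energy_layer_and_bad_thresholds_rejected(self, truth_scene):
        bathy, stack = truth_scene
        partial = PredictorStack(geometry=bathy)
        partial.add("tide", stack["tide"])
        with pytest.raises(ValueError, match="missing layer"):
            simulate_truth(bathy, TruthParams(), partial)
        with pytest.raises(ValueError, match="strictly increasing"):
            TruthParams(thresholds=(0.5, 0.1, 0.9))

    def test_class_prevalence_stays_in_band_across_seeds(self):
        # every class between 5% and 60% of marine cells, 20 seeds
        for seed in range(20):
            bathy = simulate_bathymetry(_small_params(seed=seed))
            stack = _energy_stack(bathy, seed)
            tp = dataclasses.replace(TruthParams(), seed=seed)
            truth = simulate_truth(bathy, tp, stack, decay_scale=30.0)
            marine = truth[bathy.marine]
            for code in (1, 2, 3, 4):
                share = (marine == code).mean()
                assert 0.05 <= share <= 0.60, (seed, CODE_TO_CLASS[code], share)

    def test_label_noise_flip_rate_matches(self, truth_scene):
        bathy, stack = truth_scene
        clean = simulate_truth(
            bathy, TruthParams(noise_sd=0.0, label_noise=0.0, seed=11), stack
        )
        noisy = simulate_truth(
            bathy, TruthParams(noise_sd=0.0, label_noise=0.2, seed=11), stack
        )
        marine = bathy.marine
        rate = (clean[marine] != noisy[marine]).mean()
        assert rate == pytest.approx(0.2, abs=0.02)

    def test_bayes_rule_is_noise_free_truth(self, truth_scene):
        bathy, stack = truth_scene
        tp = TruthParams(noise_sd=0.0, label_noise=0.0, seed=2)
        assert np.array_equal(bayes_rule(bathy, tp, stack), simulate_truth(bathy, tp, stack))

    def test_heterogeneity_decays_with_depth(self):
        # mean count of distinct classes in 5x5 windows strictly
        # decreases from the 0-5 zone through 20-50 to 100-200
        def window_diversity(truth, bathy, zone):
            zones = assign_zone(np.clip(bathy.values, -1, None))
            nr, nc = truth.shape
            counts = []
            for r in range(0, nr - 5, 3):
                for c in range(0, nc - 5, 3):
                    win = truth[r : r + 5, c : c + 5]
                    if (win == 0).any():
                        continue
                    if zones[r + 2, c + 2] != zone:
                        continue
                    counts.append(len(np.unique(win)))
            return np.mean(counts) if counts else np.nan

        shallower, mid, deep = [], [], []
        for seed in range(10):
            p = SeafloorParams(shape=(150, 150), cell=25.0, shelf_gradient=60.0, seed=seed)
            bathy = simulate_bathymetry(p)
            stack = _energy_stack(bathy, seed)
            truth = simulate_truth(
                bathy, dataclasses.replace(TruthParams(), seed=seed), stack,
                decay_scale=p.decay_scale,
            )
            shallower.append(window_diversity(truth, bathy, "0-5"))
            mid.append(window_diversity(truth, bathy, "20-50"))
            deep.append(window_diversity(truth, bathy, "100-200"))
        assert np.nanmean(shallower) > np.nanmean(mid) > np.nanmean(deep)


class TestSampler:
    def test_depth_window_respected(self, sampler_scene):
        bathy, truth = sampler_scene
        s = SamplerScheme("dive", (0.0, 20.0), n=500, seed=1)
        obs = sample_observations(truth, bathy, s)
        assert ((obs["depth_m"] > 0) & (obs["depth_m"] <= 20)).all()
        assert len(obs) == 500
        assert (obs["source"] == "dive").all()

    def test_determinism_and_empty_window(self, sampler_scene):
        bathy, truth = sampler_scene
        s = SamplerScheme("grab", (0.0, 50.0), n=200, seed=5)
        a = sample_observations(truth, bathy, s)
        b = sample_observations(truth, bathy, s)
        assert a.equals(b)
        with pytest.raises(ValueError, match="no eligible cells"):
            sample_observations(
                truth, bathy, SamplerScheme("rov", (5000.0, 6000.0), n=10)
            )

    def test_unbiased_sampler_matches_map_prevalence(self, sampler_scene):
        bathy, truth = sampler_scene
        s = SamplerScheme("grab", (0.0, 100.0), n=20_000, seed=2)
        obs = sample_observations(truth, bathy, s)
        window = bathy.marine & (bathy.values > 0) & (bathy.values <= 100) & (truth > 0)
        for code, cls in CODE_TO_CLASS.items():
            p = (truth[window] == code).mean()
            if p == 0:
                continue
            share = (obs["class"] == cls).mean()
            half = stats.norm.ppf(0.995) * np.sqrt(p * (1 - p) / len(obs))
            assert abs(share - p) <= half + 1e-9, cls

    def test_rock_bias_two_matches_weighted_sampling_closed_form(self, sampler_scene):
        bathy, truth = sampler_scene
        bias = {"Rock": 2.0, "Mixed": 1.0, "Sand": 1.0, "Mud": 1.0}
        s = SamplerScheme("grab", (0.0, 100.0), bias=bias, n=20_000, seed=3)
        obs = sample_observations(truth, bathy, s)
        window = bathy.marine & (bathy.values > 0) & (bathy.values <= 100) & (truth > 0)
        p_rock = (truth[window] == CLASS_CODES["Rock"]).mean()
        expected = 2 * p_rock / (1 + p_rock)
        share = (obs["class"] == "Rock").mean()
        half = stats.norm.ppf(0.995) * np.sqrt(expected * (1 - expected) / len(obs))
        assert share == pytest.approx(expected, abs=half + 1e-9)

    def test_bias_multipliers_recoverable_from_sample(self, sampler_scene):
        # estimated multiplier = (sample share / map share), normalized
        # to the Mud class; recovered within 10% at n = 50,000
        bathy, truth = sampler_scene
        bias = {"Rock": 3.0, "Mixed": 1.5, "Sand": 1.0, "Mud": 1.0}
        s = SamplerScheme("grab", (0.0, 100.0), bias=bias, n=50_000, seed=4)
        obs = sample_observations(truth, bathy, s)
        window = bathy.marine & (bathy.values > 0) & (bathy.values <= 100) & (truth > 0)
        est = {}
        for code, cls in CODE_TO_CLASS.items():
            p = (truth[window] == code).mean()
            est[cls] = (obs["class"] == cls).mean() / p
        for cls in bias:
            ratio = (est[cls] / est["Mud"]) / (bias[cls] / bias["Mud"])
            assert abs(ratio - 1) <= 0.10, cls

    def test_jitter_keeps_points_on_marine_cells(self, sampler_scene):
        bathy, truth = sampler_scene
        s = SamplerScheme("dive", (0.0, 30.0), n=2000, jitter_sd=10.0, seed=6)
        obs = sample_observations(truth, bathy, s)
        r, c = bathy.index_of(obs["x"].to_numpy(), obs["y"].to_numpy())
        assert bathy.marine[r, c].all()


def test_classify_index_ordering():
    e = np.array([[-1.0, -0.2, 0.0, 0.2, 1.0]])
    codes = classify_index(e, (-0.15, 0.10, 0.35))
    assert list(codes[0]) == [4, 4, 3, 2, 1]  # Mud..Rock with rising energy
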