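import numpy as np
import pytest
from scipy import stats

from aposcan.cone_mapping import camera_sensitivities, catch_matrix
from aposcan.spectral import CAMERA_CHANNELS, DEFAULT_WAVELENGTHS
from aposcan.synthetic import (
    DEFAULT_DILUTIONS,
    SyntheticWorldConfig,
    default_archetypes,
    default_world_config,
    generate_reflectance_library,
    generate_world,
    mortality_probability,
    simulate_bioassay,
    simulate_camera_image,
    simulate_field_predation,
)
from aposcan.types import ReflectanceSpectrum


def flat_spectrum(value, wl=DEFAULT_WAVELENGTHS):
    return ReflectanceSpectrum(wl, np.full(wl.shape, float(value)))


class TestReflectanceLibrary:
    def test_deterministic_under_seed(self):
        a = generate_reflectance_library(1, seed=7)
        b = generate_reflectance_library(1, seed=7)
        np.testing.assert_array_equal(a[0].reflectance, b[0].reflectance)

    def test_values_in_unit_interval(self):
        for s in generate_reflectance_library(50, seed=3):
            assert np.all(s.reflectance >= 0) and np.all(s.reflectance <= 1)

    def test_variance_vanishes_with_smoothness(self):
        # oracle: per-spectrum variance across wavelengths, averaged over the
        # library, must decrease as the bandwidth grows
        mean_vars = []
        for smoothness in (100.0, 1000.0, 5000.0):
            lib = generate_reflectance_library(40, smoothness, seed=5)
            mean_vars.append(np.mean([s.reflectance.var() for s in lib]))
        assert mean_vars[0] > mean_vars[1] > mean_vars[2]
        assert mean_vars[2] < 1e-3

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_reflectance_library(0)


class TestCameraSimulation:
    def test_gamma_one_is_proportional_to_catches(self):
        spectra = {f"r{i}": s for i, s in
                   enumerate(generate_reflectance_library(3, seed=11))}
        img = simulate_camera_image(spectra, camera_gamma=1.0, noise_sd=0.0,
                                    quantise=False)
        cam = camera_sensitivities(DEFAULT_WAVELENGTHS)
        _, W = catch_matrix({c: cam[c] for c in CAMERA_CHANNELS},
                            DEFAULT_WAVELENGTHS)
        stack = img.channel_stack()
        for name, spec in spectra.items():
            mask = img.region_mask(img.region_polygons[name])
            measured = stack[mask].mean(axis=0) / 255.0
            np.testing.assert_allclose(measured, W @ spec.reflectance,
                                       atol=1e-10)

    def test_zero_reflectance_gives_zero(self):
        img = simulate_camera_image({"black": flat_spectrum(0.0)},
                                    noise_sd=0.0, quantise=False)
        mask = img.region_mask(img.region_polygons["black"])
        assert np.all(img.channel_stack()[mask] == 0)

    def test_standard_ratio_closed_form(self):
        # oracle: raw ratio of the 4% and 99% standards is (0.04/0.99)^(1/2.2)
        img = simulate_camera_image(
            {"x": flat_spectrum(0.5)}, camera_gamma=2.2,
            grey_standards=(0.04, 0.40, 0.99), noise_sd=0.0, quantise=False)
        stack = img.channel_stack()
        lo = stack[img.region_mask(img.standard_polygons[0.04])].mean()
        hi = stack[img.region_mask(img.standard_polygons[0.99])].mean()
        assert lo / hi == pytest.approx((0.04 / 0.99) ** (1 / 2.2), rel=1e-12)

    def test_missing_40_standard_rejected(self):
        with pytest.raises(ValueError, match="0.40"):
            simulate_camera_image({"x": flat_spectrum(0.5)},
                                  grey_standards=(0.02, 0.99))

    def test_empty_region_map_rejected(self):
        with pytest.raises(ValueError):
            simulate_camera_image({})

    def test_quantised_output_is_uint8(self):
        img = simulate_camera_image({"x": flat_spectrum(0.5)}, noise_sd=1.0)
        assert img.vis.dtype == np.uint8 and img.uv.dtype == np.uint8


class TestBioassay:
    def test_zero_toxicity_zero_background_all_alive(self):
        recs = simulate_bioassay(0.0, background_rate=0.0, seed=2)
        assert all(r.dead == 0 for r in recs)

    def test_counts_bounded_and_monotone_in_time(self):
        recs = simulate_bioassay(8.0, seed=9)
        assert all(0 <= r.dead <= 10 for r in recs)
        for dose in DEFAULT_DILUTIONS:
            series = [r.dead for r in recs if r.dilution == dose]
            assert series == sorted(series)

    def test_binomial_expectation(self):
        # oracle: mean dead over many replicates equals 10 * p(dose, t)
        tox, dose = 2.6, 1.0
        p = mortality_probability(dose, 3.0, tox)
        assert 0.3 < p < 0.7  # regime check: near the binomial mid-range
        rng = np.random.default_rng(0)
        total = sum(simulate_bioassay(tox, dilutions=(dose,), times=(3.0,),
                                      seed=rng)[0].dead
                    for _ in range(10_000))
        assert total / 10_000 == pytest.approx(10 * p, abs=0.1)

    def test_monotone_in_dose(self):
        ps = [mortality_probability(d, 3.0, 5.0) for d in
              (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_bad_dilution_rejected(self):
        with pytest.raises(ValueError):
            simulate_bioassay(1.0, dilutions=(1.2,))


class TestFieldPredation:
    def test_zero_baseline_all_censored(self):
        recs = simulate_field_predation([("red", 2.0)] * 20, baseline_hazard=0.0)
        assert all(not r.event and r.time == 48.0 for r in recs)

    def test_times_on_check_grid(self):
        recs = simulate_field_predation([("red", 1.0)] * 500,
                                        baseline_hazard=0.05, seed=3,
                                        censor_fraction=0.1)
        grid = set(np.arange(4.0, 52.0, 4.0))
        assert all(r.time in grid for r in recs)

    def test_null_hazard_coefficient_attack_rate_independent_of_jnd(self):
        # oracle: chi-square across colours is non-significant under the null
        models = [(f"c{k}", float(k)) for k in range(5)] * 2000
        recs = simulate_field_predation(models, hazard_coefficient=0.0,
                                        baseline_hazard=0.02, seed=8)
        attacked = {}
        totals = {}
        for r in recs:
            totals[r.colour_label] = totals.get(r.colour_label, 0) + 1
            attacked[r.colour_label] = attacked.get(r.colour_label, 0) + r.event
        table = np.array([[attacked[c], totals[c] - attacked[c]]
                          for c in sorted(totals)])
        assert stats.chi2_contingency(table)[1] > 0.01

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            simulate_field_predation([("red", 1.0)], baseline_hazard=-0.1)

    def test_grid_must_divide_window(self):
        with pytest.raises(ValueError):
            simulate_field_predation([("red", 1.0)], check_interval=5.0,
                                     admin_censor_time=48.0)


class TestWorld:
    def test_replay_equality(self):
        cfg = default_world_config(seed=5, honesty_slope=1.0)
        w1 = generate_world(cfg, n_per_species=4, n_leaves=3)
        w2 = generate_world(cfg, n_per_species=4, n_leaves=3)
        assert w1.specimens.equals(w2.specimens)
        for sid in w1.elytra_spectra:
            np.testing.assert_array_equal(w1.elytra_spectra[sid].reflectance,
                                          w2.elytra_spectra[sid].reflectance)
        assert w1.bioassay == w2.bioassay

    def test_archetype_catches_positive(self):
        for arch in default_archetypes():
            assert np.all(arch.elytra_catch.singles() > 0)
            assert np.all(arch.background_catch.singles() > 0)

    def test_bad_gamma_rejected(self):
        with pytest.raises(ValueError):
            SyntheticWorldConfig(camera_gamma=0.0)

    def test_honesty_slope_strengthens_species_level_correlation(self):
        # equal-toxicity archetypes: any correlation comes from the slope
        base = default_archetypes()
        from dataclasses import replace
        arches = tuple(replace(a, true_toxicity=4.0) for a in base)
        mean_corr = []
        for slope in (0.0, 0.2, 0.6):
            corrs = []
            for rep in range(50):
                cfg = SyntheticWorldConfig(seed=1000 + rep,
                                           species_archetypes=arches,
                                           honesty_slope=slope)
                w = generate_world(cfg, n_per_species=6, n_leaves=3,
                                   toxicity_noise_sd=1.5)
                sp = w.specimens.groupby("species")[
                    ["true_jnd", "true_toxicity"]].mean()
                corrs.append(np.corrcoef(sp.true_jnd, sp.true_toxicity)[0, 1])
            mean_corr.append(np.mean(corrs))
        assert mean_corr[0] < mean_corr[1] < mean_corr[2]
        assert abs(mean_corr[0]) < 0.3 and mean_corr[2] > 0.5
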