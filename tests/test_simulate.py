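"""Synthetic-data generator: grids, mixture designs, spectra and noise."""
import dataclasses
import itertools
import math

import numpy as np
import pytest

from serscal import (
    BandModel,
    ComponentModel,
    NoiseConfig,
    WavenumberGrid,
    concentration_matrix,
    default_components,
    make_wavenumber_grid,
    mixture_design,
    pure_component_spectrum,
    simulate_dataset,
    simulate_sample,
)
from serscal.simulate import NOISELESS, component_response


class TestWavenumberGrid:
    def test_default_instrument_grid(self):
        g = make_wavenumber_grid(200, 3400, 1024)
        assert g.n_points == 1024
        assert g.values[0] == 200 and g.values[-1] == 3400
        assert np.allclose(np.diff(g.values), 3200 / 1023)

    def test_two_point_grid_is_endpoints(self):
        assert np.array_equal(make_wavenumber_grid(0, 1, 2).values, [0.0, 1.0])

    def test_midpoint_symmetry(self, grid):
        assert grid.values[511] + grid.values[512] == pytest.approx(200 + 3400)

    @pytest.mark.parametrize("args", [(3400, 200, 1024), (200, 200, 10), (0, 1, 1)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_wavenumber_grid(*args)


def brute_force_design(k, m):
    return sorted(
        tuple(p / m for p in parts)
        for parts in itertools.product(range(m + 1), repeat=k)
        if sum(parts) == m
    )


class TestMixtureDesign:
    def test_ternary_ten_percent_design_has_66_mixtures(self):
        d = mixture_design(3, 0.1)
        assert d.n_compositions == 66

    @pytest.mark.parametrize(
        "k,m", [(1, 10), (2, 10), (3, 10), (2, 12), (3, 7), (4, 5), (4, 12)]
    )
    def test_matches_brute_force_enumeration(self, k, m):
        d = mixture_design(k, 1.0 / m)
        assert d.n_compositions == math.comb(m + k - 1, k - 1)
        assert list(d.compositions) == brute_force_design(k, m)
        arr = d.as_array()
        assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-12)
        assert len(set(d.compositions)) == d.n_compositions

    def test_single_component(self):
        assert mixture_design(1, 0.1).compositions == ((1.0,),)

    def test_binary_design(self):
        assert mixture_design(2, 0.1).n_compositions == 11

    def test_step_must_divide_one(self):
        with pytest.raises(ValueError):
            mixture_design(3, 0.3)


class TestPureComponentSpectrum:
    def test_theobromine_peaks_at_assigned_bands(self, grid):
        theo = default_components()[1]
        y = pure_component_spectrum(theo, grid)
        for center in (637, 1228, 1303, 1353, 1413, 1603, 2953):
            i = grid.nearest_index(center)
            assert y[i] > y[i - 1] and y[i] > y[i + 1], f"no apex at {center}"

    def test_max_amplitude_is_one(self, grid):
        for comp in default_components():
            assert pure_component_spectrum(comp, grid).max() == pytest.approx(1.0)

    def test_single_gaussian_band_normalised_to_one_at_center(self, grid):
        comp = ComponentModel(
            "x", (BandModel(1000, 10, 0.4, "gaussian"),), sensitivity=1.0
        )
        y = pure_component_spectrum(comp, grid)
        assert y[grid.nearest_index(1000)] == pytest.approx(1.0)

    def test_separated_unit_lorentzians_have_equal_areas(self):
        g = make_wavenumber_grid(0, 2000, 8001)  # 0.25 cm^-1 spacing
        comp = ComponentModel(
            "x", (BandModel(500, 8, 1.0), BandModel(1500, 8, 1.0)), sensitivity=1.0
        )
        y = pure_component_spectrum(comp, g)
        areas = []
        for c in (500, 1500):
            m = np.abs(g.values - c) <= 100
            areas.append(np.trapezoid(y[m], g.values[m]))
        assert areas[0] == pytest.approx(areas[1], rel=0.01)

    def test_band_outside_grid_rejected(self):
        g = make_wavenumber_grid(200, 1800, 128)
        with pytest.raises(ValueError, match="outside"):
            pure_component_spectrum(default_components()[0], g)


class TestSimulateSample:
    def test_all_zero_composition_and_noise_gives_zero_spectrum(self, grid):
        y = simulate_sample(
            (0, 0, 0), 1e-5, default_components(), NOISELESS,
            np.random.default_rng(0), grid,
        )
        assert np.all(y == 0)

    def test_single_component_zero_noise_is_scaled_pure_spectrum(self, grid):
        comps = default_components()
        y = simulate_sample(
            (1, 0, 0), 1e-5, comps, NOISELESS, np.random.default_rng(0), grid
        )
        expected = component_response(comps[0], 1e-5) * pure_component_spectrum(
            comps[0], grid
        )
        assert np.allclose(y, expected, rtol=0, atol=1e-15)

    def test_linear_response_doubles_with_concentration(self, grid, linear_components):
        y1 = simulate_sample(
            (0, 1, 0), 4e-6, linear_components, NOISELESS,
            np.random.default_rng(0), grid,
        )
        y2 = simulate_sample(
            (0, 1, 0), 8e-6, linear_components, NOISELESS,
            np.random.default_rng(0), grid,
        )
        assert np.allclose(y2, 2 * y1, rtol=1e-12)

    def test_saturating_response_is_sublinear(self):
        comp = default_components()[0]  # saturation_conc = 1e-5
        assert component_response(comp, 1e-5) < 2 * component_response(comp, 5e-6)

    def test_negative_concentration_rejected(self, grid):
        with pytest.raises(ValueError):
            simulate_sample(
                (-0.1, 0.6, 0.5), 1e-5, default_components(), NOISELESS,
                np.random.default_rng(0), grid,
            )


class TestSimulateDataset:
    def test_paper_scale_campaign(self):
        ds = simulate_dataset(seed=0)
        assert ds.spectra.n_samples == 198
        assert ds.spectra.n_channels == 1024
        assert len(ds.concentrations) == 198
        assert ds.design.n_compositions == 66 and ds.replicates == 3
        conc = concentration_matrix(ds.concentrations)
        assert np.allclose(conc.sum(axis=1), 1e-5)

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = simulate_dataset(seed=5)
        b = simulate_dataset(seed=5)
        c = simulate_dataset(seed=6)
        assert a.spectra.equals(b.spectra)
        assert not a.spectra.equals(c.spectra)

    def test_zero_noise_replicates_identical(self, small_grid, linear_components):
        ds = simulate_dataset(
            replicates=2, components=linear_components, noise=NOISELESS,
            seed=3, grid=small_grid,
        )
        X = ds.spectra.intensities
        assert np.array_equal(X[0], X[1])

    def test_noise_free_dataset_is_exact_linear_mixing(
        self, noisefree_small_dataset, small_grid, linear_components
    ):
        """Oracle: with all noise off and linear responses, every spectrum is
        the matrix product of concentrations-scaled responses and the pure
        spectra."""
        ds = noisefree_small_dataset
        pure = np.vstack(
            [pure_component_spectrum(c, small_grid) for c in linear_components]
        )
        conc = concentration_matrix(ds.concentrations)
        resp = conc * np.array([c.sensitivity for c in linear_components])
        assert np.allclose(ds.spectra.intensities, resp @ pure, atol=1e-12)

    def test_metadata_alignment(self):
        ds = simulate_dataset(seed=0, replicates=2)
        meta = ds.spectra.metadata
        assert list(meta["sample_id"]) == ds.spectra.sample_ids
        assert meta["replicate"].tolist() == [1, 2] * 66


class TestNoiseConfig:
    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(additive_sd=-0.1)

    def test_bad_aggregation_level_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(aggregation_level="day")

    def test_mixture_level_aggregation_shared_within_triplicate(self):
        """The aggregation enhancement factor is a session effect: all
        replicates of one mixture feel the same factor, so the ratio of the
        metabolite signal between replicates only reflects replicate-level
        noise."""
        nz = NoiseConfig(
            additive_sd=0.0, multiplicative_sd=0.0, baseline_amplitude=0.0,
            aggregation_sd=0.3,
        )
        ds = simulate_dataset(noise=nz, seed=9, replicates=3)
        X = ds.spectra.intensities
        # pure-theobromine mixture rows: identical despite large aggregation noise
        idx = ds.spectra.metadata.query(
            "frac_theobromine == 1.0"
        ).index.to_numpy()
        assert np.allclose(X[idx[0]], X[idx[1]], rtol=1e-12)
        # but different mixtures with equal theobromine see different factors
        other = simulate_dataset(noise=nz, seed=10, replicates=3)
        assert not np.allclose(X[idx[0]], other.spectra.intensities[idx[0]])
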