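import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.signal import find_peaks

from lamedp.synthetic_data import (
    GaussianBilayerModel,
    SimulationError,
    default_model,
    default_spec,
    model_edp,
    model_form_factor,
    pseudo_voigt,
    simulate_pattern,
    study_conditions,
)

SQRT_2PI = math.sqrt(2 * math.pi)


def numerical_form_factor(model, q, z_max=90.0, n=12001):
    """Independent oracle: cosine transform of the real-space profile with
    infinite-limit Gaussians (trapezoid; spectrally accurate here)."""
    z = np.linspace(0.0, z_max, n)
    head = np.exp(-((z - model.z_H) ** 2) / (2 * model.sigma_H**2))
    head = head + np.exp(-((z + model.z_H) ** 2) / (2 * model.sigma_H**2))
    rho = model.scale * (head - model.rho_ratio * np.exp(-(z**2) / (2 * model.sigma_C**2)))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return 2.0 * np.trapezoid(rho[None, :] * np.cos(q[:, None] * z[None, :]), z, axis=1)


model_strategy = st.builds(
    GaussianBilayerModel,
    z_H=st.floats(16, 30),
    sigma_H=st.floats(2, 5),
    sigma_C=st.floats(3, 8),
    rho_ratio=st.floats(0.1, 2),
    scale=st.floats(0.1, 3),
    d=st.just(65.0),
)


class TestModelEdp:
    def test_central_trough_value(self, truth_model):
        # z_H=22, sigma_H=3, rho_ratio=1: drho(0) = 2 exp(-242/9) - 1
        m = truth_model
        expected = 2 * math.exp(-(22.0**2) / (2 * 9.0)) - 1.0
        val = model_edp(m, np.array([0.0]))[0]
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(-1.0, abs=1e-9)  # headgroups far away

    @given(model=model_strategy)
    @settings(max_examples=50, deadline=None)
    def test_even_function(self, model):
        half = np.linspace(model.d / 2 / 50, model.d / 2, 50)
        z = np.concatenate([-half[::-1], [0.0], half])  # exactly sign-symmetric
        rho = model_edp(model, z)
        np.testing.assert_array_equal(rho, rho[::-1])

    def test_nonnegative_without_trough(self, truth_model):
        m = default_model(rho_ratio=0.0)
        z = np.linspace(-m.d / 2, m.d / 2, 301)
        assert np.all(model_edp(m, z) >= 0)

    def test_outside_cell_rejected(self, truth_model):
        with pytest.raises(SimulationError):
            model_edp(truth_model, np.array([-40.0, 0.0, 40.0]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            default_model(z_H=40.0)  # z_H >= d/2
        with pytest.raises(SimulationError):
            default_model(sigma_H=-1.0)


class TestModelFormFactor:
    def test_q_zero_closed_form(self, truth_model):
        m = truth_model
        expected = SQRT_2PI * m.scale * (2 * m.sigma_H - m.rho_ratio * m.sigma_C)
        assert model_form_factor(m, 0.0) == pytest.approx(expected, rel=1e-14)

    def test_cancellation_limit(self):
        # equal widths, rho_ratio=2, z_H -> 0: the Gaussians cancel
        m = GaussianBilayerModel(z_H=1e-6, sigma_H=4, sigma_C=4, rho_ratio=2, scale=1, d=65)
        q = np.linspace(0, 1, 50)
        assert np.max(np.abs(model_form_factor(m, q))) < 1e-9

    def test_matches_numerical_transform(self, truth_model):
        q = np.linspace(0, 1, 101)
        fa = model_form_factor(truth_model, q)
        fn = numerical_form_factor(truth_model, q)
        assert np.max(np.abs(fa - fn)) / np.max(np.abs(fa)) < 1e-6


class TestSimulatePattern:
    def test_bragg_positions(self, noise_free_profile):
        q, y = noise_free_profile.abscissa, noise_free_profile.intensity
        idx, _ = find_peaks(y, prominence=0.001 * y.max())
        lamellar = sorted(q[idx][q[idx] < 0.5])
        expected = [2 * math.pi * h / 65.0 for h in (1, 2, 4)]
        assert len(lamellar) == 3
        np.testing.assert_allclose(lamellar, expected, atol=2e-4)

    def test_seeded_reproducibility(self):
        spec = default_spec(noise_sd_fraction=0.02, seed=11)
        a = simulate_pattern(spec)
        b = simulate_pattern(spec)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_two_broad_lattices_merge_into_shoulder(self):
        lat = ((default_model(d=62.0), 0.5), (default_model(d=70.0), 0.5))
        broad = default_spec(lattices=lat, peak_fwhm=0.015, noise_sd_fraction=0.0, waxs=None)
        prof = simulate_pattern(broad)
        mask = prof.abscissa < 0.13  # first-order region
        idx, _ = find_peaks(prof.intensity[mask], prominence=0.01 * prof.intensity.max())
        assert 1 <= idx.size <= 2  # merged or shouldered, never more

        narrow = default_spec(lattices=lat, peak_fwhm=0.003, noise_sd_fraction=0.0, waxs=None)
        prof2 = simulate_pattern(narrow)
        idx2, _ = find_peaks(prof2.intensity[mask], prominence=0.01 * prof2.intensity.max())
        assert idx2.size == 2  # resolved when sharp

    def test_peak_area_back_integration_gaussian_shape(self, truth_model):
        # single visible order, Gaussian shape: integrated area must equal
        # weight * |F(q_1)|^2 / 1 within 0.5%
        spec = default_spec(
            n_orders=2,
            visible_orders=(1,),
            peak_eta=0.0,
            noise_sd_fraction=0.0,
            waxs=None,
            background=type(default_spec().background)(0.0, 0.0, 1.0),
        )
        prof = simulate_pattern(spec)
        area = np.trapezoid(prof.intensity, prof.abscissa)
        q1 = 2 * math.pi / truth_model.d
        expected = float(model_form_factor(truth_model, q1)) ** 2
        assert area == pytest.approx(expected, rel=5e-3)

    def test_pseudo_voigt_unit_area(self):
        # independent quadrature of the line-shape normalisation
        val, _ = quad(lambda x: pseudo_voigt(np.array([x]), 0.0, 0.02, 1.0)[0], -np.inf, np.inf)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(SimulationError, match="coarse"):
            simulate_pattern(default_spec(peak_fwhm=1e-4))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            default_spec(lattices=((default_model(), 0.5),))


class TestStudyConditions:
    def test_phenomenology_of_default_conditions(self):
        grid = study_conditions()
        assert len(grid) == 27
        for (cond, chol, temp), spec in grid.items():
            model = spec.lattices[0][0]
            assert 60.0 <= model.d <= 80.0
            assert 4.1 <= spec.waxs.center_d <= 4.9
        # headgroup position decreases with cholesterol in every series
        for cond in ("water", "DBP", "VDR"):
            zs = [grid[(cond, chol, 294)].lattices[0][0].z_H for chol in (20, 30, 40)]
            assert zs[0] > zs[1] > zs[2]
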