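import math

import numpy as np
import pytest

from lamedp.peak_analysis import (
    Peak,
    PeakAnalysisError,
    characterize_waxs,
    deconvolve_first_order,
    detect_peaks,
    index_lamellar,
    subtract_background,
)
from lamedp.profile_io import AbscissaKind, DiffractionProfile
from lamedp.synthetic_data import (
    Background,
    WaxsComponent,
    default_model,
    default_spec,
    model_form_factor,
    simulate_pattern,
)

Q1 = 2 * math.pi / 65.0


def saxs_spec(**overrides):
    """Single default lattice, no WAXS, no noise unless overridden."""
    params = dict(noise_sd_fraction=0.0, waxs=None)
    params.update(overrides)
    return default_spec(**params)


class TestSubtractBackground:
    def test_flat_profile_with_constant_offset(self):
        x = np.linspace(0.05, 0.5, 200)
        prof = DiffractionProfile(x, np.full_like(x, 100.0), AbscissaKind.Q)
        res = subtract_background(prof, model="constant")
        assert np.max(np.abs(res.profile.intensity)) < 1e-9

    def test_known_power_law_recovers_peak_areas(self, truth_model):
        spec = saxs_spec(background=Background(80.0, 2.0, 1.3))
        res = subtract_background(simulate_pattern(spec), model="power_law")
        peaks = detect_peaks(res.profile, min_prominence=0.005)
        assert len(peaks) == 3
        for h, peak in zip((1, 2, 4), peaks):
            q_h = 2 * math.pi * h / truth_model.d
            truth = float(model_form_factor(truth_model, q_h)) ** 2 / h**2
            assert peak.area == pytest.approx(truth, rel=0.02)

    def test_too_few_points_rejected(self):
        x = np.linspace(0.1, 0.2, 10)
        prof = DiffractionProfile(x, np.ones_like(x), AbscissaKind.Q)
        with pytest.raises(PeakAnalysisError, match="20 points"):
            subtract_background(prof)


class TestDetectPeaks:
    def test_three_orders_within_tolerance(self):
        prof = simulate_pattern(saxs_spec(background=Background(0.0, 0.0, 1.0)))
        peaks = detect_peaks(prof, min_prominence=0.001)
        assert len(peaks) == 3
        for h, peak in zip((1, 2, 4), peaks):
            assert abs(peak.center - h * Q1) < 1e-3

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0.05, 0.5, 400)
        prof = DiffractionProfile(x, 1.0 + 0.01 * rng.random(400), AbscissaKind.Q)
        with pytest.raises(PeakAnalysisError, match="no peak"):
            detect_peaks(prof, min_prominence=0.05)

    def test_two_separated_lattices_counted(self):
        from lamedp.synthetic_data import pseudo_voigt

        lat = ((default_model(d=62.0), 0.5), (default_model(d=75.0), 0.5))
        fwhm = 0.003
        prof = simulate_pattern(saxs_spec(lattices=lat, peak_fwhm=fwhm))
        prom = 0.001
        # generator oracle: how many Bragg peaks clear the threshold
        # (near form-factor zeros a reflection is physically extinct)
        heights = [
            w * float(model_form_factor(m, 2 * math.pi * h / m.d)) ** 2 / h**2
            * pseudo_voigt(np.array([0.0]), 0.0, fwhm, 1.0)[0]
            for m, w in lat
            for h in (1, 2, 4)
        ]
        expected = sum(hgt > 2 * prom * max(heights) for hgt in heights)
        peaks = detect_peaks(prof, min_prominence=prom)
        assert len(peaks) == expected == 5


class TestDeconvolveFirstOrder:
    WINDOW = (0.06, 0.14)

    @staticmethod
    def prepare(**overrides):
        prof = simulate_pattern(saxs_spec(**overrides))
        return subtract_background(prof, model="power_law").profile

    def test_single_lattice_selects_one_component(self):
        comps = deconvolve_first_order(
            self.prepare(peak_fwhm=0.008, noise_sd_fraction=0.01), self.WINDOW
        )
        assert len(comps) == 1
        assert comps[0].center == pytest.approx(Q1, rel=1e-3)

    def test_two_lattices_resolved_within_2pct(self):
        lat = ((default_model(d=62.0), 0.5), (default_model(d=70.0), 0.5))
        comps = deconvolve_first_order(
            self.prepare(lattices=lat, peak_fwhm=0.004, noise_sd_fraction=0.01),
            self.WINDOW,
        )
        assert len(comps) == 2
        assert comps[0].center == pytest.approx(2 * math.pi / 70.0, rel=0.02)
        assert comps[1].center == pytest.approx(2 * math.pi / 62.0, rel=0.02)

    def test_identical_lattices_degenerate_to_one(self):
        lat = ((default_model(d=65.0), 0.5), (default_model(d=65.0), 0.5))
        prof = self.prepare(lattices=lat, peak_fwhm=0.008, noise_sd_fraction=0.01)
        assert len(deconvolve_first_order(prof, self.WINDOW)) == 1

    def test_no_false_split_across_noise_realizations(self):
        # a single-lattice feature must never be reported as two components
        for seed in range(50):
            prof = self.prepare(peak_fwhm=0.008, noise_sd_fraction=0.02, seed=seed)
            assert len(deconvolve_first_order(prof, self.WINDOW)) == 1


def make_peak(center_q, area=1.0):
    return Peak(center=center_q, fwhm=0.005, area=area)


class TestIndexLamellar:
    def test_exact_harmonics(self):
        peaks = [make_peak(h * Q1) for h in (1, 2, 4)]
        lattices = index_lamellar(peaks)
        assert len(lattices) == 1
        assert lattices[0].d == pytest.approx(65.0, abs=1e-9)
        assert [h for h, _ in lattices[0].orders] == [1, 2, 4]
        assert all(p.label == "lamellar" for p in peaks)

    def test_cholesterol_reflection_stays_unassigned(self):
        # a 34 A reflection is not an integer harmonic of a 65 A lattice
        peaks = [make_peak(h * Q1) for h in (1, 2, 4)] + [make_peak(2 * math.pi / 34.0)]
        lattices = index_lamellar(peaks)
        assert len(lattices) == 1
        assert peaks[-1].label == "non_lamellar"

    def test_two_interleaved_series_recovered(self):
        peaks = [make_peak(2 * math.pi * h / 62.0) for h in (1, 2, 4)]
        peaks += [make_peak(2 * math.pi * h / 70.0) for h in (1, 2, 4)]
        lattices = index_lamellar(peaks)
        assert len(lattices) == 2
        assert lattices[0].d == pytest.approx(70.0, rel=0.002)  # sorted d descending
        assert lattices[1].d == pytest.approx(62.0, rel=0.002)

    def test_scale_equivariance(self):
        peaks_a = [make_peak(h * Q1) for h in (1, 2, 4)]
        c = 1.7
        peaks_b = [make_peak(h * Q1 * c) for h in (1, 2, 4)]
        d_a = index_lamellar(peaks_a)[0].d
        d_b = index_lamellar(peaks_b)[0].d
        assert d_b == pytest.approx(d_a / c, rel=1e-12)

    def test_noise_free_d_recovery_within_01pct(self):
        prof = simulate_pattern(saxs_spec(peak_fwhm=0.005))
        peaks = detect_peaks(prof, min_prominence=0.001)
        d = index_lamellar(peaks)[0].d
        assert d == pytest.approx(65.0, rel=1e-3)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(PeakAnalysisError):
            index_lamellar([make_peak(Q1)])

    def test_no_consistent_lattice(self):
        with pytest.raises(PeakAnalysisError, match="no self-consistent"):
            index_lamellar([make_peak(0.10), make_peak(0.13)])


class TestCharacterizeWaxs:
    @pytest.mark.parametrize("center,lo,hi", [(4.15, 4.13, 4.17), (4.75, 4.6, 4.9)])
    def test_center_recovery(self, center, lo, hi):
        spec = default_spec(noise_sd_fraction=0.005, waxs=WaxsComponent(center_d=center))
        res = characterize_waxs(simulate_pattern(spec))
        assert lo <= res.peak.center <= hi
        assert res.peak.label == "waxs"
        assert not res.has_crystalline_candidate  # broad chain-packing peak only

    def test_no_waxs_component_raises(self):
        prof = simulate_pattern(saxs_spec())
        with pytest.raises(PeakAnalysisError, match="no peak"):
            characterize_waxs(prof)

    def test_sharp_component_flagged(self):
        spec = default_spec(
            noise_sd_fraction=0.0,
            waxs=WaxsComponent(center_d=4.15, fwhm_d=0.02, height=80.0),
        )
        res = characterize_waxs(simulate_pattern(spec))
        assert res.has_crystalline_candidate
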