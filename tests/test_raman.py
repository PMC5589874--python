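"""Spectral preprocessing: fingerprint restriction, iterative polynomial
baseline removal, SNV, and band quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from qpraman.raman import (
    RamanSpectrum,
    SpectralDataset,
    band_intensity,
    group_mean_spectra,
    preprocess,
    remove_baseline,
    restrict_fingerprint,
    snv,
)
from qpraman.synthetic import SpectralGroupSpec, make_spectra


def _spec(w, y, group=None):
    return RamanSpectrum(np.asarray(w, float), np.asarray(y, float), group=group)


class TestRestrict:
    def test_wide_grid_clipped_to_fingerprint(self):
        w = np.arange(400.0, 2001.0)
        out = restrict_fingerprint(_spec(w, np.ones_like(w)))
        assert out.wavenumber[0] == 600.0 and out.wavenumber[-1] == 1800.0

    def test_in_range_grid_unchanged(self):
        w = np.arange(700.0, 1500.0)
        out = restrict_fingerprint(_spec(w, w * 0.1))
        np.testing.assert_array_equal(out.wavenumber, w)
        np.testing.assert_array_equal(out.intensity, w * 0.1)

    def test_no_overlap_rejected(self):
        w = np.arange(1900.0, 2500.0)
        with pytest.raises(ValueError, match="overlap"):
            restrict_fingerprint(_spec(w, np.ones_like(w)))


class TestBaseline:
    def test_pure_quartic_annihilated(self):
        w = np.arange(600.0, 1801.0)
        u = (w - 600) / 1200
        y = 5 + 3 * u - 2 * u**2 + u**3 + 0.5 * u**4
        out = remove_baseline(_spec(w, y))
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.ptp(y)

    def test_constant_spectrum_zeroed(self):
        w = np.arange(600.0, 1801.0)
        out = remove_baseline(_spec(w, np.full_like(w, 3.7)))
        assert np.all(out.intensity == 0.0)

    def test_band_area_preserved_on_polynomial_background(self):
        """A Lorentzian on a quartic background keeps its area within 5 %."""
        w = np.arange(600.0, 1801.0)
        u = (w - 600) / 1200
        gamma, amp = 8.0, 1.0
        band = amp * gamma**2 / ((w - 1004.0) ** 2 + gamma**2)
        y = (4 - 2 * u + u**2) + band
        out = remove_baseline(_spec(w, y))
        window = np.abs(w - 1004.0) <= 60
        assert out.intensity[window].sum() == pytest.approx(band[window].sum(), rel=0.05)

    def test_shift_equivariance_in_intensity(self):
        rng = np.random.default_rng(5)
        w = np.arange(600.0, 1801.0)
        y = np.exp(-((w - 1300) ** 2) / 800.0) + 0.02 * rng.standard_normal(w.size)
        u = (w - 600) / 1200
        poly = 2 + u - 0.5 * u**2
        a = remove_baseline(_spec(w, y)).intensity
        b = remove_baseline(_spec(w, y + poly)).intensity
        np.testing.assert_allclose(a, b, atol=1e-6 * np.ptp(y))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            remove_baseline(_spec([1, 2, 3], [1.0, 2.0, 3.0]))


class TestSNV:
    def test_hand_computed_example(self):
        out = snv(_spec([600, 700, 800], [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensity, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_sd_one_contract(self):
        rng = np.random.default_rng(2)
        out = snv(_spec(np.arange(600.0, 1801.0), rng.uniform(1, 5, 1201)))
        assert abs(out.intensity.mean()) < 1e-12
        assert abs(np.std(out.intensity, ddof=1) - 1.0) < 1e-12

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        s = _spec(np.arange(600.0, 1801.0), rng.uniform(0, 3, 1201))
        once = snv(s)
        twice = snv(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant spectrum"):
            snv(_spec([600, 700, 800], [2.0, 2.0, 2.0]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(5, 60),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_contract_and_idempotence_hold_for_any_spectrum(self, y):
        if np.std(y, ddof=1) == 0:
            return
        s = _spec(np.arange(600.0, 600.0 + y.size), y)
        out = snv(s)
        assert abs(out.intensity.mean()) < 1e-9
        assert abs(np.std(out.intensity, ddof=1) - 1.0) < 1e-9
        np.testing.assert_allclose(snv(out).intensity, out.intensity, atol=1e-9)


class TestBandIntensity:
    def test_delta_peak_average(self):
        w = np.arange(990.0, 1011.0)  # 1000 ± 5 window holds 11 points
        y = np.zeros_like(w)
        y[w == 1000.0] = 7.0
        assert band_intensity(_spec(w, y), 1000.0, 5.0) == pytest.approx(7.0 / 11.0)

    def test_symmetric_band_mirror_invariant(self):
        w = np.arange(950.0, 1051.0)
        y = np.exp(-((w - 1000.0) ** 2) / 50.0)
        v = band_intensity(_spec(w, y), 1000.0, 5.0)
        mirrored = _spec(w, y[::-1])
        assert band_intensity(mirrored, 1000.0, 5.0) == pytest.approx(v, rel=1e-12)

    def test_window_outside_grid_rejected(self):
        w = np.arange(600.0, 1001.0)
        with pytest.raises(ValueError, match="outside"):
            band_intensity(_spec(w, np.ones_like(w)), 1000.0, 5.0)

    def test_monotone_generated_amplitudes_recovered(self, wavenumber_axis):
        """Groups generated with increasing 1584 cm⁻¹ amplitude come out
        monotone in the preprocessed group-mean band intensity."""
        datasets = []
        for i, (g, amp) in enumerate(
            zip(("control", "T50", "T100", "T200"), (0.3, 0.5, 0.7, 0.9))
        ):
            spec = SpectralGroupSpec(
                group=g,
                band_centers=[1004.0, 1440.0, 1584.0],
                band_amplitudes=[1.0, 0.9, amp],
                band_widths=[6.0, 9.0, 8.0],
                baseline_coeffs=[3.0, -2.0, 1.0, 0.0, 0.1],
                noise_sd=0.01,
                n_spectra=8,
            )
            datasets.append(make_spectra(spec, wavenumber_axis, seed=100 + i))
        full = datasets[0]
        for d in datasets[1:]:
            full = full.concat(d)
        proc = preprocess(full)
        means = []
        for g in ("control", "T50", "T100", "T200"):
            vals = [band_intensity(s, 1584.0) for s in proc.spectra() if s.group == g]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestGroupMeans:
    def test_identical_spectra_mean_and_zero_sd(self):
        w = np.arange(600.0, 700.0)
        y = np.sin(w / 30.0)
        ds = SpectralDataset(np.vstack([y, y]), w, ["control", "control"])
        means = group_mean_spectra(ds)
        np.testing.assert_allclose(means["control"][0], y)
        assert np.all(means["control"][1] == 0.0)

    def test_opposite_spectra_average_to_zero(self):
        w = np.arange(600.0, 700.0)
        y = np.cos(w / 10.0)
        ds = SpectralDataset(np.vstack([y, -y]), w, ["T50", "T50"])
        np.testing.assert_allclose(group_mean_spectra(ds)["T50"][0], 0.0, atol=1e-15)

    def test_singleton_group_warns_with_zero_sd(self):
        w = np.arange(600.0, 700.0)
        ds = SpectralDataset(np.ones((1, w.size)), w, ["T100"])
        with pytest.warns(UserWarning, match="single spectrum"):
            means = group_mean_spectra(ds)
        assert np.all(means["T100"][1] == 0.0)

    def test_group_mean_within_clt_bound_of_template(self, wavenumber_axis):
        """Pointwise |mean − template| stays below 4·σ/√n at ≥99 % of
        channels for a noise-only group (jitter disabled)."""
        noise_sd, n = 0.05, 25
        spec = SpectralGroupSpec(
            group="control", band_centers=[1004.0], band_amplitudes=[1.0],
            band_widths=[6.0], baseline_coeffs=[1.0, 0.5, 0.0, 0.0, 0.0],
            noise_sd=noise_sd, n_spectra=n, amplitude_jitter=0.0,
        )
        ds = make_spectra(spec, wavenumber_axis, seed=77)
        template = make_spectra(
            SpectralGroupSpec(group="control", band_centers=[1004.0],
                              band_amplitudes=[1.0], band_widths=[6.0],
                              baseline_coeffs=[1.0, 0.5, 0.0, 0.0, 0.0],
                              noise_sd=0.0, n_spectra=1, amplitude_jitter=0.0),
            wavenumber_axis, seed=1).matrix[0]
        mean = ds.matrix.mean(axis=0)
        frac = np.mean(np.abs(mean - template) < 4 * noise_sd / np.sqrt(n))
        assert frac >= 0.99


class TestPipelineOrder:
    def test_preprocess_restricts_then_centres(self, spectral_groups, wavenumber_axis):
        ds = make_spectra(spectral_groups[0], wavenumber_axis, seed=5)
        proc = preprocess(ds)
        assert proc.axis[0] >= 600.0 and proc.axis[-1] <= 1800.0
        # terminal representation is SNV: every row mean 0, SD 1
        assert np.allclose(proc.matrix.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(proc.matrix.std(axis=1, ddof=1), 1.0, atol=1e-10)
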