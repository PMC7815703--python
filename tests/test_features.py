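"""Welch spectra, the relative power-shift feature and contact depth."""

import numpy as np
import pytest

from seegwm.features import (PowerSpectrum, ShankRecord, depth_feature,
                             depth_intervals, records_from_table,
                             records_to_table, relative_power_shift,
                             welch_psd)
from seegwm.signal_io import ShankLayout


def _spectrum(offset, shape=None, fmax=200.0, df=1.0):
    f = np.arange(0.0, fmax + df, df)
    if shape is None:
        shape = -np.log1p(f)          # 1/f-ish reference curve
    excluded = np.zeros_like(f, bool)
    for c in (60.0, 120.0):
        excluded |= np.abs(f - c) <= 2.0
    return PowerSpectrum(freqs=f, log_psd=shape + offset, excluded=excluded)


class TestWelch:
    def test_sinusoid_peak_and_amplitude_scaling(self):
        fs, dur, f0 = 1000.0, 120.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        ps1 = welch_psd(x, fs)
        ps2 = welch_psd(2 * x, fs)
        peak = ps1.freqs[np.argmax(ps1.log_psd)]
        assert abs(peak - f0) <= ps1.freqs[1] - ps1.freqs[0]
        # doubling the amplitude quadruples power: log shift = log 4
        assert np.isclose(ps2.log_psd[np.argmax(ps1.log_psd)]
                          - ps1.log_psd[np.argmax(ps1.log_psd)],
                          np.log(4.0), rtol=1e-10)

    def test_white_noise_band_power_matches_variance(self):
        fs, sigma = 1000.0, 3.0
        rng = np.random.default_rng(0)
        x = sigma * rng.standard_normal(int(fs * 120))
        ps = welch_psd(x, fs)
        band = (ps.freqs > 0) & (ps.freqs < fs / 2)
        mean_psd = np.exp(ps.log_psd[band]).mean()
        # flat spectrum: PSD level = sigma^2 / (fs/2) per Hz
        assert np.isclose(mean_psd, sigma ** 2 / (fs / 2), rtol=0.05)

    def test_identical_windows_average_to_single_window(self):
        fs = 500.0
        rng = np.random.default_rng(1)
        chunk = rng.standard_normal(int(10 * fs))
        x = np.tile(chunk, 2)
        two = welch_psd(x, fs, n_windows=2)
        one = welch_psd(chunk, fs, n_windows=1)
        assert np.allclose(two.log_psd, one.log_psd)

    def test_short_recording_overlaps_windows_with_warning(self):
        fs = 200.0
        x = np.random.default_rng(2).standard_normal(int(50 * fs))
        with pytest.warns(UserWarning, match="overlapping"):
            ps = welch_psd(x, fs, n_windows=10, window_length_s=10.0)
        assert ps.freqs.max() >= 100.0 - 1.0

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 1000.0)


class TestRelativePowerShift:
    def test_constant_offset_two_contacts(self):
        s = relative_power_shift([_spectrum(0.0), _spectrum(1.0)])
        assert np.allclose(s, [-0.5, 0.5], atol=1e-12)

    def test_identical_contacts_give_zero(self):
        s = relative_power_shift([_spectrum(0.3)] * 4)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_three_offsets_recovered(self):
        s = relative_power_shift([_spectrum(0.0), _spectrum(1.0),
                                  _spectrum(2.0)])
        assert np.allclose(s, [-1.0, 0.0, 1.0], atol=1e-9)

    def test_patient_mean_is_zero(self):
        rng = np.random.default_rng(3)
        spectra = [_spectrum(rng.normal(), shape=rng.normal(size=201))
                   for _ in range(7)]
        # distinct shapes share one grid; centering is exact by construction
        base = spectra[0].log_psd * 0 - np.log1p(spectra[0].freqs)
        spectra = [PowerSpectrum(sp.freqs, base + rng.normal(), sp.excluded)
                   for sp in spectra]
        s = relative_power_shift(spectra)
        assert abs(s.mean()) < 1e-12

    def test_common_gain_invariance(self):
        # multiplying every raw signal by g adds log g^2 to every log-PSD
        specs = [_spectrum(0.0), _spectrum(0.7), _spectrum(-0.2)]
        gained = [PowerSpectrum(sp.freqs, sp.log_psd + 2 * np.log(3.0),
                                sp.excluded) for sp in specs]
        assert np.allclose(relative_power_shift(specs),
                           relative_power_shift(gained), atol=1e-12)

    def test_upper_limit_insensitive_for_pure_offsets(self):
        specs = [_spectrum(0.0), _spectrum(1.4)]
        for fmax in (100.0, 150.0, 200.0):
            s = relative_power_shift(specs, band_hz=(1.0, fmax))
            assert np.allclose(s, [-0.7, 0.7], atol=1e-12)

    def test_power_domain_reference_supported(self):
        specs = [_spectrum(0.0), _spectrum(1.0)]
        s = relative_power_shift(specs, average="power")
        assert np.allclose(s, [-0.5, 0.5], atol=1e-12)

    def test_single_contact_rejected(self):
        with pytest.raises(ValueError):
            relative_power_shift([_spectrum(0.0)])

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            relative_power_shift([_spectrum(0.0), _spectrum(1.0)],
                                 band_hz=(300.0, 301.0))


class TestDepth:
    def _layout(self, n, in_brain=None, gaps=None):
        return ShankLayout(
            shank="A", contacts=[f"A{i + 1}" for i in range(n)],
            in_brain=np.ones(n, bool) if in_brain is None else in_brain,
            excluded=np.zeros(n, bool), gaps_mm=gaps)

    def test_outside_brain_contacts_shift_the_zero(self):
        # outermost 3 of 8 outside the brain: in-brain depths 0..4
        in_brain = np.array([1, 1, 1, 1, 1, 0, 0, 0], bool)
        d = depth_feature(self._layout(8, in_brain))
        assert np.allclose(d[:5], [4, 3, 2, 1, 0])
        assert np.isnan(d[5:]).all()

    def test_all_in_brain_uniform(self):
        d = depth_feature(self._layout(6))
        assert np.allclose(d, [5, 4, 3, 2, 1, 0])

    def test_irregular_spacing_in_mm(self):
        # gaps (5, 3.5, 3.5) mm from the periphery -> depths (0, 5, 8.5, 12)
        gaps_tip_to_periphery = np.array([3.5, 3.5, 5.0])
        d = depth_feature(self._layout(4, gaps=gaps_tip_to_periphery),
                          units="mm")
        assert np.allclose(d, [12.0, 8.5, 5.0, 0.0])

    def test_no_in_brain_contact_rejected(self):
        with pytest.raises(ValueError):
            depth_feature(self._layout(3, in_brain=np.zeros(3, bool)))

    def test_depth_intervals_midpoints_and_ends(self):
        iv = depth_intervals(np.array([3.0, 2.0, 1.0, 0.0]))
        assert np.allclose(iv, [[2.5, 3.5], [1.5, 2.5], [0.5, 1.5],
                                [-0.5, 0.5]])
        iv1 = depth_intervals(np.array([2.0]))
        assert np.allclose(iv1, [[1.5, 2.5]])


def test_feature_table_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    recs = [ShankRecord(patient="P0", shank=f"S{i}",
                        contacts=[f"S{i}-{j}" for j in range(5)],
                        s=rng.normal(size=5),
                        depth=np.arange(4.0, -1.0, -1.0),
                        labels=np.where(rng.random(5) < 0.3, 1.0, -1.0))
            for i in range(3)]
    table = records_to_table(recs)
    back = records_from_table(table)
    assert len(back) == 3
    for a, b in zip(recs, back):
        assert np.allclose(a.s, b.s) and np.allclose(a.depth, b.depth)
        assert np.array_equal(a.labels, b.labels)
        assert a.contacts == b.contacts
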