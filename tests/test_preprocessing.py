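"""Filtering, resampling, interpolation, and Hilbert phase extraction."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import sine_recording
from hyperbrain import (
    DualRecording,
    bandpass,
    downsample,
    hilbert_phase,
    interpolate_bad_channels,
)
from hyperbrain.montage import CHANNELS_29, channel_positions, great_circle_distances
from hyperbrain.preprocessing import InvalidRecordingError


class TestDualRecording:
    def test_mismatched_blocks_rejected(self):
        a = np.zeros((3, 100))
        b = np.zeros((3, 99))
        with pytest.raises(InvalidRecordingError):
            DualRecording((a, b), 500.0, ("c1", "c2", "c3"))

    def test_duplicate_labels_rejected(self):
        a = np.zeros((2, 10))
        with pytest.raises(InvalidRecordingError):
            DualRecording((a, a.copy()), 500.0, ("x", "x"))


class TestDownsample:
    def test_halves_sample_count(self):
        rec = sine_recording([5.0], duration=4.0, fs=500.0)
        out = downsample(rec, 250.0)
        assert out.n_samples == rec.n_samples // 2
        assert out.sampling_rate == 250.0

    def test_sinusoid_amplitude_preserved(self):
        rec = sine_recording([5.0], duration=4.0, fs=500.0)
        out = downsample(rec, 250.0)
        t = np.arange(out.n_samples) / 250.0
        ref = np.cos(2 * np.pi * 5.0 * t)
        interior = slice(100, -100)
        sig = out.participant_blocks[0][0]
        amp_ratio = np.abs(sig[interior]).max() / np.abs(ref[interior]).max()
        assert amp_ratio == pytest.approx(1.0, abs=0.01)
        assert np.corrcoef(sig[interior], ref[interior])[0, 1] > 0.999

    def test_identity_rate_is_noop(self):
        rec = sine_recording([5.0], duration=2.0)
        out = downsample(rec, rec.sampling_rate)
        assert np.array_equal(out.participant_blocks[0], rec.participant_blocks[0])

    def test_upsampling_rejected(self):
        rec = sine_recording([5.0], duration=2.0, fs=250.0)
        with pytest.raises(InvalidRecordingError):
            downsample(rec, 500.0)


class TestBandpass:
    def test_extracts_component_in_band(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        mix = np.cos(2 * np.pi * 2 * t) + np.cos(2 * np.pi * 10 * t)
        block = mix[None, :]
        rec = DualRecording((block, block.copy()), fs, ("ch0",))
        out = bandpass(rec, 8.0, 12.0)
        interior = slice(500, -500)
        ref = np.cos(2 * np.pi * 10 * t)
        r = np.corrcoef(out.participant_blocks[0][0][interior], ref[interior])[0, 1]
        assert r > 0.99
        assert out.band_tag == "alpha"

    def test_zero_phase_no_lag(self):
        rec = sine_recording([5.0], duration=4.0)
        out = bandpass(rec, 4.0, 7.0)
        x = rec.participant_blocks[0][0]
        y = out.participant_blocks[0][0]
        interior = slice(500, -500)
        xc = np.correlate(y[interior], x[interior], mode="full")
        lag = np.argmax(xc) - (len(x[interior]) - 1)
        assert lag == 0

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        block = rng.standard_normal((2, 4000))
        rec = DualRecording((block, block.copy()), 500.0, ("a", "b"))
        fwd = bandpass(rec, 4.0, 7.0).participant_blocks[0]
        rev_in = DualRecording(
            (block[:, ::-1].copy(), block[:, ::-1].copy()), 500.0, ("a", "b")
        )
        rev = bandpass(rev_in, 4.0, 7.0).participant_blocks[0]
        # Filter transients depend on the padding direction and, for this
        # narrow band, ring with a ~2 s time constant; the zero-phase
        # symmetry holds in the interior beyond them.
        interior = slice(1000, -1000)
        assert np.abs(fwd[:, interior] - rev[:, ::-1][:, interior]).max() < 5e-4

    @pytest.mark.parametrize("band", [(7.0, 4.0), (4.0, 4.0), (10.0, 300.0), (0.0, 7.0)])
    def test_invalid_bands_rejected(self, band):
        rec = sine_recording([5.0], duration=2.0)
        with pytest.raises(InvalidRecordingError):
            bandpass(rec, *band)


@pytest.fixture(scope="module")
def positions():
    return channel_positions(CHANNELS_29)


class TestInterpolation:

    def _recording(self, block, bad):
        return DualRecording(
            (block, block.copy()), 500.0, CHANNELS_29, bad_channels=(bad, ())
        )

    def test_identical_good_channels_reproduced_exactly(self, positions):
        t = np.linspace(0, 1, 300)
        s = np.sin(2 * np.pi * 6 * t)
        block = np.tile(s, (29, 1))
        rec = self._recording(block, ("Cz",))
        out = interpolate_bad_channels(rec, positions)
        i = CHANNELS_29.index("Cz")
        assert np.allclose(out.participant_blocks[0][i], s, atol=1e-12)

    def test_no_bad_channels_is_noop(self, positions):
        block = np.random.default_rng(0).standard_normal((29, 100))
        rec = self._recording(block, ())
        out = interpolate_bad_channels(rec, positions)
        assert np.array_equal(out.participant_blocks[0], block)

    def test_smooth_field_beats_nearest_neighbor_copy(self, positions):
        # Spatially smooth gain field times a common waveform: the local
        # inverse-distance estimate must beat copying the closest electrode.
        t = np.linspace(0, 1, 400)
        base = np.sin(2 * np.pi * 5 * t)
        gain = (
            1.0 + 0.8 * positions[:, 0] + 0.6 * positions[:, 1]
            + 0.4 * positions[:, 2] + 0.3 * positions[:, 0] * positions[:, 1]
        )
        block = gain[:, None] * base[None, :]
        bad = "Cz"
        i = CHANNELS_29.index(bad)
        rec = self._recording(block.copy(), (bad,))
        out = interpolate_bad_channels(rec, positions)
        interp_err = np.abs(out.participant_blocks[0][i] - block[i]).max()
        d = great_circle_distances(positions)[i].copy()
        d[i] = np.inf
        nn_err = np.abs(block[np.argmin(d)] - block[i]).max()
        assert interp_err < nn_err

    def test_all_channels_bad_rejected(self, positions):
        block = np.zeros((29, 50))
        rec = self._recording(block, tuple(CHANNELS_29))
        with pytest.raises(InvalidRecordingError):
            interpolate_bad_channels(rec, positions)


class TestHilbertPhase:
    def test_linear_phase_advance(self):
        rec = sine_recording([5.0], duration=6.0, band_tag="theta")
        ps = hilbert_phase(rec)
        t0 = ps.trim_samples
        phase = np.unwrap(ps.phases[0][0])[t0:-t0]
        slope = np.polyfit(np.arange(phase.size) / rec.sampling_rate, phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5.0, rel=0.01)

    def test_constant_lag_recovered(self):
        rec = sine_recording([5.0, 5.0], duration=6.0, phases=[0.0, -np.pi / 3], band_tag="theta")
        ps = hilbert_phase(rec)
        t0 = ps.trim_samples
        diff = ps.phases[0][0] - ps.phases[0][1]
        diff = np.angle(np.exp(1j * diff))[t0:-t0]
        assert np.abs(diff - np.pi / 3).max() < 0.01

    def test_phase_range_and_amplitude(self):
        rec = sine_recording([5.0, 6.0], duration=4.0, band_tag="theta")
        ps = hilbert_phase(rec)
        for ph, an in zip(ps.phases, ps.analytic_signals):
            assert np.all(ph >= -np.pi) and np.all(ph <= np.pi)
            assert np.all(np.abs(an) >= 0)

    def test_broadband_input_rejected(self):
        rec = sine_recording([5.0], duration=4.0, band_tag=None)
        with pytest.raises(InvalidRecordingError):
            hilbert_phase(rec)

    def test_all_zero_signal_rejected(self):
        block = np.zeros((1, 2000))
        rec = DualRecording((block, block.copy()), 500.0, ("ch0",), band_tag="theta")
        with pytest.raises(InvalidRecordingError):
            hilbert_phase(rec)

    def test_channel_order_preserved_through_chain(self):
        rec = sine_recording([4.5, 5.5, 6.5], duration=6.0)
        out = bandpass(downsample(rec, 250.0), 4.0, 7.0)
        ps = hilbert_phase(out)
        t0 = ps.trim_samples
        for c, f in enumerate([4.5, 5.5, 6.5]):
            phase = np.unwrap(ps.phases[0][c])[t0:-t0]
            slope = np.polyfit(np.arange(phase.size) / 250.0, phase, 1)[0]
            assert slope == pytest.approx(2 * np.pi * f, rel=0.02)
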