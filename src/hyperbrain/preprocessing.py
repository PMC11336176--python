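"""Preprocessing of dual-EEG recordings into band-limited analytic phase.

The chain mirrors a standard hyperscanning workflow: downsample with
anti-alias filtering, zero-phase band-pass into a named frequency band
(theta 4-7 Hz, alpha 8-12 Hz, beta 13-30 Hz), spherical interpolation of
channels marked bad, and Hilbert-transform extraction of instantaneous
phase. All filtering is zero-phase (forward-backward), because any
channel-dependent group delay would corrupt the phase-difference metrics
computed downstream.

Independent-component artifact rejection is deliberately NOT part of this
module: it requires manual component selection and the pipeline therefore
expects already-clean (or synthetic) data plus an explicit bad-channel list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import channel_positions, great_circle_distances

#: Named frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Broad-band artifact-rejection filter applied before band splitting, Hz.
BROADBAND: tuple[float, float] = (1.0, 45.0)

#: Butterworth order used for all band-pass filters (applied forward-backward).
FILTER_ORDER = 4

#: Minimum edge trim, seconds, excluded from all synchrony sums.
TRIM_SECONDS = 1.0


class InvalidRecordingError(ValueError):
    """Raised for structurally invalid recordings or arguments."""


@dataclass
class DualRecording:
    """Two synchronized multichannel EEG blocks from one participant pair.

    ``participant_blocks`` holds two (n_channels, n_samples) float arrays
    sharing a sampling rate and sample count. ``band_tag`` is ``None`` for
    broadband data and a :data:`BANDS` key once band-pass filtered.
    """

    participant_blocks: tuple[np.ndarray, np.ndarray]
    sampling_rate: float
    channel_labels: tuple[str, ...]
    band_tag: str | None = None
    bad_channels: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())

    def __post_init__(self) -> None:
        a, b = self.participant_blocks
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.ndim != 2 or b.ndim != 2:
            raise InvalidRecordingError("participant blocks must be 2-D (channels x samples)")
        if a.shape != b.shape:
            raise InvalidRecordingError(f"participant blocks differ in shape: {a.shape} vs {b.shape}")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidRecordingError("channel labels must be unique")
        if a.shape[0] != len(self.channel_labels):
            raise InvalidRecordingError(
                f"{a.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise InvalidRecordingError("sampling_rate must be positive")
        self.participant_blocks = (a, b)
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.participant_blocks[0].shape[0]

    @property
    def n_samples(self) -> int:
        return self.participant_blocks[0].shape[1]


@dataclass
class PhaseSet:
    """Instantaneous phase and analytic signal per channel per participant.

    ``trim_samples`` edge samples at each end are contaminated by filter and
    Hilbert edge effects; every synchrony computation must exclude them.
    """

    phases: tuple[np.ndarray, np.ndarray]
    analytic_signals: tuple[np.ndarray, np.ndarray]
    sampling_rate: float
    channel_labels: tuple[str, ...]
    band_tag: str
    trim_samples: int

    @property
    def n_channels(self) -> int:
        return self.phases[0].shape[0]

    def trimmed_analytic(self) -> tuple[np.ndarray, np.ndarray]:
        """Analytic signals with the edge-trim applied, per participant."""
        t = self.trim_samples
        sl = slice(t, -t) if t > 0 else slice(None)
        a, b = self.analytic_signals
        return a[:, sl], b[:, sl]

    def trimmed_phases(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.trim_samples
        sl = slice(t, -t) if t > 0 else slice(None)
        a, b = self.phases
        return a[:, sl], b[:, sl]


def _named_band(low: float, high: float) -> str | None:
    for name, (lo, hi) in BANDS.items():
        if np.isclose(low, lo) and np.isclose(high, hi):
            return name
    return None


def downsample(rec: DualRecording, target_rate: float) -> DualRecording:
    """Resample both blocks to ``target_rate`` with anti-alias filtering.

    Uses polyphase resampling, which applies a zero-phase FIR anti-alias
    filter; spectra above ``target_rate / 2`` are attenuated.
    """
    if target_rate <= 0:
        raise InvalidRecordingError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise InvalidRecordingError(
            f"target_rate {target_rate} exceeds sampling rate {rec.sampling_rate}"
        )
    if target_rate == rec.sampling_rate:
        return rec
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    blocks = tuple(
        sps.resample_poly(block, frac.numerator, frac.denominator, axis=1)
        for block in rec.participant_blocks
    )
    return replace(rec, participant_blocks=blocks, sampling_rate=float(target_rate))


def bandpass(rec: DualRecording, low: float, high: float) -> DualRecording:
    """Zero-phase Butterworth band-pass of both participants' blocks.

    Forward-backward application (``sosfiltfilt``) guarantees zero group
    delay, so relative phase between channels is untouched in the passband.
    ``band_tag`` is set when (low, high) matches a named band.
    """
    nyquist = rec.sampling_rate / 2.0
    if not 0 < low < high < nyquist:
        raise InvalidRecordingError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyquist} Hz"
        )
    sos = sps.butter(FILTER_ORDER, [low, high], btype="band", fs=rec.sampling_rate, output="sos")
    # Narrow bands ring for several periods of the low edge; extend the
    # reflection padding accordingly or edge transients leak inward.
    padlen = min(rec.n_samples - 1, int(6 * rec.sampling_rate / low))
    blocks = tuple(
        sps.sosfiltfilt(sos, block, axis=1, padlen=padlen)
        for block in rec.participant_blocks
    )
    return replace(rec, participant_blocks=blocks, band_tag=_named_band(low, high))


def bandpass_named(rec: DualRecording, band: str) -> DualRecording:
    low, high = BANDS[band]
    return bandpass(rec, low, high)


def interpolate_bad_channels(
    rec: DualRecording, positions: np.ndarray | None = None
) -> DualRecording:
    """Replace channels listed in ``rec.bad_channels`` by spatial interpolation.

    Each bad channel becomes a convex combination of its nearest good
    channels, weighted by inverse squared great-circle distance on the unit
    scalp sphere; restricting to the local neighborhood keeps the estimate
    from regressing toward the whole-scalp mean. The weighting function is
    isolated here so a spherical-spline kernel could be swapped in without
    touching callers. Good channels pass through untouched.
    """
    if positions is None:
        positions = channel_positions(rec.channel_labels)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (rec.n_channels, 3):
        raise InvalidRecordingError(
            f"positions must be ({rec.n_channels}, 3), got {positions.shape}"
        )
    dist = great_circle_distances(positions)

    new_blocks = []
    for block, bads in zip(rec.participant_blocks, rec.bad_channels):
        bad_idx = [rec.channel_labels.index(lab) for lab in bads]
        if not bad_idx:
            new_blocks.append(block)
            continue
        good_idx = [i for i in range(rec.n_channels) if i not in set(bad_idx)]
        if not good_idx:
            raise InvalidRecordingError("all channels marked bad; recording unrecoverable")
        out = block.copy()
        n_neighbors = min(4, len(good_idx))
        for i in bad_idx:
            d = dist[i, good_idx]
            sel = np.argsort(d)[:n_neighbors]
            with np.errstate(divide="ignore"):
                w = 1.0 / d[sel] ** 2
            if np.any(np.isinf(w)):  # coincident electrode: copy it outright
                w = np.where(np.isinf(w), 1.0, 0.0)
            w = w / w.sum()
            out[i] = w @ block[np.asarray(good_idx)[sel]]
        new_blocks.append(out)
    return replace(rec, participant_blocks=tuple(new_blocks), bad_channels=((), ()))


def hilbert_phase(rec: DualRecording, trim_seconds: float = TRIM_SECONDS) -> PhaseSet:
    """Analytic signal and instantaneous phase via the Hilbert transform.

    Requires narrow-band input (``band_tag`` set); a broadband instantaneous
    phase is not interpretable. The edge trim is
    ``max(trim_seconds, 3 / band_low)`` seconds per edge — at least three
    periods of the band's slowest component — flagged in ``trim_samples``
    and excluded from every downstream synchrony sum.
    """
    if rec.band_tag is None:
        raise InvalidRecordingError("hilbert_phase requires band-limited input (band_tag set)")
    if rec.band_tag in BANDS:
        trim_seconds = max(trim_seconds, 3.0 / BANDS[rec.band_tag][0])
    trim = int(np.ceil(rec.sampling_rate * trim_seconds))
    if 2 * trim >= rec.n_samples:
        raise InvalidRecordingError(
            f"recording too short: {rec.n_samples} samples, edge trim {trim} per side"
        )
    analytic = tuple(sps.hilbert(block, axis=1) for block in rec.participant_blocks)
    for block in analytic:
        if np.allclose(np.abs(block), 0.0):
            raise InvalidRecordingError("degenerate all-zero signal; phase undefined")
    phases = tuple(np.angle(block) for block in analytic)
    return PhaseSet(
        phases=phases,
        analytic_signals=analytic,
        sampling_rate=rec.sampling_rate,
        channel_labels=rec.channel_labels,
        band_tag=rec.band_tag,
        trim_samples=trim,
    )
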