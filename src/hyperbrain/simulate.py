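"""Synthetic dual-EEG and tapping generators with known ground-truth coupling.

The EEG generator is a Kuramoto-style network of phase oscillators: every
channel carries one oscillator whose natural frequency is drawn uniformly
within the chosen carrier band, with mean-field sine coupling of strength
``k_intra_1`` / ``k_intra_2`` among a participant's own channels and
``k_inter`` across participants, integrated by Euler steps. The emitted
signal is ``cos(phase)`` plus 1/f-shaped additive noise. Each channel also
carries a fixed Sakaguchi frustration angle from a deterministic gradient
across the array, so under strong coupling the channels lock at
heterogeneous constant offsets from the cluster phase rather than
collapsing onto a single zero-lag waveform. One knob per
coupling pathway makes the extremes analytically predictable: with zero
coupling all channels drift independently (synchrony estimators go to their
null levels), with coupling much larger than the band's frequency
dispersion the network phase-locks (inter-brain PLV near 1).

The tap generator produces dyadic anti-phase tapping: participant 1 taps at
cumulative sums of a requested inter-tap interval plus Gaussian jitter;
participant 2 taps at a fixed fraction of each of participant 1's intervals
(0.5 = perfect anti-phase), plus its own jitter.

Seeding: a root seed spawns one deterministic substream per (participant,
channel), so adding channels never reshuffles the signals of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import TapRecord
from .preprocessing import BANDS, DualRecording

#: Seconds of simulated signal discarded at the start so coupling equilibrates.
BURN_IN_SECONDS = 1.0

#: Default std-dev of per-channel white frequency jitter, Hz (phase diffusion).
#: Sets each oscillator's linewidth; kept small so nearly all power stays in band.
FREQ_JITTER_SD_HZ = 0.05

#: Default half-width (radians) of the per-channel Sakaguchi frustration
#: gradient. Channel c's coupling is frustrated by an angle evenly spaced in
#: [-spread, +spread] across the array, so under coupling the channels lock at
#: heterogeneous, stable offsets from the cluster phase (a crude analogue of a
#: conduction-delay gradient); with zero coupling it has no effect at all.
PHASE_LAG_SPREAD = 1.2


class InvalidConfigError(ValueError):
    """Raised for simulation configs that violate their invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dual-EEG recording."""

    duration: float
    carrier_band: str = "theta"
    n_channels_per_participant: int = 29
    sampling_rate: float = 500.0
    k_intra_1: float = 0.0
    k_intra_2: float = 0.0
    k_inter: float = 0.0
    noise_sd: float = 0.0
    freq_jitter_sd: float = FREQ_JITTER_SD_HZ
    phase_lag_spread: float = PHASE_LAG_SPREAD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidConfigError("duration and sampling_rate must be positive")
        if self.carrier_band not in BANDS:
            raise InvalidConfigError(f"carrier_band must be one of {sorted(BANDS)}")
        for name in ("k_intra_1", "k_intra_2", "k_inter", "noise_sd", "freq_jitter_sd",
                     "phase_lag_spread"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise InvalidConfigError(f"{name} must be finite and non-negative")
        if self.n_channels_per_participant < 1:
            raise InvalidConfigError("need at least one channel per participant")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise InvalidConfigError("duration x sampling_rate must be an integer sample count")


@dataclass(frozen=True)
class TapSimConfig:
    """Parameters of one synthetic dyadic anti-phase tapping session."""

    requested_iti: float = 0.5
    jitter_sd: float = 0.02
    n_taps_per_participant: int = 150
    phase_offset_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taps_per_participant < 2:
            raise InvalidConfigError("need at least 2 taps per participant")
        if not 0 < self.phase_offset_fraction < 1:
            raise InvalidConfigError("phase_offset_fraction must lie strictly in (0, 1)")
        if self.jitter_sd < 0 or self.requested_iti <= 0:
            raise InvalidConfigError("jitter_sd must be >= 0 and requested_iti > 0")


def _channel_rng(seed: int, participant: int, channel: int) -> np.random.Generator:
    # Keyed substream: channel-count changes never reshuffle other channels.
    return np.random.default_rng(np.random.SeedSequence((seed, participant, channel)))


def _one_over_f_noise(rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """Unit-variance noise with an approximately 1/f amplitude spectrum.

    White Gaussian noise is shaped in the frequency domain by 1/sqrt(f)
    (power ~ 1/f) with the DC bin zeroed; the result is standardised.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_coupled_pair(config: SimulationConfig) -> DualRecording:
    """Simulate one dual recording with the configured coupling structure.

    Returns two (n_channels, n_samples) blocks where
    ``n_samples = duration * sampling_rate``; an extra burn-in second is
    simulated and discarded so the coupled dynamics have equilibrated.
    Bit-identical for identical configs.
    """
    n_ch = config.n_channels_per_participant
    fs = config.sampling_rate
    dt = 1.0 / fs
    n_burn = int(round(BURN_IN_SECONDS * fs))
    n_keep = int(round(config.duration * fs))
    n_total = n_burn + n_keep
    low, high = BANDS[config.carrier_band]

    # Per-channel natural frequencies, initial phases, and noise streams.
    omega = np.empty((2, n_ch))
    theta = np.empty((2, n_ch))
    alpha = np.empty((2, n_ch))
    jitter = np.empty((2, n_ch, n_total))
    noise = np.zeros((2, n_ch, n_keep))
    for p in range(2):
        for c in range(n_ch):
            rng = _channel_rng(config.seed, p, c)
            omega[p, c] = 2.0 * np.pi * rng.uniform(low, high)
            theta[p, c] = rng.uniform(-np.pi, np.pi)
            jitter[p, c] = rng.standard_normal(n_total)
            if config.noise_sd > 0:
                noise[p, c] = config.noise_sd * _one_over_f_noise(rng, n_keep)
        # Deterministic frustration gradient across the channel array: under
        # coupling, channel c locks about alpha[c] away from the cluster
        # phase, so every channel pair sees a stable, nonzero lag.
        if n_ch > 1:
            alpha[p] = np.linspace(-config.phase_lag_spread, config.phase_lag_spread, n_ch)
        else:
            alpha[p] = 0.0

    k = np.array(
        [[config.k_intra_1, config.k_inter], [config.k_inter, config.k_intra_2]]
    )
    jitter_scale = 2.0 * np.pi * config.freq_jitter_sd * np.sqrt(dt)

    phases = np.empty((2, n_ch, n_total))
    for t in range(n_total):
        phases[:, :, t] = theta
        # Mean-field coupling via the per-participant Kuramoto order parameter.
        z = np.exp(1j * theta).mean(axis=1)  # shape (2,)
        drive = np.zeros((2, n_ch))
        for p in range(2):
            for q in range(2):
                if k[p, q] > 0:
                    drive[p] += k[p, q] * np.abs(z[q]) * np.sin(
                        np.angle(z[q]) - theta[p] - alpha[p]
                    )
        theta = theta + dt * (omega + drive) + jitter_scale * jitter[:, :, t]

    kept = phases[:, :, n_burn:]
    signals = np.cos(kept) + noise
    labels = tuple(f"SIM{i:02d}" for i in range(n_ch))
    return DualRecording(
        participant_blocks=(signals[0], signals[1]),
        sampling_rate=fs,
        channel_labels=labels,
        band_tag=None,
    )


def generate_tap_series(config: TapSimConfig) -> tuple[TapRecord, TapRecord]:
    """Simulate one dyad's alternating tap-onset sequences.

    Participant 1's onsets are cumulative sums of
    ``requested_iti + N(0, jitter_sd)``; participant 2 taps at
    ``phase_offset_fraction`` of each of participant 1's intervals, plus its
    own jitter, clipped to stay strictly inside the interval so the merged
    stream remains alternating.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9)))
    n = config.n_taps_per_participant
    itis = config.requested_iti + config.jitter_sd * rng.standard_normal(n - 1)
    itis = np.maximum(itis, 0.05 * config.requested_iti)  # keep strictly increasing
    p1 = np.concatenate([[0.0], np.cumsum(itis)])

    intervals = np.diff(p1)
    offsets = config.phase_offset_fraction * intervals
    offsets = offsets + config.jitter_sd * rng.standard_normal(n - 1)
    eps = 1e-6
    offsets = np.clip(offsets, eps, intervals - eps)
    p2_inside = p1[:-1] + offsets
    # One final p2 tap after p1's last onset keeps the counts equal.
    last = p1[-1] + config.phase_offset_fraction * intervals[-1]
    p2 = np.concatenate([p2_inside, [last]])

    return (
        TapRecord(onsets=p1, participant_id="sim_p1"),
        TapRecord(onsets=p2, participant_id="sim_p2"),
    )
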