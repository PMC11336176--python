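from __future__ import annotations

import numpy as np
import pytest

from hyperbrain.preprocessing import DualRecording
from hyperbrain.surrogate import HyperbrainGraph


def make_graph(adj: np.ndarray, modules: np.ndarray | None = None) -> HyperbrainGraph:
    """Wrap a plain adjacency matrix into a HyperbrainGraph for metric tests."""
    adj = np.asarray(adj, dtype=int)
    n = adj.shape[0]
    if modules is None:
        modules = np.where(np.arange(n) < n // 2, 1, 2)
    return HyperbrainGraph(
        adjacency=adj,
        node_labels=tuple(f"n{i}" for i in range(n)),
        module_of=np.asarray(modules),
        band_tag="theta",
    )


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.3) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(int)


def sine_recording(
    freqs_hz,
    duration: float = 4.0,
    fs: float = 500.0,
    phases=None,
    band_tag: str | None = None,
) -> DualRecording:
    """Two identical blocks of pure sinusoids, one frequency per channel."""
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    phases = np.zeros_like(freqs) if phases is None else np.atleast_1d(phases)
    t = np.arange(int(duration * fs)) / fs
    block = np.array([np.cos(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)])
    return DualRecording(
        participant_blocks=(block, block.copy()),
        sampling_rate=fs,
        channel_labels=tuple(f"ch{i}" for i in range(len(freqs))),
        band_tag=band_tag,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240229)
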