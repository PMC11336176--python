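"""Fourier phase-randomization surrogates and the binary hyperbrain graph.

To decide which of a dyad's 1653 channel pairs (2 x 406 intra + 841 inter
for 29+29 channels) carry above-chance synchrony, each channel is
phase-randomized independently in the frequency domain: the phases of the
positive-frequency Fourier bins are randomly permuted while every bin's
amplitude — hence the power spectrum — is preserved exactly, and DC/Nyquist
stay real. This destroys all phase relations within and between brains
while keeping each channel's autospectrum, giving a proper null for both
wPLI and PLV.

Each channel pair's original metric is then compared against its surrogate
distribution with a one-sided predictive one-sample t-test (see
:func:`significance_mask`), Bonferroni-corrected over all tested pairs.
Pairs whose original synchrony significantly exceeds the surrogate level
become edges of a (2n x 2n) binary undirected hyperbrain graph whose first
n nodes are participant 1's channels and whose modules are the two brains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .connectivity import SyncMatrices, compute_sync_matrices
from .preprocessing import DualRecording, hilbert_phase

DEFAULT_N_SURROGATES = 100
DEFAULT_ALPHA = 0.05


@dataclass
class SurrogateEnsemble:
    """Per-pair surrogate metric distributions for one dyad/band/condition.

    ``intra_1``/``intra_2``: (n_surrogates, n_ch, n_ch) wPLI arrays;
    ``inter``: (n_surrogates, n_ch, n_ch) PLV arrays.
    """

    intra_1: np.ndarray
    intra_2: np.ndarray
    inter: np.ndarray
    band_tag: str
    seed: int | None = None

    @property
    def n_surrogates(self) -> int:
        return self.intra_1.shape[0]


@dataclass
class HyperbrainGraph:
    """Binary undirected adjacency over both participants' channels.

    Node i < n belongs to participant 1 (module 1), node i >= n to
    participant 2 (module 2). Block layout::

        [ intra_1      inter   ]
        [ inter.T      intra_2 ]
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    module_of: np.ndarray
    band_tag: str
    condition: str | None = None
    alpha_per_test: float = float("nan")
    n_tests: int = 0
    n_flagged_degenerate: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = adj.astype(np.int8)
        self.module_of = np.asarray(self.module_of, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def block_edge_counts(self) -> dict[str, int]:
        """Undirected edge counts in the intra-1, intra-2, and inter blocks."""
        n = self.n_nodes // 2
        a = self.adjacency
        iu = np.triu_indices(n, k=1)
        return {
            "intra_1": int(a[:n, :n][iu].sum()),
            "intra_2": int(a[n:, n:][iu].sum()),
            "inter": int(a[:n, n:].sum()),
        }


def phase_randomize(sig: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spectrum-preserving Fourier surrogate of one real series.

    The phase values of the positive-frequency bins are randomly permuted
    among those bins; bin amplitudes are untouched, and the DC (and Nyquist,
    for even length) bins remain real, so the inverse transform is real and
    the periodogram matches the original bin-for-bin.
    """
    x = np.asarray(sig, dtype=float)
    if x.ndim != 1:
        raise ValueError("phase_randomize expects a 1-D series")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    spec = np.fft.rfft(x)
    n = x.size
    # Positive-frequency bins excluding DC and (for even n) Nyquist.
    stop = spec.size - 1 if n % 2 == 0 else spec.size
    amps = np.abs(spec[1:stop])
    phases = np.angle(spec[1:stop])
    permuted = rng.permutation(phases)
    new_spec = spec.copy()
    new_spec[1:stop] = amps * np.exp(1j * permuted)
    return np.fft.irfft(new_spec, n=n)


def build_ensemble(
    rec: DualRecording,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | None = None,
) -> SurrogateEnsemble:
    """Surrogate metric distributions for every channel pair of one dyad.

    ``rec`` must already be band-limited (the same input
    :func:`~hyperbrain.connectivity.compute_sync_matrices` sees). For each
    replicate every channel of both participants is independently
    phase-randomized, Hilbert phases are recomputed, and the full intra-wPLI
    / inter-PLV set is evaluated. Each (replicate, channel) gets its own
    deterministic substream of ``seed``.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates to form a distribution")
    if rec.band_tag is None:
        raise ValueError("surrogates require band-limited input")
    n_ch = rec.n_channels
    intra_1 = np.empty((n_surrogates, n_ch, n_ch))
    intra_2 = np.empty((n_surrogates, n_ch, n_ch))
    inter = np.empty((n_surrogates, n_ch, n_ch))
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_surrogates)
    for r in range(n_surrogates):
        child = streams[r].spawn(2 * n_ch)
        blocks = []
        for p, block in enumerate(rec.participant_blocks):
            out = np.empty_like(block)
            for c in range(n_ch):
                rng = np.random.default_rng(child[p * n_ch + c])
                out[c] = phase_randomize(block[c], rng)
            blocks.append(out)
        surr_rec = DualRecording(
            participant_blocks=(blocks[0], blocks[1]),
            sampling_rate=rec.sampling_rate,
            channel_labels=rec.channel_labels,
            band_tag=rec.band_tag,
        )
        sync = compute_sync_matrices(hilbert_phase(surr_rec))
        intra_1[r] = sync.intra_1
        intra_2[r] = sync.intra_2
        inter[r] = sync.inter
    return SurrogateEnsemble(
        intra_1=intra_1, intra_2=intra_2, inter=inter, band_tag=rec.band_tag, seed=seed
    )


def _one_sided_p(
    originals: np.ndarray, surrogates: np.ndarray, original_variance: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair one-sided p-values that the original exceeds the surrogate level.

    Returns (p, degenerate_mask). ``original_variance="predict"`` uses the
    predictive standard error s*sqrt(1 + 1/n), which treats the original
    value as one further draw from the null and is near-calibrated;
    ``"ignore"`` uses the plain one-sample standard error s/sqrt(n), which
    treats the original as a fixed population mean and is strongly
    anti-conservative under the null.
    """
    n = surrogates.shape[0]
    mean = surrogates.mean(axis=0)
    sd = surrogates.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    scale = np.sqrt(1.0 + 1.0 / n) if original_variance == "predict" else np.sqrt(1.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (originals - mean) / (sd * scale)
    p = sstats.t.sf(t, df=n - 1)
    # Zero surrogate variance: no distribution to test against -> no edge.
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


def significance_mask(
    original: SyncMatrices,
    ens: SurrogateEnsemble,
    alpha: float = DEFAULT_ALPHA,
    condition: str | None = None,
    original_variance: str = "predict",
    n_tests: int | None = None,
) -> HyperbrainGraph:
    """Threshold every channel pair against its surrogate null distribution.

    A pair becomes an edge iff its original wPLI (intra) or PLV (inter)
    exceeds the surrogate mean AND the one-sided test of the original
    against the surrogate distribution survives Bonferroni correction over
    all tested pairs (``alpha / n_tests``; 1653 for 29+29 channels, or pass
    ``n_tests`` to fix the denominator). The result is assembled into the
    symmetric binary hyperbrain adjacency.
    """
    if original_variance not in ("predict", "ignore"):
        raise ValueError("original_variance must be 'predict' or 'ignore'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_ch = original.n_channels
    if ens.intra_1.shape[1] != n_ch:
        raise ValueError("ensemble and original cover different channel counts")
    iu = np.triu_indices(n_ch, k=1)
    m = n_tests if n_tests is not None else 2 * len(iu[0]) + n_ch * n_ch
    alpha_per_test = alpha / m

    p1, d1 = _one_sided_p(original.intra_1, ens.intra_1, original_variance)
    p2, d2 = _one_sided_p(original.intra_2, ens.intra_2, original_variance)
    pi, di = _one_sided_p(original.inter, ens.inter, original_variance)

    above_1 = original.intra_1 > ens.intra_1.mean(axis=0)
    above_2 = original.intra_2 > ens.intra_2.mean(axis=0)
    above_i = original.inter > ens.inter.mean(axis=0)

    edge_1 = (p1 < alpha_per_test) & above_1
    edge_2 = (p2 < alpha_per_test) & above_2
    edge_i = (pi < alpha_per_test) & above_i
    # Intra matrices are symmetric with a NaN diagonal; enforce exactly.
    edge_1 = np.triu(edge_1, k=1)
    edge_1 = edge_1 | edge_1.T
    edge_2 = np.triu(edge_2, k=1)
    edge_2 = edge_2 | edge_2.T

    adj = np.zeros((2 * n_ch, 2 * n_ch), dtype=np.int8)
    adj[:n_ch, :n_ch] = edge_1
    adj[n_ch:, n_ch:] = edge_2
    adj[:n_ch, n_ch:] = edge_i
    adj[n_ch:, :n_ch] = edge_i.T

    labels = tuple(f"p1:{c}" for c in original.channel_labels) + tuple(
        f"p2:{c}" for c in original.channel_labels
    )
    n_degenerate = int(d1[iu].sum() + d2[iu].sum() + di.sum())
    return HyperbrainGraph(
        adjacency=adj,
        node_labels=labels,
        module_of=np.repeat([1, 2], n_ch),
        band_tag=original.band_tag,
        condition=condition,
        alpha_per_test=alpha_per_test,
        n_tests=m,
        n_flagged_degenerate=n_degenerate,
    )
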