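"""Phase-synchrony estimators: wPLI within brains, PLV between brains.

The weighted phase lag index (wPLI) of two narrow-band signals is

    wPLI = | sum_t |Im(C_t)| sgn(Im(C_t)) | / sum_t |Im(C_t)|

with ``C_t = x_t * conj(y_t)`` the per-sample cross-spectrum of the Hilbert
analytic signals. Because only the imaginary part enters, zero-lag
(volume-conducted) synchrony contributes nothing — the reason wPLI is used
for intra-brain channel pairs, where a single cortical source can project
to many electrodes. When every Im(C_t) is zero (identical or exactly
in/anti-phase signals) the estimator is 0/0; by convention we return 0,
consistent with discounting zero-lag coupling.

The phase locking value (PLV) of two phase series is

    PLV = (1/T) | sum_t exp(j (phi_t - psi_t)) |

and is used for inter-brain pairs, where volume conduction between two
physically separate heads is impossible.

For a 29+29-channel dyad this yields 406 unordered intra-brain pairs per
participant and 841 ordered inter-brain pairs (29 x 29).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import PhaseSet


@dataclass
class SyncMatrices:
    """Synchrony matrices of one dyad in one band/condition.

    ``intra_1`` / ``intra_2``: symmetric (n, n) wPLI with NaN diagonal.
    ``inter``: (n, n) PLV, rows = participant-1 channels, columns =
    participant-2 channels; not symmetric in general.
    """

    intra_1: np.ndarray
    intra_2: np.ndarray
    inter: np.ndarray
    channel_labels: tuple[str, ...]
    band_tag: str
    n_samples_used: int

    @property
    def n_channels(self) -> int:
        return self.inter.shape[0]

    def intra_pair_values(self, participant: int) -> np.ndarray:
        """The C(n,2) distinct off-diagonal values of one intra matrix."""
        mat = (self.intra_1, self.intra_2)[participant]
        iu = np.triu_indices(mat.shape[0], k=1)
        return mat[iu]


@dataclass
class AverageSyncSummary:
    """Grand averages over all intra pairs (per participant) and inter pairs."""

    averaged_wpli: tuple[float, float]
    averaged_plv: float
    band_tag: str
    n_intra_pairs: int
    n_inter_pairs: int
    n_excluded: int = 0


def wpli(x_analytic: np.ndarray, y_analytic: np.ndarray) -> float:
    """wPLI of two equal-length analytic (complex) series, in [0, 1]."""
    x = np.asarray(x_analytic)
    y = np.asarray(y_analytic)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    cross = x * np.conj(y)
    imag_c = np.imag(cross)
    denom = np.abs(imag_c).sum()
    # 0/0 guard with float tolerance: exactly in/anti-phase signals leave
    # only rounding residue in Im(C) relative to the cross-spectrum power.
    if denom <= 1e-12 * np.abs(cross).sum():
        return 0.0
    return float(np.abs(imag_c.sum()) / denom)


def plv(phase_i: np.ndarray, phase_k: np.ndarray) -> float:
    """Phase locking value of two equal-length phase series, in [0, 1]."""
    a = np.asarray(phase_i, dtype=float)
    b = np.asarray(phase_k, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("need at least 1 sample")
    return float(np.abs(np.exp(1j * (a - b)).mean()))


def _wpli_matrix(analytic: np.ndarray, chunk: int = 512) -> np.ndarray:
    """All-pairs wPLI of one participant's analytic block (n_ch, T).

    Im(x conj y) = Im(x) Re(y) - Re(x) Im(y), so the numerator's inner sum
    collapses to one matrix product; the denominator needs per-sample
    absolute values and is accumulated over time chunks.
    """
    re = np.real(analytic)
    im = np.imag(analytic)
    num = im @ re.T - re @ im.T  # sum_t Im(C_xy,t), antisymmetric
    n_ch, T = analytic.shape
    den = np.zeros((n_ch, n_ch))
    for start in range(0, T, chunk):
        r = re[:, start : start + chunk]
        i = im[:, start : start + chunk]
        imc = i[:, None, :] * r[None, :, :] - r[:, None, :] * i[None, :, :]
        den += np.abs(imc).sum(axis=2)
    # 0/0 guard with float tolerance, as in the scalar estimator.
    amp = np.abs(analytic)
    power = amp @ amp.T
    degenerate = den <= 1e-12 * power
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.abs(num) / den
    mat[degenerate] = 0.0
    np.fill_diagonal(mat, np.nan)
    return mat


def intra_matrices(phases: PhaseSet) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric wPLI matrices for both participants (edge trim applied)."""
    a, b = phases.trimmed_analytic()
    return _wpli_matrix(a), _wpli_matrix(b)


def inter_matrix(phases: PhaseSet) -> np.ndarray:
    """PLV over all cross-participant channel pairs (edge trim applied).

    Entry (i, k) is the PLV between participant 1's channel i and
    participant 2's channel k; all n^2 ordered pairs are populated.
    """
    ph1, ph2 = phases.trimmed_phases()
    u1 = np.exp(1j * ph1)
    u2 = np.exp(1j * ph2)
    T = ph1.shape[1]
    return np.abs(u1 @ np.conj(u2).T) / T


def compute_sync_matrices(phases: PhaseSet) -> SyncMatrices:
    """wPLI intra matrices plus PLV inter matrix for one preprocessed dyad."""
    intra_1, intra_2 = intra_matrices(phases)
    inter = inter_matrix(phases)
    T = phases.trimmed_phases()[0].shape[1]
    return SyncMatrices(
        intra_1=intra_1,
        intra_2=intra_2,
        inter=inter,
        channel_labels=phases.channel_labels,
        band_tag=phases.band_tag,
        n_samples_used=T,
    )


def average_sync(sync: SyncMatrices) -> AverageSyncSummary:
    """Arithmetic means over all intra pairs (per participant) and inter pairs.

    NaN entries (beyond the masked diagonal) are excluded and counted.
    """
    vals_1 = sync.intra_pair_values(0)
    vals_2 = sync.intra_pair_values(1)
    inter_vals = sync.inter.ravel()
    n_excluded = int(
        np.isnan(vals_1).sum() + np.isnan(vals_2).sum() + np.isnan(inter_vals).sum()
    )
    return AverageSyncSummary(
        averaged_wpli=(float(np.nanmean(vals_1)), float(np.nanmean(vals_2))),
        averaged_plv=float(np.nanmean(inter_vals)),
        band_tag=sync.band_tag,
        n_intra_pairs=vals_1.size,
        n_inter_pairs=inter_vals.size,
        n_excluded=n_excluded,
    )
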