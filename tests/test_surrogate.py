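"""Fourier phase-randomization surrogates and significance thresholding."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from hyperbrain import (
    SimulationConfig,
    bandpass_named,
    build_ensemble,
    compute_sync_matrices,
    downsample,
    generate_coupled_pair,
    hilbert_phase,
    phase_randomize,
    plv,
    significance_mask,
)
from hyperbrain.connectivity import SyncMatrices
from hyperbrain.surrogate import SurrogateEnsemble


def _coupled_recording(k=12.0, seed=0, n_ch=4, duration=12.0):
    cfg = SimulationConfig(
        duration=duration, n_channels_per_participant=n_ch, seed=seed,
        k_inter=k, k_intra_1=k, k_intra_2=k, noise_sd=0.2, freq_jitter_sd=0.4,
    )
    return bandpass_named(downsample(generate_coupled_pair(cfg), 250.0), "theta")


class TestPhaseRandomize:
    def test_power_spectrum_preserved_bin_for_bin(self, rng):
        x = rng.standard_normal(1024)
        y = phase_randomize(x, np.random.default_rng(0))
        px = np.abs(np.fft.rfft(x)) ** 2
        py = np.abs(np.fft.rfft(y)) ** 2
        np.testing.assert_allclose(py, px, rtol=1e-9, atol=1e-9 * px.max())

    def test_odd_length_spectrum_preserved(self, rng):
        x = rng.standard_normal(1001)
        y = phase_randomize(x, np.random.default_rng(1))
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)), rtol=1e-9
        )

    def test_output_real_and_variance_preserved(self, rng):
        x = rng.standard_normal(4096)
        y = phase_randomize(x, np.random.default_rng(2))
        assert np.isrealobj(y)
        assert y.var() == pytest.approx(x.var(), rel=1e-9)

    def test_deterministic_given_rng(self, rng):
        x = rng.standard_normal(512)
        a = phase_randomize(x, np.random.default_rng(5))
        b = phase_randomize(x, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            phase_randomize(np.ones(3), np.random.default_rng(0))

    def test_destroys_coupling_between_channels(self):
        # Two strongly coupled channels, independently randomized, must lose
        # their phase locking down to the independent-signal null level.
        rec = _coupled_recording(k=12.0, seed=3, n_ch=4, duration=24.0)
        x = rec.participant_blocks[0][0]
        y = rec.participant_blocks[1][0]
        phi_x = np.angle(sps.hilbert(x))[500:-500]
        phi_y = np.angle(sps.hilbert(y))[500:-500]
        original = plv(phi_x, phi_y)
        surr_vals = []
        for s in range(20):
            xs = phase_randomize(x, np.random.default_rng(100 + s))
            ys = phase_randomize(y, np.random.default_rng(200 + s))
            surr_vals.append(
                plv(np.angle(sps.hilbert(xs))[500:-500], np.angle(sps.hilbert(ys))[500:-500])
            )
        assert max(surr_vals) < original


class TestBuildEnsemble:
    def test_bookkeeping_counts(self):
        rec = _coupled_recording(k=0.0, seed=1, n_ch=3, duration=6.0)
        ens = build_ensemble(rec, 4, seed=9)
        assert ens.n_surrogates == 4
        assert ens.intra_1.shape == (4, 3, 3)
        assert ens.inter.shape == (4, 3, 3)
        iu = np.triu_indices(3, k=1)
        # 2 x C(3,2) intra + 9 inter = 15 pairs, each with 4 values
        n_values = 2 * 4 * iu[0].size + 4 * 9
        assert n_values == 4 * 15

    def test_deterministic_under_seed(self):
        rec = _coupled_recording(k=0.0, seed=2, n_ch=3, duration=6.0)
        a = build_ensemble(rec, 3, seed=5)
        b = build_ensemble(rec, 3, seed=5)
        assert np.array_equal(a.inter, b.inter)
        assert np.array_equal(a.intra_1, b.intra_1, equal_nan=True)

    def test_too_few_surrogates_rejected(self):
        rec = _coupled_recording(k=0.0, seed=1, n_ch=3, duration=6.0)
        with pytest.raises(ValueError):
            build_ensemble(rec, 1, seed=0)

    def test_values_within_unit_interval(self):
        rec = _coupled_recording(k=0.0, seed=4, n_ch=3, duration=6.0)
        ens = build_ensemble(rec, 3, seed=1)
        for arr in (ens.intra_1, ens.intra_2, ens.inter):
            finite = arr[np.isfinite(arr)]
            assert np.all((finite >= 0) & (finite <= 1 + 1e-12))


def _toy_sync(n_ch, intra_val, inter_val):
    intra = np.full((n_ch, n_ch), float(intra_val))
    np.fill_diagonal(intra, np.nan)
    return SyncMatrices(
        intra_1=intra, intra_2=intra.copy(), inter=np.full((n_ch, n_ch), float(inter_val)),
        channel_labels=tuple(f"c{i}" for i in range(n_ch)), band_tag="theta",
        n_samples_used=1000,
    )


def _toy_ensemble(n_ch, n_surr, mean, sd, seed=0):
    rng = np.random.default_rng(seed)
    shape = (n_surr, n_ch, n_ch)
    return SurrogateEnsemble(
        intra_1=np.clip(rng.normal(mean, sd, shape), 0, 1),
        intra_2=np.clip(rng.normal(mean, sd, shape), 0, 1),
        inter=np.clip(rng.normal(mean, sd, shape), 0, 1),
        band_tag="theta",
    )


class TestSignificanceMask:
    def test_overwhelming_separation_gives_edges(self):
        sync = _toy_sync(4, 0.9, 0.9)
        ens = _toy_ensemble(4, 100, 0.1, 0.02)
        g = significance_mask(sync, ens)
        assert g.adjacency.sum() == 4 * 4 * 2 + 2 * 2 * 6  # all 28 pairs, doubled

    def test_original_below_surrogate_mean_never_an_edge(self):
        sync = _toy_sync(4, 0.05, 0.05)
        ens = _toy_ensemble(4, 100, 0.5, 0.3)
        g = significance_mask(sync, ens)
        assert g.adjacency.sum() == 0

    def test_zero_surrogate_variance_flagged_no_edge(self):
        sync = _toy_sync(3, 0.5, 0.5)
        ens = _toy_ensemble(3, 10, 0.5, 0.0)
        ens.intra_1[:] = 0.5
        ens.intra_2[:] = 0.5
        ens.inter[:] = 0.5
        g = significance_mask(sync, ens)
        assert g.adjacency.sum() == 0
        assert g.n_flagged_degenerate == 2 * 3 + 9

    def test_graph_structure_invariants(self):
        sync = _toy_sync(5, 0.9, 0.9)
        ens = _toy_ensemble(5, 50, 0.2, 0.05, seed=3)
        g = significance_mask(sync, ens)
        adj = g.adjacency
        assert adj.shape == (10, 10)
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        n = 5
        assert np.array_equal(adj[:n, n:], adj[n:, :n].T)
        assert g.n_tests == 2 * 10 + 25
        assert g.alpha_per_test == pytest.approx(0.05 / 45)

    def test_monotone_in_original_synchrony(self):
        # Raising original values (ensemble fixed) can only add edges.
        rng = np.random.default_rng(8)
        ens = _toy_ensemble(4, 60, 0.3, 0.1, seed=2)
        base = _toy_sync(4, 0.4, 0.4)
        noise = rng.uniform(0, 0.2, (4, 4))
        base.intra_1 += (noise + noise.T) / 2
        base.inter += rng.uniform(0, 0.2, (4, 4))
        g1 = significance_mask(base, ens)
        boosted = _toy_sync(4, 0.4, 0.4)
        boosted.intra_1 = base.intra_1 + 0.05
        boosted.intra_2 = base.intra_2 + 0.05
        boosted.inter = base.inter + 0.05
        g2 = significance_mask(boosted, ens)
        assert np.all(g2.adjacency >= g1.adjacency)

    def test_fully_coupled_pair_yields_complete_graph(self):
        # End-to-end: strong coupling with stable channel lags must connect
        # every pair once surrogates are compared against the original.
        rec = _coupled_recording(k=12.0, seed=6, n_ch=3, duration=30.0)
        sync = compute_sync_matrices(hilbert_phase(rec))
        ens = build_ensemble(rec, 30, seed=11)
        g = significance_mask(sync, ens)
        n_pairs = 2 * 3 + 9  # 15 for a 3+3-channel dyad
        assert g.n_tests == n_pairs
        assert np.triu(g.adjacency, k=1).sum() >= 0.8 * n_pairs

    def test_naive_variance_mode_is_more_liberal(self):
        sync = _toy_sync(4, 0.45, 0.45)
        ens = _toy_ensemble(4, 60, 0.35, 0.08, seed=5)
        g_pred = significance_mask(sync, ens, original_variance="predict")
        g_naive = significance_mask(sync, ens, original_variance="ignore")
        assert g_naive.adjacency.sum() >= g_pred.adjacency.sum()
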