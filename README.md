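# hyperbrain

Dual-EEG ("hyperscanning") network analysis for dyads performing
anti-phase joint tapping: from two participants' synchronized multichannel
EEG and tap-onset times to behavioral coordination statistics, intra-brain
wPLI / inter-brain PLV synchrony matrices, surrogate-thresholded binary
hyperbrain networks, and graph-theoretic topology metrics.

It is written for researchers who record two people's EEG simultaneously
(29 channels each, 10/20 montage, 500 Hz) while the pair coordinates a
rhythmic task, and who want a tested, reproducible route from raw signals
to a tidy table of per-dyad network metrics — plus a synthetic-data
generator with known ground-truth coupling so every stage can be validated
without real recordings.

## The method

**Behavior.** Tap onsets t(m) give inter-tap intervals
ITI_m = t(m+1) − t(m) (mean ITI is computed on the merged dyadic stream).
The relative phase of participant 2's tap inside participant 1's interval
is RP_n = [(t(n)_p2 − t(n)_p1) / (t(n+1)_p1 − t(n)_p1)] × 360°, with 180°
= perfect anti-phase. Coordination instability is the circular standard
deviation SDRP = √(−2 ln R), R = |mean exp(j·RP)|.

**Synchrony.** Per frequency band (theta 4–7, alpha 8–12, beta 13–30 Hz),
each channel's instantaneous phase comes from the Hilbert transform of the
zero-phase band-passed signal. Within a brain, every unordered channel
pair (29C2 = 406 per participant) is scored with the weighted phase lag
index

    wPLI = |Σ_t |Im C_t| sgn(Im C_t)| / Σ_t |Im C_t|,   C_t = x_t ȳ_t,

which ignores zero-lag (volume-conducted) synchrony. Between brains, all
29 × 29 = 841 ordered pairs are scored with the phase locking value
PLV = (1/T)|Σ_t e^{j(φ_t − ψ_t)}|.

**Surrogate thresholding.** Each channel is independently
phase-randomized in the Fourier domain (bin amplitudes — hence the power
spectrum — preserved exactly; phases of positive-frequency bins permuted),
n times per dyad. A channel pair becomes an edge when its original metric
exceeds the surrogate mean and a one-sided test of the original against
the surrogate distribution survives Bonferroni correction over all 1653
tested pairs. Edges form one 58 × 58 binary undirected "hyperbrain" graph
per dyad/condition/band.

**Topology.** On that graph: edge number, global efficiency (mean inverse
shortest-path length), local efficiency (mean efficiency of each node's
neighborhood subgraph), Newman modularity Q for the fixed two-module
partition given by participant membership (high Q = two nearly
disconnected brains), plus characteristic path length and clustering
coefficient.

## Worked example

Simulate one strongly coupled dyad (6 channels per participant, theta
carriers, Kuramoto-style coupling k = 12, 40 s), run the full chain, and
print the summary:

```python
from hyperbrain import (SimulationConfig, TapSimConfig, generate_coupled_pair,
    generate_tap_series, summarize_behavior, downsample, bandpass_named,
    hilbert_phase, compute_sync_matrices, average_sync, build_ensemble,
    significance_mask, compute_graph_metrics)

cfg = SimulationConfig(duration=40.0, n_channels_per_participant=6, seed=3,
                       k_inter=12.0, k_intra_1=12.0, k_intra_2=12.0,
                       noise_sd=0.2, freq_jitter_sd=0.4)
rec = bandpass_named(downsample(generate_coupled_pair(cfg), 250.0), "theta")
sync = compute_sync_matrices(hilbert_phase(rec))
avg = average_sync(sync)
ens = build_ensemble(rec, 40, seed=99)
graph = significance_mask(sync, ens)
m = compute_graph_metrics(graph)
p1, p2 = generate_tap_series(TapSimConfig(seed=3))
b = summarize_behavior(p1, p2)
```

Output:

```
averaged_wpli = (0.733, 0.798)
averaged_plv  = 0.821
edges: {'intra_1': 1, 'intra_2': 1, 'inter': 21}  (of 66 tested pairs)
EN=23  GE=0.636  LE=0.314  Q=-0.413
mean_iti=0.249  sdrp=0.232  R=0.973
```

Reading it: the coupled oscillators produce high average intra-brain wPLI
and inter-brain PLV; the surrogate test certifies 23 of the 66 possible
channel pairs as above-chance edges, most of them inter-brain, so the
combined graph is integrated (GE 0.64) and its modularity is strongly
negative (the two "brains" are more interconnected than a degree-matched
null). The simulated tapping alternates at a 0.25 s merged inter-tap
interval with tight anti-phase coordination (R ≈ 0.97). An uncoupled dyad
(k = 0) run through the same chain yields near-null synchrony and an
(almost) empty graph.

The same pipeline runs from the shell over a YAML study configuration:

```bash
hyperbrain run --config study.yaml          # pairs x conditions x bands -> results.tsv
hyperbrain simulate --config sim.yaml --out fixtures/
hyperbrain behavior --taps fixtures/taps.csv
```

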