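# Methods notes

This note records the modeling assumptions, parameter defaults, and
numerical decisions behind the package, in the order data flows through
the pipeline.

## Synthetic dual-EEG generator

The generator exists so that every downstream stage — filtering, phase
extraction, wPLI/PLV, surrogate thresholding, graph metrics — can be
validated against known ground truth. It is a phase-oscillator model, not
a biophysical one.

**Model.** Each of the 2 × n channels carries a phase oscillator with a
natural frequency drawn uniformly in the carrier band (theta 4–7, alpha
8–12, or beta 13–30 Hz). Phases evolve by Euler steps at the sampling
rate with Kuramoto mean-field sine coupling: strength `k_intra_1` /
`k_intra_2` toward the channel's own participant's order parameter,
`k_inter` toward the partner's. The emitted signal is `cos(phase)` plus
optional 1/f-shaped noise (white noise scaled by 1/√f in the frequency
domain, standardized, times `noise_sd`). The first second is simulated
and discarded as burn-in so coupled dynamics are at equilibrium.

**Linewidth (`freq_jitter_sd`, default 0.05 Hz).** Every channel receives
independent white frequency jitter (phase diffusion), giving each
oscillator a finite spectral linewidth. This matters for two reasons:
uncoupled channels must decorrelate (PLV null decays with duration), and
— more subtly — the Fourier-surrogate significance test can only detect
coupling between signals that have bandwidth. Two signals locked onto one
infinitely narrow line keep PLV ≈ 1 after phase randomization (a shared
frequency with a constant random lag), so coupling on a zero-linewidth
carrier is invisible to the surrogate test. The default is kept small so
that, uncoupled and noiseless, more than 95 % of signal power stays
inside the carrier band; experiments that exercise surrogate
detectability (e.g. the group-contrast recovery test) raise it to 0.4 Hz
explicitly, which is the regime where the cluster's common-mode frequency
wanders (broad line, fast surrogate decoherence) while the locked phase
relations within the dyad stay intact.

**Phase-lag gradient (`phase_lag_spread`, default 1.2 rad).** Pure
mean-field coupling drives all channels toward a common phase, and wPLI
is by construction blind to zero-lag synchrony — a perfectly locked
zero-lag network would score *zero* intra-brain wPLI. Real EEG channels
show stable nonzero lags (conduction delays, traveling waves). We emulate
this with a Sakaguchi-style frustration term: channel c's coupling is
`sin(Θ − θ_c − α_c)` with `α_c` evenly spaced in [−spread, +spread]
across the channel array. Under coupling each channel locks at its own
stable offset from the cluster phase, so channel pairs see constant,
heterogeneous, nonzero lags — exactly what wPLI rewards. With zero
coupling the term has no effect. The gradient is deterministic (not
drawn per seed) so the lag structure does not vary across replicates.

**Seeding.** One root seed; per-(participant, channel) substreams via
`SeedSequence((seed, participant, channel))`, so enlarging the montage
never reshuffles existing channels. Identical configs are bit-identical.

**Tapping.** Participant 1 taps at cumulative sums of
`requested_iti + N(0, jitter_sd)` (defaults 0.5 s and 0.02 s; 150 taps,
matching one session of the task the pipeline targets); participant 2
taps at `phase_offset_fraction` (default 0.5 = anti-phase) of each
interval plus its own jitter, clipped to stay inside the interval so the
merged stream alternates.

**What the generator does not emulate.** No volume conduction or forward
model (channels are uncorrelated at zero coupling, unlike real scalp
EEG), no artifacts (blinks, muscle), no nonstationarity beyond phase
diffusion, no realistic 1/f exponent per channel. Passing tests on this
data therefore validate the *estimators and the decision procedure*, not
robustness to real-world recording pathology.

## Preprocessing

* Downsampling: polyphase resampling (`scipy.signal.resample_poly`),
  which embeds a zero-phase FIR anti-alias filter. Default target 250 Hz.
* Band-pass: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`) for exactly zero group delay — any channel-dependent
  delay would corrupt phase metrics. Reflection padding is extended to
  6/low-edge seconds because a 4–7 Hz band of this order rings with a
  ~2 s time constant and the default padding lets transients leak inward.
* Broadband artifact filter 1–45 Hz before band splitting.
* Bad channels (a human-supplied list; there is no automatic detection,
  and manual independent-component cleaning is deliberately outside this
  package) are replaced by an inverse-squared great-circle-distance
  weighted average of the 4 nearest good electrodes on the unit scalp
  sphere. Restricting to the local neighborhood keeps the estimate from
  regressing toward the scalp mean; measured on smooth spatial fields it
  beats a nearest-neighbor copy for interior electrodes. The weighting
  lives behind a single function so a spherical-spline kernel can be
  swapped in. Electrode positions come from MNE's standard 10/20
  template montage at runtime.
* Hilbert phase requires a band tag; the edge trim is
  `max(1 s, 3 / band_low)` per side and is excluded from every synchrony
  sum (`T` in the estimators is the trimmed length).

## Synchrony estimators

* The cross-spectrum in wPLI is formed per sample from the Hilbert
  analytic signals of the whole (trimmed) session; no Welch segmentation
  and no segment averaging. This is the interpretation taken of a
  phase-based pipeline; a segmented variant would be a separate estimator.
* wPLI 0/0 convention: when Σ|Im C| is zero the pair is exactly in or
  anti-phase and the estimator returns 0, consistent with discounting
  zero-lag coupling. The degeneracy test uses a relative tolerance
  (denominator ≤ 1e−12 × cross-spectrum power) because floating-point
  products leave ~1e−17 residue in Im(x·conj(x)).
* The intra matrices are dense symmetric with a masked (NaN) diagonal;
  the inter matrix is rectangular-semantics (rows = participant 1) and
  not symmetric in general.

## Surrogate thresholding

* Surrogates randomize the *phase spectrum* while preserving every bin's
  amplitude: the phases of the positive-frequency bins are permuted
  (DC and Nyquist stay real), per channel, independently — destroying
  intra- and inter-brain phase relations alike.
* Decision rule, per channel pair: edge ⇔ original metric > surrogate
  mean AND one-sided p < α / m with m = number of tested pairs (1653 for
  29+29 channels; recomputed from the actual montage, or fixed via
  `n_tests`).
* The test is a *predictive* one-sample t-test: t = (orig − mean) /
  (s·√(1 + 1/n)), df = n − 1. The √(1+1/n) term treats the original
  value as one further draw from the null rather than a fixed population
  mean. Without it (option `original_variance="ignore"`), the statistic
  is inflated by ≈ √(n+1) under the null and roughly a quarter of all
  null pairs become "significant" even after Bonferroni; with it, the
  spurious-edge rate on zero-coupling data stays orders of magnitude
  below α. The one-sided direction follows from the question asked
  (original larger than surrogates).
* Pairs with zero surrogate variance are flagged and never become edges.

## Graph metrics

* Edge number counts each undirected edge once (the ordered-pair double
  count would exceed the 1653 maximum the thresholding allows).
* Global efficiency is the mean over ordered node pairs of the inverse
  shortest-path *hop count*, with 1/∞ = 0 for unreachable pairs — the
  standard binary-graph definition.
* Local efficiency of node i is the global efficiency of the subgraph
  induced by i's neighbors (paths confined to that neighborhood); nodes
  of degree < 2 contribute 0.
* Modularity is Newman's Q for the fixed two-module participant
  partition; no community detection anywhere.
* Characteristic path length averages over reachable ordered pairs only
  and reports the unreachable fraction alongside; clustering is the mean
  triangle density over nodes (degree < 2 → 0).
* Metrics run on the full 58-node graph including isolated nodes (they
  legitimately depress the efficiencies). Implementation is networkx;
  the test suite checks every metric against independent brute-force
  implementations (Floyd–Warshall + direct summation) to 1e−12 on
  random graphs.

## Group statistics

Welch's t-test (unequal variances, Welch–Satterthwaite df), all-pairs
paired t contrasts with Holm step-down adjustment, and Bonferroni
correction are implemented; Holm is coded directly (a sort plus a
running maximum) so simulation studies can call it 10⁴ times in seconds,
and is cross-checked against statsmodels in the tests. Mixed-effects
group models are intentionally not implemented; the tidy per-(pair,
condition, band) results table is exported for external modeling tools.

## Problem sizes used in the validation suite

Chosen so each property is measured with comfortable statistical margin:
null calibration uses 20 uncoupled 29+29-channel dyads × 50 surrogates
(6 s of signal each); the end-to-end group contrast uses 20 seeds × two
6+6-channel dyads (40 s, 40 surrogates, k = 12 vs 0); oracle equivalence
uses 100+ random 10–20-node graphs; estimator nulls use 100 Monte-Carlo
replicates at T = 5000–10000 samples.

## Known limitations

* No ICA / artifact rejection: the pipeline assumes clean or synthetic
  input plus an explicit bad-channel list.
* Whole-session synchrony only; no sliding-window or segmented variants.
* The surrogate test's power depends on signal bandwidth; for
  near-sinusoidal narrowband signals even strong coupling is
  undetectable in principle (see the generator notes above).
* The binary-graph metrics discard synchrony strength above threshold;
  no weighted-graph variants are provided.
* Interpolation is inverse-distance, not spherical splines; fine for
  validation, cruder than MNE's spline interpolation on real data.
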