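# Methods

This note documents the models, estimators and design choices behind
`eegnet`, a pipeline for comparing scalp EEG immediately before and after
epileptic seizures: spectral power, signal complexity, coherence-based
functional networks, weighted graph metrics, and paired statistics, together
with a synthetic-EEG generator that provides planted ground truth for
end-to-end validation.

## Recording regime and preprocessing

The pipeline targets 16-channel scalp EEG (10-20 montage: Fp1/2, F3/4, F7/8,
C3/4, P3/4, O1/2, T3/4, T5/6) sampled at 256 Hz in µV, with 10 min windows
taken immediately before seizure onset and immediately after seizure offset
(`extract_peri_seizure`; a configurable `guard_s` gap defaults to 0; the pre
window is `[onset − w, onset)`, the post window `(offset, offset + w]`, so
epoch counts are unambiguous).

Preprocessing runs in a fixed order, enforced by the chain runner:

1. **Common-average re-reference** — subtract the across-channel mean at
   every sample.  Idempotent; requires ≥ 2 channels.
2. **Band-pass 1–45 Hz** — 4th-order Butterworth applied forward–backward
   (`sosfiltfilt`), i.e. zero phase, so epoch alignment is preserved.  The
   filter realisation is a design choice (standard EEG practice); only the
   passband is dictated by the analysis.
3. **Segmentation into 6 s epochs** — consecutive and non-overlapping; the
   trailing remainder is discarded.  600 s yields exactly 100 epochs of
   1536 samples.
4. **Amplitude-threshold artifact rejection** — an epoch is dropped iff any
   sample on any channel satisfies |x| > 80 µV.  The boundary is strict (a
   sample at exactly 80 µV is retained); both the threshold and inclusivity
   are configurable, and the any-channel rule (rather than per-channel) is a
   documented choice.

## Spectral analysis

PSDs are estimated by Welch's method: 2 s Hann windows with 50% overlap
within each 6 s epoch, averaged over windows and over retained epochs
(density scaling, µV²/Hz; the integral over frequency recovers the signal
variance up to the window-taper correction).  The window choice gives 0.5 Hz
resolution — enough to resolve the delta band — and five averages per epoch.

Band power integrates the PSD by the trapezoid rule over the closed interval
[low, high].  With trapezoid quadrature the closed convention is the one
under which adjacent bands tile the analysis range exactly: the five band
powers sum to the total 1–45 Hz power to machine precision.  Band edges are
the conventional clinical definitions consistent with the 1–45 Hz passband —
delta 1–4, theta 4–8, alpha 8–13, beta 13–30, low gamma 30–45 Hz — and are
configurable.  Channel-wise statistics are computed on log10 band power
(variance stabilisation for paired t-tests); raw power is always exported,
and relative (normalised) band power is available behind a flag.

## Fuzzy entropy

Signal complexity is measured by fuzzy entropy, the sample-entropy variant
with a smooth similarity kernel.  For a series u(1..N) and embedding
dimension m, the N − m templates of length m (and, over the same starting
points, length m + 1) have their own mean removed; template pairs i ≠ j get
membership exp(−(d_ij/r_abs)^n_fuzz) on Chebyshev distances, with
r_abs = r·SD(u); φ^m is the mean membership, and

    FuzzyEn = ln φ^m − ln φ^(m+1)   (nats).

Baseline removal gives exact additive-offset invariance; tying the tolerance
to the signal SD gives exact positive-scale invariance (both are asserted in
tests).  A constant signal returns 0 with a warning rather than raising —
flat channels occur in practice.  Defaults m = 2, r = 0.2, n_fuzz = 2 are
the dominant convention in the EEG fuzzy-entropy literature; all three are
exposed in configuration.  The vectorised implementation is verified against
a literal O(N²) double-loop reference to 1e-12 relative error.

Band-limited entropy filters each epoch to the requested band (zero-phase,
4th order) before the computation; the pipeline default is delta-filtered
entropy with broadband available as an option.  Note that the generator's
complexity handle — the broadband noise-to-oscillation ratio — is nearly
invisible to delta-filtered entropy (white noise puts only ≈ 3/128 of its
power into 1–4 Hz), so the planted-complexity recovery experiments use
broadband entropy.

## Coherence networks

Synchrony between channels x, y is the magnitude-squared coherence

    C(f) = |S_xy(f)|² / (S_xx(f) S_yy(f)) ∈ [0, 1],

with cross- and auto-spectra estimated from the same Hann-windowed segments
as the PSD, pooled across windows and epochs (one network per state per
band).  Band-level connectivity is the mean of C(f) over the bins inside
[low, high) — the variance-minimising aggregation.  Matrices are symmetric
with the diagonal fixed at 0 so graph metrics never traverse self-loops.

With L independent segments the coherence of unrelated signals has
expectation ≈ 1/L; a single segment gives the degenerate estimate C ≡ 1 and
is rejected.  For edge-wise paired statistics, per-epoch matrices (5 windows
each) are computed alongside the pooled network: their small-sample bias is
identical in the two compared states, so paired differences are unbiased
under the null.

## Graph metrics

Edge lengths are reciprocal weights, d = 1/w (the standard convention for
similarity-weighted networks; 1 − w is available behind a flag).
Characteristic path length is the mean all-pairs shortest weighted path
length over ordered pairs; a disconnected graph raises by default, with a
harmonic-mean (global-efficiency) fallback behind a flag.  Full unthresholded
weighted matrices are used; a proportional-threshold utility exists for
sensitivity analysis only.

The weighted clustering coefficient is computed in two variants that differ
in the per-node denominator of the triangle-intensity ratio
T_i = Σ_{j,h} (w_ij w_ih w_jh)^{1/3}:

* **printed** — strength-based, T_i / [s_i (s_i − 1)] with s_i = Σ_j w_ij;
* **standard** — degree-based, T_i / [k_i (k_i − 1)] with k_i the count of
  nonzero edges (the conventional weighted form).

The variants coincide on binary graphs but differ on weighted ones; the
strength form is not invariant to uniform weight rescaling (tested
explicitly) and degenerates when node strengths fall to ≤ 1, in which case
the node's term is zeroed with a warning.  Both are always reported and
neither is silently preferred.  On sparse low-coherence scalp networks the
strength denominator is routinely ≤ 1, so the seizure-trend analysis reports
the standard variant (CPL is unaffected by the choice).

## Statistics

Channel- and edge-wise contrasts use the classical paired t-test on matched
sampling units.  The default pairing unit is the epoch index within a
pre/post pair; subject-level pairing is available for group analyses (the
appropriate unit is a modelling choice the pipeline does not hard-code).
FDR control uses Benjamini–Hochberg step-up adjustment.  Per-analysis
defaults: channel-wise band power at raw p < 0.05; entropy at FDR 0.01;
edges at raw p < 0.05 with FDR-adjusted values always co-reported.  The
seizure-number relation is the Pearson correlation between a network metric
and the rank of the temporally ordered segments 1-pre, 1-post, 2-pre, …
(linear-trend reading; requires ≥ 3 segments and a non-constant series).

## Synthetic EEG generator

Each channel is a sum of five narrowband components — unit-variance filtered
white noise (4th-order Butterworth per band, 2 s warm-up trimmed), scaled to
the configured per-channel band variance — plus broadband sensor noise
(white by default; a 1/f "pink" option exists because real EEG backgrounds
are not white, and is shaped exactly in the Fourier domain).  Default band
variances (delta 20, theta 8, alpha 15, beta 5, low gamma 2 µV²; noise SD
2 µV) mimic a delta-dominant resting scalp spectrum with total SD ≈ 7 µV.

Pairwise synchrony is planted by shared-source mixing: a coupled pair (i, j)
receives a common narrowband source with variance fraction g_ij alongside
each channel's private source.  Because every band source shares one
spectral shape, the magnitude-squared coherence at the band's peak frequency
is g_ij² / [(1 + N_i/(σ_i²P*))(1 + N_j/(σ_j²P*))] in closed form (N = noise
PSD, σ²P* = band-signal PSD at the peak), and g is chosen so that this
equals the configured coupling κ exactly.  Infeasible requests — g ≥ 1, or a
channel whose mixing fractions sum past 1 — raise an error naming the pair
or channel.  This construction was chosen over a VAR simulation precisely
because it gives a closed-form coherence target per pair per band.  Note the
feasibility budget: since g = √κ at low noise, a channel can carry at most a
few strong partners (Σ_j √κ_ij ≤ 1), which rules out dense strongly coupled
graphs; the validation experiments use disjoint pairs or ring topologies
accordingly.

Pre/post contrasts (`PrePostEffect`): a multiplicative post/pre delta-power
ratio per channel; a complexity change implemented as a change in the
broadband noise-to-oscillation ratio (fuzzy entropy of noisier signals is
higher, a monotone handle); additive per-edge coupling shifts in a chosen
band; and a per-seizure trend under which segment k-pre carries shift scale
t·(k−1) and k-post carries t·(k−1) + 1 — damage accumulates monotonically
across consecutive seizures for t ≥ 0, and t = 0 makes the pre/post pairs
exchangeable across seizures.  Artifacts are 0.5 s square pulses or 1 s
ramps of configurable peak amplitude (> 80 µV required) planted into exactly
round(rate·n) randomly chosen 6 s windows, so rejection counts are exactly
verifiable.  Generation is a pure function of (config, seed, state,
seizure index); pre and post windows use independent substreams, as distinct
time windows of a real recording would be.

What the generator does **not** emulate: seizure waveform morphology,
volume conduction / a head model, non-stationarity within windows, and
heavy-tailed artifact families beyond pulses and ramps.  Passing recovery
tests therefore demonstrate that the estimators recover planted linear
band-limited structure through the full chain — not that the pipeline's
clinical conclusions transfer to any particular patient population.

## Validation experiments (problem sizes and rationale)

All experiments run the full preprocessing → feature → statistics path on
generated recordings; sizes were chosen to keep the whole suite within
minutes on one CPU while leaving comfortable statistical margins.

* **Oracle equivalence** — fuzzy entropy vs a double-loop reference (100
  random signals, N ≤ 200, m ∈ {1,2,3}, 1e-12 relative); CPL vs
  Floyd–Warshall and both CC variants vs a triple-loop reference (100 random
  16-node graphs, 1e-12).
* **Coherence calibration** — couplings {0.1, 0.3, 0.5, 0.7, 0.9} planted on
  disjoint pairs, 100 epochs × 20 seeds; recovered band coherence within
  ±0.1 and strictly monotone.  This experiment checks the generator's
  analytic contract against the estimator, so two confounds that are not
  part of that contract are excluded by design: power is restricted to the
  calibrated band (adjacent-band sources leak into shared band-edge bins —
  both neighbouring Butterworth bands sit at −3 dB at their common edge —
  and dilute the band mean by up to ≈ 0.12 at κ = 0.9), and no
  common-average reference is applied (the montage transformation mixes all
  channels and costs a further ≈ 0.03–0.06).  The full default chain is
  exercised qualitatively elsewhere (zero-coupling floor, planted-pair
  recovery, monotonicity).
* **Preprocessing exactness** — 10 planted > 80 µV windows among 100; the
  chain rejects exactly those 10; 600 s → 100 × 1536 samples.  Fixtures use
  200 µV artifacts: the measured survival of a 0.5 s pulse through
  re-referencing plus zero-phase band-passing is ≈ 0.58× peak, so 200 µV
  lands near 116 µV against a ≈ 22 µV filtered background — unambiguous on
  both sides of the threshold.
* **Type-I calibration** — 2000 replicates of the channel-wise log-power
  path under a global null (10 epochs per state); per-channel rejection at
  α = 5% must stay ≤ 7%.
* **Effect recovery** — 2× delta power planted on P3, P4, F7, F8, T5, T6;
  100 epochs, 20 seeds; all six channels detected at FDR 0.05 in ≥ 90% of
  seeds, false positives co-reported.  (Exact-set recovery is not a
  meaningful bar under BH: with six near-zero p-values occupying the lowest
  ranks, a null channel clears the rank-7 step-up threshold in ≈ 20% of
  realisations even under a perfect null.)
* **Edge recovery** — three weakened long-range pairs (κ 0.5 → 0.2) and
  three enhanced local pairs (κ 0.2 → 0.5) in delta; per-epoch coherence,
  paired t at raw p < 0.05; all six recovered with correct signs, and the
  mean false-positive count reported against the 0.05 × 120 budget.  The
  budget bounds the *expectation* (measured null rejection rate 0.0485 per
  edge, so ≈ 5.5 expected on 114 null edges); a 20-seed mean estimates it
  with SE ≈ 0.6, so single-run values can land a fraction of an edge either
  side of the budget.
* **Trend recovery** — a 16-channel ring with κ = 0.2 per delta edge loses
  0.02 per accumulated shift unit across 4 seizures (scales 0,1,1,2,2,3,3,4);
  120 s segments (20 epochs) × 40 seeds.  r(CPL, order) > 0 and
  r(CC, order) < 0 in ≥ 95% of seeds; a fully null series (no planted
  contrast — note that a pre/post alternation without a trend is not
  sign-neutral, because even-order segments sit at higher mean rank) keeps
  |r| < 0.7 in ≥ 90%.
* **Determinism** — one config + seed, two runs, byte-identical CSVs.

## Numerical choices and degenerate inputs

Strict rejection boundary at the threshold; coherence clipped to [0, 1] and
symmetrised against rounding before graph metrics; zero-strength nodes
contribute 0 to clustering; zero-variance paired differences raise (t is
undefined) while identical samples return t = 0, p = 1; constant series
raise in the trend; CSV output uses a fixed float format ("%.12g") so equal
runs are byte-equal.

## Known limitations

Single-band calibration isolates the generator contract — band-edge leakage
and reference-montage effects on coherence are real properties of the
analysis that users of the full chain should expect (documented above, and
visible in the full-chain tests).  The strength-denominator clustering
variant is reported faithfully but is fragile on weak graphs.  Welch
parameters, band edges, entropy parameters and all thresholds are
configurable but the defaults above are the tested configuration.
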