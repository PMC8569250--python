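# Methods

This note documents the models and estimators implemented in `neurocoh`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where the
underlying methodology is genuinely open.

## Preprocessing

The chain runs in a fixed order: resample → band-pass → epoch → ICA →
amplitude rejection → common-average reference.

* **Resampling** uses polyphase rational resampling with the exact ratio
  (2048 → 1000 Hz is 125/256), which applies an anti-alias low-pass and
  cannot drift over long recordings. Output length is ⌈n·up/down⌉.
* **Band-pass** is a 4th-order Butterworth (0.1–40 Hz by default) applied
  forward–backward, i.e. zero-phase with the squared magnitude response.
  The 0.1 Hz high-pass pole is slow (settling over seconds), so spectral
  measurements near recording edges of very short signals carry start-up
  transients; the epoching stage makes this irrelevant for recordings of
  realistic length.
* **Epochs** are consecutive, non-overlapping, 2000 ms, with the trailing
  remainder discarded and no baseline correction.
* **ICA artifact removal** is best-effort and off by default for synthetic
  data. Components are estimated by FastICA with a fixed seed (hence
  deterministic) and flagged automatically: |kurtosis| > 5 (blinks,
  transients) or broadband high-frequency dominance
  (power(20–40 Hz)/power(1–10 Hz) > 2, muscle). The stage skips with a
  warning when data are too short (< 20 × n_channels samples) or the
  decomposition fails; it never raises. This is an automated stand-in for
  interactive component review and is deliberately conservative.
* **Epoch rejection** removes epochs whose peak absolute amplitude is
  *strictly greater* than 100 μV; an epoch at exactly the threshold is
  kept. Rejection and re-referencing are idempotent.
* **Average reference** subtracts the per-sample mean over all stored
  channels. The online reference channel is not reconstructed first: the
  recorded channels as stored are averaged, which is the simplest
  defensible convention when the acquisition reference is not separately
  available.

## Spectral estimation

All spectra use Welch's averaged modified periodogram with 1 s Hann
segments at 50% overlap, pooled across every retained epoch (a 2 s epoch
contributes 3 segments). One-second segments give 1 Hz resolution, which
places the band edges 1, 4, 8, 13, 30 Hz on exact bins. Band edges are
half-open [f_lo, f_hi), so shared edges are counted once.

"Absolute power" is the integral of the one-sided density over the band
(μV²), not the mean density — chosen to match the μV² unit convention.
The density scaling satisfies Parseval (integral over [0, fs/2] ≈ signal
variance), and the implementation agrees with `scipy.signal.welch` to
machine precision on identical segmentation.

## Coherence and the interhemispheric summary

Magnitude-squared coherence uses the same segmentation:
MSC(f) = |S̄_xy|²/(S̄_xx S̄_yy) with segment-averaged spectra. Two
conventions are deliberately configurable because the field uses both:

* **Fisher transform variant** — default `z = atanh(√MSC)`, treating
  √MSC as a correlation magnitude (the standard variance stabilizer for
  coherence); `atanh(MSC)` is available for sensitivity analysis. Values
  at or above 1 − 1e−12 are clipped and the clipping logged.
* **Order of operations** — default is average the coherence spectrum over
  band bins, then transform; per-bin transform before averaging is
  available.

The interhemispheric summary for a band is the arithmetic mean of z over
all left×right sensorimotor cluster pairs (81 entries for the default
9 + 9 clusters); within-hemisphere pairs never contribute.

With L averaged segments the MSC of independent signals has expectation
≈ 1/L; tests use this known small-sample bias as a calibration anchor.

## Networks

Graphs are weighted and undirected on all montage electrodes, with the
Fisher-z coherence matrix as weights. Two open conventions are config
switches with documented defaults:

* **Threshold semantics** — default is *sparsity*: retain the
  ⌈s·N(N−1)/2⌉ strongest edges, s ∈ {0.10, 0.15, …, 0.40}. This
  guarantees equal edge counts across subjects so efficiency differences
  are not driven by edge count. Ties at the cut are broken by node-index
  lexicographic order, making the selection deterministic. An absolute
  weight cut is available.
* **Edge length** — default 1/weight (reciprocal); 1 − weight available.

Global efficiency is E = 1/(N(N−1)) Σ_{i≠j} 1/D(i,j) with 1/∞ := 0 for
disconnected pairs; D comes from Dijkstra on the retained edges. The AUC
over the sparsity grid is trapezoidal on the sorted grid (grid width 0.3).
E is non-decreasing in sparsity, and scaling all weights by c scales E by
c — both asserted as properties in the test suite, alongside exact
agreement with exhaustive path enumeration (≤ 6 nodes) and an independent
Floyd–Warshall oracle.

## Group × Timepoint inference

The model is a linear mixed-effects model: Group, Timepoint and
Group × Timepoint as fixed effects, subject as random effect. For a
complete two-timepoint design this model admits an exact stratum
decomposition, and that is how it is fit:

* change scores d_i = post_i − pre_i carry the Timepoint main effect
  (unweighted mean of group change means) and the interaction (difference
  of group change means), tested against the pooled within-group variance
  of d with n − 2 error degrees of freedom;
* subject means (pre_i + post_i)/2 carry the Group main effect.

This closed form is the GLS solution under compound symmetry and — unlike
an iterative random-intercept fit, which floors the intercept variance at
zero — remains exact when the within-subject correlation is negative. For
30 subjects every F has (1, 28) degrees of freedom, and the interaction F
equals the squared two-sample t on change scores, which the test suite
uses as an independent oracle (together with a statsmodels `MixedLM`
cross-check in the positive-ICC regime).

Post hoc pre-vs-post contrasts within each group use the within-subject
error stratum and a Tukey–Kramer adjustment over the four Group × Timepoint
cell means (studentized-range distribution, k = 4, n − 2 df). Adjusted P
is never below unadjusted P. No correction is applied across bands or
measures; reports should state this. Clinical correlations are Pearson r
with two-sided P; a Kolmogorov–Smirnov normality check (parameters
estimated from the sample) is reported alongside and never gates.

## Stimulation protocol and cohort

The iTBS schedule is generated pulse-by-pulse: bursts of 3 pulses at
50 Hz, bursts at 5 Hz, 2 s trains starting every 10 s. A train is
scheduled only if its full 2 s fits within the session span; with the
default 192 s this yields trains at 0, 10, …, 190 s — 20 trains, 200
bursts, 600 pulses, last pulse at 191.84 s. Totals are counted from the
generated schedule, never from closed-form shortcuts.

Delivered intensity is min(0.7·RMT, 40) %MSO with no rounding — the
no-rounding choice reproduces the packaged cohort's printed group means
(38.7 and 37.1 %MSO) exactly. RMT = 100 %MSO encodes "MEP not elicitable"
and passes through the same rule (delivered 40). Cohort summaries report
the arithmetic mean, sample SD (n − 1) and range.

## Synthetic data

Per band b with coupling κ_b, a shared narrowband source (band-pass
filtered unit-variance Gaussian noise) is mixed into both sensorimotor
clusters as x = √κ·s + √(1−κ)·n_ch, with private noises produced by the
same filter so in-band spectra match exactly; non-cluster channels get
independent narrowband noise. All channels add 1/f background and white
sensor noise. Under matched spectra the in-band MSC between coupled
channels is κ² (attenuated to (κ(1−ρ))² when an independent broadband
background contributes power fraction ρ in-band — `expected_msc`).

Default recording conditions: 64-channel montage, 2048 Hz, 360 s, band
RMS amplitudes delta/theta/alpha/beta = 12/8/10/5 μV, 1/f 4 μV, white
2 μV — eyes-closed resting-EEG scale (total RMS ≈ 19 μV). Cohorts draw a
per-subject baseline κ ~ N(0.45, 0.10) per band (clipped to [0.02, 0.95]),
shared by pre and post; the active group's post recordings add Δκ (default
0.25 in delta and theta, mirroring the qualitative pattern the pipeline is
designed to detect).

What the generator does *not* emulate: volume conduction and realistic
lead fields, non-stationarity, alpha reactivity, artifacts beyond the
blink-like transients used in the ICA test, or lesion asymmetries.
Passing tests therefore demonstrate estimator and inference correctness
under a controlled coupling model, not clinical realism of any particular
effect size.

An important interaction to be aware of: common-average referencing
subtracts a fraction of any source shared across channels, equal to the
fraction of channels carrying it. A shared source on all channels of a
small montage would be cancelled entirely. The reduced validation montage
(below) therefore couples only C3 and C4 out of 12 channels, keeping the
coupled channels a small minority, just as the 18 cluster electrodes are a
minority of the 64-channel cap.

## Reduced validation protocols

Repeated-simulation checks run the full chain at deliberately small
problem sizes, chosen once as this package's validation protocol:

* **Coupling recovery** — 2 coupled channels, 250 Hz, 180 two-second
  epochs (540 Welch segments), no background noise; estimated in-band MSC
  vs κ² for κ ∈ {0.2, 0.4, 0.6, 0.8}, tolerance ±0.05.
* **Type-I error** — 200 null cohorts (Δκ = 0), each 15 + 15 subjects,
  12-channel montage, 250 Hz, 12 s per recording, delta + theta bands;
  the Group × Timepoint rejection rate at α = 0.05 must lie in [0.03,
  0.07]. Type-I error of the interaction test does not depend on recording
  length, so the reduced duration changes nothing about this check.
* **Detection** — 25 cohorts with Δκ = 0.25: the interaction and the
  active within-group contrast must be flagged in the majority of runs,
  the sham contrast in fewer than half (observed: 100% / 100% / 0%).

## Numerical conventions and degenerate inputs

* Coherence with a zero-variance segment set raises; per-bin 0/0 from
  empty bins maps to 0.
* Fisher z clips at 1 − 1e−12 (logged), keeping identical channels finite.
* All-epoch rejection raises with advice rather than returning an empty
  set; boundary amplitudes are kept.
* All randomness flows from explicit integer seeds (`numpy` Generators);
  per-recording seeds are derived from the cohort seed, so cohorts are
  byte-identical across runs and insensitive to iteration order.
* Matrix I/O stores μV; EDF physical units are converted on load; channel
  labels compare case-insensitively.

## Known limitations

* The ICA heuristics are coarse; real clinical pipelines should review
  components or use a trained classifier.
* The closed-form mixed model targets the two-timepoint complete-pairs
  design; unbalanced group sizes are handled, but missing timepoints are
  an error by design rather than being imputed.
* Tukey–Kramer over the 2×2 cell means treats the four means as a family
  with a common error term; with strongly unequal variances across strata
  this is an approximation (as it is in the standard software it mirrors).
* Absolute-threshold graphs can disconnect; efficiency handles this
  (unreachable pairs contribute zero), but comparisons across subjects
  are then confounded by edge count — the sparsity default avoids this.
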