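# Methods

This note documents the models behind `neurosync`, the parameters that
matter, what the simulators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## 1. Clock and transport model

Each simulated device stamps sample *k* (reference time `t = k / rate`)
with

```
raw_t = t · (1 + drift) + offset₀ + jitter,   jitter ~ N(0, jitter_sd²)
```

* `offset₀` (s): boot-time clock offset; defaults in the benchmarks span
  ±20 ms.
* `drift` (dimensionless): clock-rate error; physical crystals sit within
  ±100 ppm; the model rejects |drift| ≥ 1000 ppm.
* `jitter_sd` (s): per-sample timestamp noise; 0.1–1 ms is typical of
  software timestamping.

Independently, the stream *content* is delayed by a transport latency
drawn once per session from `N(latency_mean, latency_sd)` truncated at 0 —
the wireless-handshake delay that clock synchronization cannot observe.
The benchmark defaults use latency means 2/22/40/33 ms with 0.5–4 ms
across-startup spread, the regime of an embedded hub plus BLE/WiFi nodes.

Clock-offset measurements (the out-of-band synchronization channel) are
logged every 5 s with `N(0, 0.2 ms)` measurement noise.  The cadence of
real middleware is configurable and not standardized; 5 s exercises drift
fitting without making it trivial, and both numbers are parameters of
`sample_stream`, not claims.

**Clock correction** is a Theil–Sen line (median of pairwise slopes)
through the offset history.  A plain least-squares line would satisfy the
recovery targets on clean histories, but startup handshake transients can
leave gross outliers in early measurements; Theil–Sen tolerates ~29%
contamination with near-least-squares efficiency on Gaussian noise.  With
120 measurements over 10 minutes and 0.5 ms noise, intercept and slope are
recovered within 0.5 ms / 5 ppm in ≥95% of runs (tested).  Remapping is
`shared_t = raw_t − (intercept + slope · raw_t)`; evaluating the fitted
offset at `raw_t` rather than the unknown reference time introduces an
O(drift²·t + drift·offset₀) error, below 20 µs over 10 minutes at 100 ppm
— negligible against the millisecond targets.  `ClockCorrection.inverse()`
gives the exact algebraic inverse of the affine map (simply negating the
coefficients would leave an O(slope²·t) error).

**Dejittering** splits the timeline where a gap exceeds
`max(2 / rate, 10 ms)` (a dropout) and replaces each segment's timestamps
with their least-squares line in sample index — the maximum-likelihood
equispaced grid under Gaussian timestamp noise.  The 10 ms floor mirrors
common recorder-loader behavior and keeps high-rate streams from
fragmenting on single late packets.

## 2. Perturbation calibration

All devices ride one rigid structure, so a mechanical perturbation is a
shared physical event.  The pipeline is:

1. **Magnitude**: per-sample Euclidean norm of the 3-axis accelerometer,
   mean-removed — rotation-invariant, so mounting orientation is
   irrelevant.
2. **Resampling**: linear interpolation of every magnitude trace onto a
   shared 1 kHz grid spanning the intersection of supports.  Linear
   interpolation matches the simulator's own sampling interpolation and
   keeps closed-form oracles valid; lost-sample regions are marked invalid
   and zeroed out of correlation sums rather than interpolated (no
   fabricated signal).
3. **Chunk detection**: 100 ms moving RMS thresholded at
   `median + 10·MAD`; windows closer than 200 ms are merged, shorter than
   100 ms dropped.  At 10 MAD a Gaussian-noise trace crosses the threshold
   with probability far below 1% per 10 s trace (tested over 100 seeds),
   while strokes 5× above baseline noise exceed it by orders of magnitude.
4. **Lag estimation**: per chunk, normalized cross-correlation between the
   reference segment and the other trace over integer-sample shifts in
   ±500 ms, i.e. 1 ms resolution at the 1 kHz grid.  No sub-sample
   interpolation is attempted: reported offsets are integer ms by design,
   matching the resolution at which such latencies are meaningful.  The
   ±500 ms window generously covers wireless latencies (tens of ms).
   Chunks shorter than twice the maximum lag are skipped with a warning
   (their correlation support would be dominated by the search window).
   Sign convention: positive lag means the other stream's content trails
   the reference.  Per-chunk lags are combined by mean (median available),
   and the argmax provably equals a brute-force integer-shift scan (tested
   against one).
5. **Offset matrix**: per-session pairwise lag matrices averaged across
   cold restarts (mean, sample sd); the mean matrix is antisymmetrized as
   `(M − Mᵀ)/2`; sample equivalents are `round(mean_ms · rate_receiver /
   1000)`.  Compensation shifts each stream's shared timestamps by
   `−offset(ref, device)`.

Because transport latencies are redrawn at every startup, compensation is
meaningful only with a same-session calibration; the benchmark therefore
scores post-compensation residuals against the session's own matrix while
reporting the cross-startup mean ± sd as the summary table.  Expected
accuracy, verified end-to-end: every recovered pairwise offset within
±2 ms of truth, residuals ≤ 1 ms, transitivity within 3 ms, and a 25 Hz
stream recovered within half its 40 ms sampling interval.

## 3. Synthetic EEG

Recordings are 7 channels (Fpz, Fz, Cz, Pz, Oz, C3, C4) at 500 Hz, in µV,
starting with a 60 s free-blinking baseline used by blink identification.

**Background** is 80% 1/f ("pink", spectral power slope −1) plus 20% white
noise, scaled to `background_noise_uv` (default 4 µV rms) times the device
profile's noise multiplier (`lab_grade` 1.0 without packet loss,
`wearable_dry` 2.0 with loss — the dry-electrode wireless regime).  A 1/f
floor is essential for dB-based rules and ERSP baselines to behave as they
do on real EEG.

**Task signatures** (all amplitudes defaults of `EffectSpec`, chosen as
realistic scalp values):

* *eyes*: 10 Hz alpha at Oz (0.6× at Pz), 1.5 µV eyes-open vs 5 µV
  eyes-closed, 10 repetitions of 5 s open / 5 s closed;
* *motor*: an 11 + 19 Hz sensorimotor rhythm (4 µV) at C3/C4/Cz whose
  power drops by `erd_fraction` (0.5) during the 4 s movement windows,
  25 trials, rests uniform on 8–12 s;
* *ssvep*: 3 µV occipital oscillation at **twice** the 5/6 Hz checkerboard
  modulation (pattern-reversal doubling), three 10 s runs per frequency
  with 7 s rests;
* *oddball*: 5 runs of 10–12 targets with 6× as many non-targets
  (sequence order uniform under the no-consecutive-targets constraint),
  200 ms stimulus + 400 ms ISI; targets add a Gaussian bump at Cz (0.8× at
  Pz), 6 µV, centered at 320 ms (±10 ms trial jitter), sd 60 ms.  The
  printed protocol pairing (10→60, 12→72 non-targets) fixes the non-target
  rule at 6 × targets; the nominal "1/5" ratio is inconsistent with that
  pairing and is available only as an explicit override.

All narrow-band oscillations carry random phase and slow amplitude
modulation so spectral features are not line spectra.

**Artifacts** are injected with an exact log (the rejection ground truth):
stereotyped 300 ms biphasic blinks with a front-to-back scalp gradient
(maximal at Fpz, default 120 µV at 0.25 Hz), geometric-run packet loss
(zero-order-hold values, mask marked), 4 Hz amplitude bursts above the
rejection bound, and linear drift ramps.  Bursts and ramps use per-channel
gain gradients so they survive common-average referencing instead of being
cancelled as pure common-mode signals.

Not emulated: volume conduction and realistic topographies beyond the
channel assignments, non-stationary background (drowsiness), muscle/EMG
artifacts, line noise, electrode-gel drift dynamics, and high-density
montages.  Passing tests therefore demonstrate pipeline correctness —
rules firing on what they should, statistics holding their error rates —
not that real recordings of a given device would yield the same n80
values.

## 4. Analysis pipeline

* **Preprocess**: common-average reference, then zero-phase Butterworth
  band-pass 1–30 Hz (validation) or no re-reference and 0.1–30 Hz (BCI
  preset).  Order 5 per edge: the forward-backward pass then attenuates
  50 Hz by ≳44 dB for the 1–30 Hz band (order 4 falls just short of 40 dB)
  while passband ripple stays below 5% at 10 Hz; zero-phase filtering
  preserves ERP latencies.
* **Blink SSP**: blinks detected on Fpz smoothed over 100 ms, robust
  |z| > 3 sustained for ≥150 ms (brief noise excursions cross 3 z but do
  not persist); ±200 ms windows are concatenated and the first left
  singular vector — the blink topography — projected out of the whole
  recording.  One component is removed; more would start eating occipital
  alpha (the Oz alpha-preservation test bounds leakage at 10%).
* **Epochs**: eyes [0.5, 5] s (response-time guard); motor [0, 4] s of
  movement and [2, 6] s of rest; SSVEP three 50%-overlapping 5 s epochs
  per 10 s trial; oddball [−0.2, 0.7] s baseline-corrected on [−0.2, 0] s;
  BCI [0, 0.7] s baseline-corrected on the first 100 ms.  ERSP callers
  pass a wider window (e.g. (−6, 4) s) so the pre-event baseline fits.
* **Rejection**, in order, first hit recorded: (1) strictly more than 20
  consecutive lost samples; (2) any sample outside ±50 µV (±100 µV BCI);
  (3) mean multitaper PSD over 20–30 Hz above 60 dB re 1 µV²/Hz on any
  channel (the dB reference is not standardized; 1 µV²/Hz is the
  conventional EEG choice, and the band mean is robust to single-bin
  spikes); (4) any channel with amplitude-vs-time r² > 0.85 (constant
  channels define r² = 0 to avoid 0/0).  The BCI preset applies rules 1–2
  only.  The manual-review step of a semi-automatic procedure is replaced
  by the returned flagged-epoch list (a dry-run report); no interactive UI
  is in scope.
* **PSD**: multitaper with 2 Hz half-bandwidth, non-adaptive weights, over
  1–30 Hz; Welch with Hann window, 2000-sample segments, 1000-sample
  overlap, 5000-point FFT (0.1 Hz grid at 500 Hz — one full segment per
  5 s epoch).  Units µV²/Hz; dB = 10·log₁₀(PSD / 1 µV²/Hz).
* **ERSP**: Morlet wavelets at 1..30 Hz with cycle counts 1..30 matched
  index-wise; trial-averaged power converted to dB against the mean
  pre-event baseline per channel and frequency.  Multiplicative power
  changes reproduce closed-form dB (±0.5 dB tested; halving power reads
  −3 dB).
* **Statistics**: Bonferroni route = independent two-sample t per bin at
  α/m.  Cluster route = dependent-sample t on paired differences,
  two-sided threshold at the α t-quantile, cluster mass = sum of t within
  contiguous supra-threshold runs, null = max |mass| over sign-flip
  permutations (exhaustive when 2ⁿ ≤ n_perm, else sampled), corrected
  p = proportion of null maxima ≥ observed.  Verified against an
  exhaustive 2⁸ enumeration oracle and calibrated to a 3.4% empirical
  type-I rate at nominal 5% over 500 null datasets.
* **Power curves**: the per-trial scalar feature (peak band PSD or peak
  ERP amplitude) is computed once per trial; for each n, 1000 (default)
  subsamples of n trials per condition are drawn *without replacement*
  ("randomly selected permutations" of a finite trial pool) and compared
  with a pooled two-sided t-test; the curve is the significant fraction
  and n80 its first crossing of 0.8.  Note that as n approaches the
  available trial count the draws overlap heavily and at n = N become
  deterministic; grids should stay below the pool size.

## 5. Problem sizes and determinism

Benchmarks are sized for a single CPU: four 30 s sessions for the
synchronization study, single sessions per task × profile for the EEG grid
(≈160–420 s of 500 Hz signal each), 200–300 subsampling draws per grid
point in test runs (1000 for final curves), and 500 null datasets × 200
permutations for the type-I calibration.  Every source of randomness
derives from one seed through `numpy.random.SeedSequence` spawning, so any
report is byte-reproducible given its seed.

## 6. Known limitations

* Transport latency is constant within a session; time-varying latency
  (e.g. adaptive radio backoff) is out of scope, as is online streaming.
* The offset matrix assumes all pairwise estimates share one timeline;
  with many devices, a reference-based spanning estimate would propagate
  less error than averaging all pairs.
* The cluster test pairs trials by index after truncating to the shorter
  condition; unequal designs lose the surplus trials.
* The power analysis treats the trial pool as exchangeable; serial
  dependence (fatigue, habituation) in real sessions would inflate its
  optimism.
* Single-component SSP can leave residual blink energy when blink
  topography varies; real pipelines sometimes remove 2–3 components at
  the cost of neural signal.
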