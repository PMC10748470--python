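# Methods

This note documents the models behind `chirpclock`, the defaults and why
they were chosen, and what the synthetic data do and do not establish.

## Zeitgeber time and photoschedules

All phases are expressed in Zeitgeber time (ZT): hours since lights-on,
so ZT0–ZT12 is the (subjective) light phase under a 12:12 cycle and
ZT12–ZT24 the dark phase. Three regimes are modeled: standard 12:12
light:dark (LD), the reversed cycle (DL), and constant darkness (DD). A
programmed LD→DL reversal happens at ZT0 of a chosen day: the light that
would have come on stays off, lights-on moves 12 h, and ZT is thereafter
referenced to the *new* lights-on (so the reversed dark phase again spans
ZT12–ZT24). Under DD, "subjective" light/dark phases are carried over from
the schedule the animal was entrained to before release into darkness.
When a recording spans the reversal instant, each minute is assigned the
regime active at that minute.

## The singing-schedule simulator

One individual's singing is a per-minute Bernoulli process driven by a
circadian oscillator:

- A circular singing window `[onset_zt, offset_zt)` on the 24-h ZT scale.
  Inside it a minute contains song with probability `p_sing`; outside,
  with probability `p_noise_sing` (sporadic daytime chirps). The window
  can be a flat boxcar (default) or a raised-cosine bump peaking at the
  window center; the true nightly activity shape is not known, so both are
  exposed rather than asserting one.
- Under LD/DL the oscillator is entrained: circadian phase equals ZT.
- Under DD the phase advances 24 h per `period_h` wall hours, so the
  window drifts by `period_h − 24` h per cycle — a continuous drift, which
  makes the series' true spectral period exactly `period_h` and
  reproduces the characteristic daily onset delay when the free-running
  period exceeds 24 h.
- After an LD→DL reversal the window starts 12 h early in the new ZT frame
  (its old wall-clock position) and delays linearly day by day over
  `transient_days` (default 4, matching the 4 post-reversal days the
  analysis discards as transient cycles; the true transient shape is
  unspecified, so the simplest monotone path is used).

Defaults are the observed study conditions: window ZT 13.06 → 23.91,
`p_sing = 0.75` (chosen so the expected dark-phase singing fraction is
0.75 × 10.85 h / 12 h ≈ 0.68), `p_noise_sing = 0.01`, free-running
τ = 25.1 h, entrained τ = 24 h. With these, expected singing effort is
≈ 8.1 h/day.

Three protocol factories emulate the experiments: (1) DL at 25 °C, n = 4,
8 days; (2) DD at 22/25/28 °C, n = 5/4/5, 8 days, per-individual
τ ~ N(25.1, 0.25) truncated to [24.2, 26.0]; (3) LD for 9 days then DL for
8 more with reversal at day-9 ZT0, n = 8/6/8. Per-individual window bounds
are drawn around the defaults (SD 0.8 h) and `p_sing` around 0.75
(SD 0.10), giving realistic between-individual variation in phase and
effort. The experiment-3 factory places the post-reversal window ~1 h
(onset) and ~2 h (offset) earlier in the new frame, emulating the phase
advance observed after reversal. All randomness descends from one integer
seed through `numpy.random.SeedSequence`; outputs, including CSV files,
are byte-identical across runs with the same seed.

## Audio synthesis

Song bouts are a long chirp (0.45 s) followed by four short chirps
(0.15 s) with 0.12-s gaps, a sinusoidal carrier at the dominant frequency
(default 4.5 kHz; valid range 3–6 kHz), raised-cosine chirp edges and a
25-Hz syllable-like amplitude modulation. Background is white Gaussian
noise (RMS 0.03) plus a 50-Hz hum, standing in for incubator fans and
electromagnetic pickup; no measured noise spectrum exists, so the simplest
two-component model is used. `snr_db` sets the chirp carrier RMS relative
to the broadband-noise RMS. A singing minute contains at least one bout
(count ~ Poisson, mean 6/min) at random offsets. A master `amplitude` gain
scales the finished clip, so clip RMS is exactly linear in it; defaults
leave ample headroom below full scale, and output is hard-limited to
[−1, 1]. Full-experiment audio (≈30 GB per cricket at 44.1 kHz) is out of
desk scale by design: audio mode emits a bounded, label-balanced clip
sample per individual, and series-only mode is the default for circadian
work.

## Features and classification

Each 60-s clip is summarized by Welch spectra (Hann window, 4096-sample
frames, 50% overlap — standard bioacoustic practice) restricted to the
3–6 kHz song band. The default 5-feature catalogue: band dominant
frequency, band-to-total energy ratio, normalized band spectral entropy,
band magnitude SD, and temporal-envelope crest factor. A 20-descriptor
catalogue (distribution statistics of band magnitudes, flatness, centroid,
bandwidth, rolloff, envelope statistics, zero-crossing rate, envelope peak
count, broadband RMS) supports replaying the iterative paring workflow by
permutation importance. Silent clips use fixed conventions (entropy and
flatness 1, dominant frequency NaN-flagged) rather than raising. Note one
windowing consequence: a pure tone's normalized band entropy bottoms out
near 0.15, not 0, because the Hann main lobe occupies three bins; the
tone/noise contrast (≈0.15 vs > 0.95) is unaffected.

The classifier is a 500-tree random forest (CART and k-NN available via
the learner switch for comparison). Class imbalance is handled by
stratification only; exact 50:50 ensemble votes are scored as singing
(favoring sensitivity, since a missed song biases rhythm amplitude down).
Evaluation: stratified 75/25 train/validation split and stratified 10-fold
CV pooling out-of-fold predictions into one confusion matrix; accuracy
with a Clopper–Pearson exact binomial CI; Cohen's κ.

## Rhythm series

Clip predictions map 1:1 onto minutes. Exclusions are masks over an intact
minute grid — recording gaps, the first 72 h (acclimation), and 4 days
after a reversal (transients) — which preserves ZT alignment and lets
gap-affected individuals stay in the dataset. Singing effort is total
unmasked singing minutes / (60 × days with data), so effort × days × 60
conserves the minute count exactly. Dark/light singing fractions count
minutes at value ≥ 1 (binary individual series; fractions of group
averages are deliberately not computed, since no threshold for averaged
values is defined). Group averages are per-minute means over members with
data at that minute. Actograms are double-plotted (row *d* shows days *d*
and *d + 1*; the duplicated half is an exact copy) and polar profiles wrap
mean singing into 48 30-min ZT bins.

## Periods

The classic normalized Lomb–Scargle periodogram is computed directly on
the unmasked minutes (irregular sampling is the point: masked spans simply
drop out). Data are centered and power is normalized by the sample
variance, so under white noise each power is ~Exp(1) and the rhythmicity
cutoff at level α with M independent frequencies is
`z* = −ln(1 − (1 − α)^(1/M))`; M is estimated as the number of independent
Fourier frequencies in the tested band, `span × (1/p_min − 1/p_max)`. The
period grid is uniform in period, 18–30 h in 0.02-h steps — chosen instead
of a frequency-space oversampling factor so the grid error is bounded
(0.01 h) everywhere in the band, covering published cricket estimates
(24.4–25.2 h) with margin. A constant series gets zero power and is
reported non-rhythmic rather than raising. Equality with a brute-force
per-frequency least-squares sinusoid fit (residual-reduction form) is
enforced in tests to 1e-8, with an additional cross-check against scipy's
unnormalized implementation.

One caveat surfaced by simulation: estimating an "entrained period" on a
concatenated LD + DL series that contains a 12-h phase step biases the
estimate above 24 h (the step masquerades as a slow drift). The pipeline
reports the concatenated estimate for that protocol as-is; per-segment
estimation is available by slicing the series.

## Phase markers

Per ZT day, activity is binned (default 30 min) and circularly smoothed by
a centered moving average (default 3 bins; binning and smoothing defaults
follow common actimetry practice since the reference tooling does not
publish its internals — they are validated by recovery of simulated truth,
not by concordance with any one program). The day's *peak* is the profile
maximum; *onset* is the last upward crossing of 20% of the peak before it
(circular search up to 24 h back — last, not first, so sporadic pre-onset
chirps cannot drag onset early); *offset* is the first downward crossing
after it; both are linearly interpolated between bins. Days with
incomplete bin coverage or a peak below `min_peak` get missing markers,
never fabricated ones. Bin values are positioned at bin centers by
default (unbiased for binned averages of a continuous profile; a
left-edge mode exists for series that already hold profile samples).
On Bernoulli data the 3-bin smoothing ramp biases boxcar-edge crossings
~25 min early/late, so for sharp-edged activity the no-smoothing setting
recovers simulated windows within ±30 min at `p_sing = 0.8`; smoothing
remains the default for real, ragged profiles.

## Circular statistics and shifts

Marker hours map to angles (24 h = 2π). Reported are the circular mean,
mean resultant length R̄ and angular variance `V_m = 1 − R̄` (0 =
perfectly concentrated, 1 = uniform). A phase shift between regimes is the
shortest-arc difference of circular means, each in its own regime's ZT
frame, positive = advance; its significance comes from a permutation test
shuffling regime labels over day-level markers (default 10,000
permutations, seeded). Group equality of periods (temperature
compensation) is likewise tested by permutation — statistic: weighted
between-group sum of squares of mean periods — keeping the package free of
distributional assumptions for these small groups.

## What the synthetic data do not show

The simulator emulates schedule structure, not cricket acoustics in full:
song variation between individuals (pitch, amplitude, bout sparsity),
colored or nonstationary incubator noise, recorder clock drift, and
temperature-dependent chirp rate are absent, and real transient
re-entrainment is unlikely to be linear. Classifier scores on synthesized
clips therefore demonstrate that the feature/learner machinery works at a
given SNR, not field-recording performance; period/marker recovery shows
the estimators are correct for the generating model, not that real singing
follows it. Bayesian circular regression and periodogram variants other
than Lomb–Scargle are intentionally out of scope.

## Problem sizes

Test and benchmark runs use desk-scale sizes: 8–17 day series at minute
resolution, 10-seed period-recovery replicates, 200-clip classifier
corpora, and 500–2,000-permutation tests (10,000 only where the default is
exercised); these sizes give stable estimates while keeping the whole
suite runnable in minutes.
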