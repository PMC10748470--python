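# chirpclock

Audio-to-circadian analysis of cricket calling song.

Male Pacific field crickets (*Teleogryllus oceanicus*) sing at night to
attract mates, and the timing of that song matters: it is shaped by sexual
selection and, in Hawaiian populations, by an acoustically orienting
parasitoid fly. Testing whether singing is scheduled by an endogenous
circadian clock requires scoring song presence around the clock for many
days per individual — far more audio than anyone can scan by ear.

`chirpclock` is a pipeline for exactly that workflow, aimed at behavioral
ecologists and chronobiologists working with continuous bioacoustic
recordings:

1. **Detect singing.** Each consecutive 60-s WAV clip is summarized by
   descriptors of the 3–6 kHz band (the species' song band: dominant
   frequency, band-to-total energy ratio, normalized spectral entropy, band
   magnitude SD, envelope crest factor; a 20-descriptor catalogue with
   permutation-importance paring is also provided) and classified
   singing/background by a random forest, evaluated with a stratified 75/25
   split and 10-fold cross-validation (accuracy with exact binomial CI,
   Cohen's κ).
2. **Build rhythm series.** Clip scores map 1:1 onto minutes, anchored to
   clock time and Zeitgeber time (ZT; hours since lights-on). Gaps and
   standard trims (first 72 h acclimation, 4 transient days after a
   photoperiod reversal) are masked, never deleted. Singing effort,
   dark/light-phase singing fractions, group averages, double-plotted
   actograms and wrapped polar profiles come from these series.
3. **Quantify circadian properties.** Periods via the classic normalized
   Lomb–Scargle periodogram on the (irregularly sampled) masked minutes,
   with the exponential-null significance cutoff
   `z* = −ln(1 − (1 − α)^(1/M))`; daily phase markers by the standard
   20%-of-peak rule (onset/peak/offset); circular means, angular variance
   `V_m = 1 − R̄`, and signed phase shifts between light regimes with
   permutation tests.
4. **Simulate everything.** A synthetic-song module generates per-minute
   ground truth from a parametric circadian oscillator (entrained windows,
   free-running drift at τ − 24 h/cycle under constant darkness,
   transient re-entrainment after an LD→DL reversal), synthesizes
   *T. oceanicus*-like clips (4–5 kHz carrier, long chirp + short-chirp
   train) over incubator-like noise, and emulates three full experimental
   protocols — so every stage is testable against known parameters without
   terabytes of study audio.

## Worked example

Simulate a free-running (constant darkness) recording and estimate its
period, then an entrained (reversed photoperiod) recording and its onset
phase:

```python
from datetime import datetime
from chirpclock import Photoschedule, SongScheduleParams, simulate_series
from chirpclock import lomb_scargle, phase_markers, summarize_phases

dd = Photoschedule("DD", lights_on=6.0, start=datetime(2022, 6, 1, 6, 0))
free = simulate_series(
    SongScheduleParams(period_h=25.1, onset_zt=13.0, offset_zt=24.0,
                       p_sing=0.8, p_noise_sing=0.01, seed=12),
    dd, days=8)
pg = lomb_scargle(free)                         # periods 18-30 h, alpha=0.05
print(f"free-running period {pg.best_period:.2f} h, rhythmic: {pg.is_rhythmic}")

dl = Photoschedule("DL", lights_on=18.0, start=datetime(2022, 6, 1, 18, 0))
entrained = simulate_series(
    SongScheduleParams(onset_zt=13.06, offset_zt=23.91,
                       p_sing=0.75, p_noise_sing=0.01, seed=12),
    dl, days=8)
pm = phase_markers(entrained, smooth_window_bins=1)
onset = summarize_phases(pm.defined("onset"))
print(f"entrained onset ZT {onset.mean_h:.2f} (V_m = {onset.V_m:.3f}, n = {onset.n})")
```

Output:

```
free-running period 25.12 h, rhythmic: True
entrained onset ZT 12.88 (V_m = 0.000, n = 8)
```

The periodogram peaks at the simulated free-running period (25.1 h) and is
significant at α = 0.05. Under the entrained schedule the daily
20%-of-peak onsets sit at the simulated window onset (ZT 13, an hour into
the dark phase) with near-zero angular variance — a tightly phased
nocturnal rhythm. Under constant darkness the onset would instead drift
about 1.1 h later each day, exactly because the free-running period
exceeds 24 h.

The same analyses run from the shell:

```bash
chirpclock simulate --experiment 2 --out sim/ --seed 1
chirpclock analyze --series sim/truth.csv --regime DD --lights-on 6 --out-dir analysis/
```

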