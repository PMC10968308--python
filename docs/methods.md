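# Methods

## Problem and model

`ecgqc` grades the *readability* of a single differential ECG lead from a
wearable recorder, not its clinical content. A trace is acceptable when
its primary waves (P, QRS, T) are identifiable; it is unacceptable when
artifacts — electrode movement or loss of adhesion, muscle activity, a
detached lead — make the QRS complex unrecognizable. The working
assumption is that a readable ECG has limited isoelectric-line
variability, a limited max−min range, and a limited standard deviation,
while the dominant wearable artifacts violate at least one of these;
classification therefore needs only window statistics that are trivially
computable in a streaming device.

Amplitudes are physical millivolts throughout. The device profile
(default ±500 mV input range, 18-bit ADC) contributes one number to the
algorithm: the full span `range = adc_max − adc_min = 1000 mV`, the anchor
of the saturation rule. The stated range is "±500 mV", which could be
read either as a 500 mV or a 1000 mV reference; we use the full span
because the rule compares it against a peak-to-peak quantity
(`max_w − min_w`). The ADC bit depth is metadata only — values are not
quantized. The same full-span reading is applied to the "70 % of the
maximal acquisition range" bound in the template search. Both are
configurable.

## Reference template

The template is the statistics triple (`max_t`, `min_t`, `SD_t`) of the
first *stable* 10 s span, scanned in 1 s steps from t = 0. Stability is
two conditions:

* peak-to-peak amplitude strictly below
  `template_variability_fraction × full span` (default 0.70 × 1000 mV);
* a constant isoelectric line, operationalized as: the spread
  (max − min) of the ten per-1 s sub-window means is at most
  `baseline_drift_fraction` (default 0.10) of the span's own peak-to-peak
  amplitude. "Constant isoelectric line" is not otherwise quantified;
  tying the tolerance to the span's own amplitude makes the criterion
  scale-free.

Dead-flat candidate spans (zero peak-to-peak) are rejected: they carry no
amplitude reference and would produce a degenerate `SD_t = 0` against
which the relative rules are meaningless. If no span in the whole
recording qualifies, `NoStableReferenceError` is raised and the caller may
supply a preset template (from device characteristics, or manually chosen
bounds) — the CLI exposes this as `--preset-template MAX,MIN,SD`.

The scan granularity (1 s) is a design choice; the method is defined only
up to "first stable period", and any granularity between one sample and
one window is defensible. Windows that overlap the template span are
classified like any others.

## Window rules

Windows are consecutive, non-overlapping, 2 s long (long enough to
contain at least one beat at any plausible heart rate ≥ 30 bpm), and a
trailing partial window is discarded with a log entry. Statistics use
the population (n) denominator for the SD; at 500 samples per window the
n vs n−1 difference is far below every threshold's margin, and fixing one
choice keeps batch, streaming and re-implementations bit-comparable.

The three rules run in the fixed order **saturation → low_amplitude →
excess_sd**, short-circuiting at the first hit, and all comparisons are
strict (`>`, `<`); a window whose statistic sits exactly on a threshold is
therefore *not* rejected by that rule. The reported `reason` is the first
rule fired, so a rail-to-rail window reports `saturation` even though its
SD is also enormous. The mean is computed and reported per window but
used by no rule.

Consequences worth noting, all covered by property tests:

* adding a constant offset to a window changes neither its range nor its
  SD — baseline drift alone never rejects;
* scaling window *and* template by the same positive factor leaves the
  two relative rules unchanged; the saturation rule is ADC-anchored and
  exempt;
* increasing zero-mean noise on a fixed window eventually and permanently
  trips `excess_sd` or `saturation`.

## Aggregation and annotation comparison

Ten-second samples take the label of whichever class covers at least half
the sample. With the default 5 windows per sample a tie is impossible;
where ties can occur (even window counts, or interval annotations split
exactly 5 s/5 s) they resolve to *unacceptable* — the conservative choice
for a quality gate. Interval annotations (an expert's start/end markers)
are rasterized by the same prevalence rule; time not covered by any
interval counts as unacceptable and is logged.

## Streaming

`StreamingClassifier` consumes one sample per `push()` and emits a verdict
every `window_len × fs` pushes — classification delayed by exactly one
window. Internally it fills a fixed window-size buffer and hands it to
the same statistics routine as the batch path. Running
max/min/sum/sum-of-squares accumulators would be mathematically
equivalent and O(1) per sample, but a sum-of-squares SD is not bit-equal
to numpy's pairwise-summed two-pass SD; the buffer (identical memory
footprint) makes stream and batch verdicts *exactly* equal, which the
equivalence suite asserts on 100+ randomized recordings.

## Synthetic data

The generator exists because the validation recordings are clinical data
and not redistributable; it emulates their artifact morphologies well
enough to exercise every code path with known ground truth.

A clean beat is a sum of five Gaussians (P, Q, R, S, T) placed at fixed
fractions of the RR interval around the R peak; defaults R = 1.0 mV,
P = 0.15 mV, T = 0.3 mV, Q = S = −0.1 mV are typical single-lead surface
values. Heart rate defaults to 70 bpm with 3 % RR jitter (cohort
recordings draw 55–85 bpm). Artifact episodes are scheduled intervals:

| kind | transform | default magnitude |
|---|---|---|
| `baseline_wander` | add ≤0.5 Hz sinusoid | 0.15 mV, 0.25 Hz |
| `powerline` | add 50 Hz sinusoid | 0.10 mV |
| `muscle` | add high-passed (≥20 Hz) white noise | SD 0.5 mV |
| `saturation` | replace with 1 Hz, 600 mV oscillation, clipped at rails | — |
| `flatline` | scale trace to a residual fraction | 0.02 |

All randomness is a pure function of the recipe seed (muscle noise is
additionally keyed by episode index). Magnitudes are our choices — the
source figures are qualitative — picked so each corrupting artifact
violates its corresponding rule unambiguously at default settings:
saturation exceeds 95 % of the span in every fully covered window,
flatline falls below the 5 % floor, muscle at SD 0.5 mV lifts the window
SD to ~0.52 mV against a clean-template `2×SD_t` threshold of ~0.3 mV.

**Ground truth** is defined from the schedule, not from the waveform: a
2 s window is truth-unacceptable iff corrupting episodes (saturation,
flatline, muscle with episode SD ≥ the clean signal's SD) cover at least
half of it; 10 s truth labels follow the same prevalence rule as the
classifier. Baseline wander is always truth-acceptable (it is readable,
and tolerating it is a design goal). Powerline is truth-acceptable by
default; the `strict_powerline` flag scores it unacceptable instead —
the convention of a human reader — which turns the classifier's known
blind spot for mains interference into a measurable sensitivity deficit.
The 50 %-coverage and muscle-SD thresholds are our operationalization of
"readable by a cardiologist" and are deliberately coarse; they are not
fitted to anything.

**Cohort generator.** Each recording opens with a 20 s clean lead-in (so
the template search always succeeds at t ≈ 0), then every later 10 s
sample is independently replaced by a full-sample corrupting episode
(saturation/flatline/muscle, equal odds) with probability rescaled so the
expected pooled truth-unacceptable fraction equals the target (default
0.46); clean samples occasionally receive benign wander (10 %) or
low-amplitude powerline (5 %) episodes. Episodes are aligned to sample
boundaries, which together with the unambiguous magnitudes is why the
classifier recovers the truth near-perfectly on this cohort — the
synthetic study validates the machinery (template search, rules,
aggregation, metrics), not the difficulty of real clinical data.

### What the generator does not emulate

Real recordings contain gradual artifact onsets, mixed and partially
overlapping noise, borderline amplitudes near the rule thresholds,
arrhythmias, and annotator behaviour (beat-resolution markers that
disagree with fixed 2 s windows near episode edges). Passing the
synthetic cohort therefore demonstrates correctness of the implementation
under separable conditions, not the error rate to expect on clinical
data — where the same rule set was reported around 95 % sensitivity and
specificity with misclassifications concentrated exactly at episode
boundaries and in the 50 Hz case.

## Evaluation

Positive class is *unacceptable* everywhere. From the 2×2 table:
sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, PPV `tp/(tp+fp)`,
NPV `tn/(tn+fn)`, efficiency `(tp+tn)/total`, prevalence `(tp+fn)/total`,
LR+ `sens/(1−spec)`, LR− `(1−sens)/spec`. Ratios with zero denominators
are reported NaN and flagged `undefined` instead of infinite. Confidence
half-widths use the normal (Wald) approximation `z·sqrt(p(1−p)/n)` on the
respective denominators; Wilson rounds identically at the reported sample
sizes, so the simpler method is documented. Reporting precision:
percentages to one decimal, LR+ to three significant figures, LR− to two.

## Problem sizes and numerical choices

The synthetic validation cohort used by the tests and the acceptance
script is 20 one-hour recordings at 250 Hz (7200 ten-second samples,
matching the original study's sample count); it generates and classifies
in well under a minute. The sampling rate is a free parameter — the
algorithm is defined in seconds — and 250 Hz is the synthesis default as
a common wearable-ECG rate. Half-open interval arithmetic uses a 1e-9 s
tolerance when flooring durations to counts; label CSVs round-trip
exactly, signal CSVs to 6 decimals (0.5 nV, far below any threshold).

## Known limitations

* The 50 Hz blind spot is inherent to the rule set: a small mains
  sinusoid changes the window SD by ~A/√2, typically far below the 2×SD_t
  threshold. A spectral check of the 50 Hz harmonic against the template
  would address it but is not part of the validated algorithm and is not
  implemented.
* The template is fixed for the whole recording; posture changes or
  electrode re-gelling that legitimately change signal amplitude are not
  re-templated.
* Quality labels say nothing about fitness for ST-segment measurement or
  other fine morphology; the gate targets basic rhythm readability.
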