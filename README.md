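# ecgqc

Real-time signal-quality classification for single-lead wearable ECG.

Wearable ECG recorders (chest-belt or t-shirt Holter devices) spend a large
fraction of their recording time producing unusable traces: electrode
motion and loss of adhesion drive the signal toward the ADC rails, muscle
activity buries the ECG in broadband noise, and a detached lead leaves a
near-flat line. `ecgqc` implements a deliberately simple, threshold-based
quality gate that can run in real time on-device, labelling each stretch of
signal *acceptable* (P, QRS and T waves identifiable) or *unacceptable*,
so the wearer or a monitoring technician can fix the electrodes before
hours of signal are lost. No filtering, no QRS detection, no learning —
just window statistics against a per-recording reference.

## The algorithm

1. **Reference template.** Scan from the start of the recording (1 s
   steps) for the first stable 10 s span: peak-to-peak amplitude below 70 %
   of the ADC full span and an approximately constant isoelectric line.
   Record its maximum, minimum and standard deviation
   (`max_t`, `min_t`, `SD_t`).
2. **Windows.** Split the trace into consecutive, non-overlapping 2 s
   windows; compute `max_w`, `min_w`, `SD_w` (and the mean) for each.
3. **Rules** (strict inequalities, first hit wins):
   - *saturation*: `max_w − min_w > 0.95 × (ADC span)` — rail-to-rail
     oscillation from electrode loss;
   - *low amplitude*: `max_w − min_w < 0.05 × (max_t − min_t)` — ECG
     absent or negligible;
   - *excess SD*: `SD_w > 2 × SD_t` — high-variability noise.
   A window that fires no rule is acceptable; in particular a drifting
   baseline alone never rejects a window, because only the SD and range
   are compared.
4. **Aggregation.** Consecutive 10 s samples take the label of whichever
   class covers at least half of the sample (5 windows per sample with the
   defaults).

A `StreamingClassifier` consumes the signal sample-by-sample and emits
verdicts with one-window delay, identical to the batch output. The
`synth` module generates seeded synthetic recordings — Gaussian-wave beat
trains plus scheduled artifact episodes (baseline wander, saturation,
muscle noise, flatline, 50 Hz powerline) — with ground-truth labels, and
the `evaluation` module computes the 2×2 agreement table and the usual
diagnostic statistics (sensitivity, specificity, PPV/NPV, likelihood
ratios, efficiency; positive class = unacceptable).

## Worked example

Generate a 60 s synthetic recording (with a saturation episode at
20–30 s and a muscle-noise episode at 40–50 s), classify it, and score it
against its own ground truth:

```
$ ecgqc synth --duration 60 --seed 42 --out-prefix demo
wrote 1 recording(s) with prefix demo

$ ecgqc classify demo.signal.csv --out-prefix cls
30 windows, 6 samples (template from t=0s)

$ ecgqc evaluate cls.samples.csv demo.truth_samples.csv --out metrics.json
algorithm\reference,unacceptable,acceptable,total
unacceptable,2,0,2
acceptable,0,4,4
total,2,4,6

n samples            6
prevalence           33.3%
efficiency           100.0%
...
```

The 60 s recording gives 30 two-second windows and 6 ten-second samples;
the two corrupted samples (saturation, muscle) are flagged and the four
clean ones pass, so every diagnostic proportion is 100 % here (LR+ is
reported as undefined rather than infinite when specificity is 1).

The full report for any published-style 2×2 agreement table:

```
$ ecgqc metrics-from-table 3150 177 175 3698
n samples            7200
prevalence           46.2%
efficiency           95.1%
sensitivity          94.7%  (±0.8% at 95% CI)
specificity          95.4%  (±0.7% at 95% CI)
PPV                  94.7%
NPV                  95.5%
LR+                  20.7
LR-                  0.055
```

Here sensitivity 94.7 % means 94.7 % of truly unreadable 10 s samples were
flagged; LR+ 20.7 means a flagged sample raises the odds of true
unreadability twenty-fold.

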