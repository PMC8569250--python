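# neurocoh

Resting-state EEG functional brain-network analysis for two-group,
pre/post stimulation studies — built around the question of how excitatory
intermittent theta-burst stimulation (iTBS) over motor cortex changes
interhemispheric functional connectivity and network efficiency in stroke
survivors.

The package implements the complete analysis chain as a tested, reusable
pipeline:

1. **Preprocessing** — downsample (default 2048 → 1000 Hz, exact rational
   polyphase), 0.1–40 Hz zero-phase band-pass, 2000 ms epochs, optional
   automatic ICA artifact removal, rejection of epochs exceeding 100 μV,
   common-average re-reference.
2. **Band power** — Welch PSD (1 s Hann segments, 50% overlap, pooled
   across epochs); absolute power (μV²) integrated over delta (1–4 Hz),
   theta (4–8), alpha (8–13) and beta (13–30), per channel and per
   sensorimotor cluster (the nine electrodes around C3 and around C4).
3. **Connectivity** — magnitude-squared coherence for every electrode
   pair, `MSC(f) = |S_xy|² / (S_xx S_yy)` from segment-averaged spectra,
   band-averaged and Fisher-stabilized as `z = atanh(√MSC)`; the
   interhemispheric summary is the mean z over all left×right cluster
   pairs (9 × 9 = 81 by default).
4. **Networks** — weighted undirected graphs on all electrodes, a
   sparsity sweep (0.10–0.40 in steps of 0.05, strongest edges kept),
   global efficiency `E(G) = 1/(N(N−1)) Σ_{i≠j} 1/D(i,j)` with edge
   length 1/weight, summarized by the trapezoidal area under the
   efficiency–threshold curve (AUC).
5. **Statistics** — linear mixed-effects Group × Timepoint inference with
   subject as random effect (exact stratum fit for the balanced pre/post
   design), Tukey–Kramer within-group post hoc contrasts, and Pearson
   correlations with clinical covariates.
6. **Protocol & cohort** — iTBS schedule arithmetic (3-pulse 50 Hz bursts
   at 5 Hz, 2 s trains every 10 s over 192 s) and a packaged 30-subject
   stroke cohort table with the delivered-intensity rule
   `min(0.7 · RMT, 40 %MSO)`.
7. **Synthetic cohorts** — a coupled-source EEG generator with known
   per-band interhemispheric coupling κ (in-band coherence κ² by
   construction), 1/f background and sensor noise, so every stage is
   testable with ground truth and no external data.

## Worked example

```python
import neurocoh as nc

# stimulation protocol: enumerate every pulse of the default session
sched = nc.itbs_schedule()
print(sched.n_pulses, sched.n_trains, round(float(sched.pulse_times[-1]), 2))
# 600 20 191.84   -> 600 pulses in 20 trains, last pulse at 191.84 s

# cohort summaries from the packaged subject table
cohort = nc.load_cohort()
for col, scope in [("rmt_pct_mso", "active"), ("intensity_pct_mso", "active")]:
    print(col, scope, round(nc.cohort_summary(cohort, col, scope)["mean"], 1))
# rmt_pct_mso active 82.7        -> mean resting motor threshold, %MSO
# intensity_pct_mso active 38.7  -> mean delivered iTBS intensity, %MSO

# a synthetic cohort with a coupling increase after active stimulation
from neurocoh.validation import reduced_cohort_spec, interaction_pvalues
pv = interaction_pvalues(reduced_cohort_spec(seed=7, effect=0.25))
print({b: round(v["interaction_p"], 4) for b, v in pv.items()})
# {'delta': 0.0483, 'theta': 0.0}  -> Group x Timepoint interaction P per band
```

The interaction P values say that the simulated coupling increase in the
active group's post-stimulation recordings is picked up by the full chain
(simulate → preprocess → coherence → Fisher z → mixed model) in both
coupled bands.

## Layout

```
src/neurocoh/
  montage.py      channel montages, recordings, clusters, bands, I/O
  preprocess.py   resample / filter / epoch / ICA / reject / re-reference
  spectral.py     Welch PSD and absolute band power
  connectivity.py coherence, Fisher z, interhemispheric summary
  network.py      thresholding, shortest paths, global efficiency, AUC
  group_stats.py  mixed-model inference, Tukey-Kramer, correlations
  protocol.py     iTBS arithmetic + packaged cohort table
  simulate.py     coupled-source synthetic EEG and cohorts
  validation.py   reduced-scale calibration and validity protocols
  pipeline.py     config-driven end-to-end runs
  cli.py          `neurocoh` command-line interface
```

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
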