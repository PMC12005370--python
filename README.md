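# srtpipe

Analysis pipeline for rodent lever-holding tasks: a simple reaction-time
(SRT) task with variable foreperiods and a self-timing task, as used to
study how motor cortex (MO) and dorsolateral striatum (DLS) contribute to
withholding and releasing a prepared movement. The package is aimed at
behavioral-neurophysiology groups who record trial event logs, spike
times, and tracked 2D trajectories from such tasks and want the full
analysis chain — and a matched simulator for every data modality — as
tested, reusable code.

## The science in brief

In the SRT task a rat presses a lever, holds it through a foreperiod
FP ∈ {0.5, 1.0, 1.5} s, and releases on a tone within a 600 ms window.
Under the **deadline model**, the response is emitted at
min(D, FP + L): D is a random internal deadline and L the detection +
motor latency. Releases before the tone (D < FP) are premature
(anticipatory) responses. The **anticipation function**

    G(t) = Σ_{i: FP_i > t} N_i F_i(t) / Σ_{i: FP_i > t} N_i

(N_i trials at foreperiod i; F_i(t) the fraction of them released
prematurely at or before t) estimates the deadline CDF from behavior
alone. The pipeline also implements:

- RT extraction (correct + late trials, 0.1–2 s window, 10×MAD outlier
  removal) and a per-rat RT ~ 1 + FP model classifying speeding /
  anti-speeding effects under Benjamini–Hochberg FDR control;
- spike density functions (Gaussian kernel, σ = 20 ms) warped piecewise
  linearly between behavioral events (press → stimulus → release → poke)
  onto median target times, z-scored, peak-ranked, and decomposed by
  population PCA with cross-region component correlations;
- occupancy-grid trajectory similarity (supercover rasterization, 2D
  Gaussian smoothing, dot-product scores, median pairwise similarity),
  camera-drift correction by 2D cross-correlation, and paw reach speed;
- two-sample and paired (sign-flip) permutation tests with automatic
  exact enumeration, the BH critical p-value, and pooled-variance t
  statistics from summary data;
- generative simulators for all of it: deadline-model SRT sessions,
  self-timing sessions, event-locked inhomogeneous-Poisson spiking, and
  noisy curved trajectories.

## Worked example

The numbered scripts under `analysis/` run a complete simulated study: a
cohort of eight SRT rats before and after a bilateral-DLS-like lesion
(deadline distribution scaled to 60%, poke latency scaled by 1.7) plus a
self-timing rat, then each analysis stage over the written tables.

```sh
python analysis/01_simulate_cohort.py
python analysis/02_behavior_analysis.py
python analysis/03_neural_analysis.py
python analysis/04_kinematics_analysis.py
python analysis/05_stats_report.py
```

Output of `02_behavior_analysis.py`:

```
median RT: Pre 0.300 s -> Post_Late 0.300 s
anticipation integral change: median +0.311 s (positive in 100% of rats)
normalized retrieval duration Post_Late: 169% of Pre
self-timing mode (Pre): 1.13 s
self-timing mode (Post): 0.97 s
```

The anticipation-function integral grows after the simulated lesion (the
deadline CDF shifted left, so the rats "wait less"), reward retrieval
slows to ~170% of baseline (the injected vigor deficit), and the
self-timed response mode shifts from just after the 1 s foreperiod to
just before it — while RT itself is unchanged, because the simulated
lesion leaves the detection latency untouched. `03`–`05` likewise print
epoch modulation and PCA variance per region, recovered camera drift and
similarity medians, and the within-subject permutation-test family with
its BH critical p-value; all tables land under `results/`.

Library use is one import away from the same results:

```python
from srtpipe import synth_tasks as st
from srtpipe import behavior_metrics as bm

session = st.simulate_srt_session(st.DeadlineModelParams(), 10_000, seed=1)
curve = bm.anticipation_function(bm.classify_trials(session))
```

A thin CLI wraps the same functions
(`srtpipe simulate-srt --n-trials 500 --seed 7 -o out/`,
`srtpipe analyze-behavior --sessions out/sessions.csv -o out/`).

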