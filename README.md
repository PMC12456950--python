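# rabflim

Analysis of two-photon fluorescence lifetime imaging (2pFLIM) experiments
that track Rab-GTPase activity in single dendritic spines with FRET sensors
— from per-pixel photon arrival-time histograms to binding-fraction maps,
spine-resolved activity and volume time courses during glutamate-uncaging
structural LTP (sLTP), and surface-corrected FRAP quantification of
receptor exocytosis. A seeded synthetic-data generator produces every input
with known ground truth, so the whole pipeline is testable without
microscope data.

Intended users: labs doing 2pFLIM/FRET sensor imaging of signaling in
spines (Rab4, Rab10 and similar sensors) who want a reproducible,
scriptable alternative to ad-hoc per-experiment analysis code.

## The model

A donor-tagged Rab bound to its acceptor-tagged effector domain undergoes
FRET, shortening the donor lifetime from τ_D to τ_AD. The measured decay is

    F(t) = F0 [ P_D·H(t, t0, τ_D, τ_G) + P_AD·H(t, t0, τ_AD, τ_G) ]

with H a single exponential convolved with a Gaussian instrument response,

    H(t, t0, τ, τ_G) = ½ exp(τ_G²/2τ² − (t−t0)/τ) · erfc((τ_G² − τ(t−t0)) / (√2 τ τ_G)),

evaluated through the scaled complementary error function for numerical
stability. The bound fraction P_AD (the sensor's activity readout) comes
either from a Poisson maximum-likelihood fit or from the mean photon
arrival time ⟨t⟩ via ⟨τ⟩ = ⟨t⟩ − t0 and

    P_AD = τ_D(τ_D − ⟨τ⟩) / [(τ_D − τ_AD)(τ_D + τ_AD − ⟨τ⟩)],

with a window-aware variant that removes the bias introduced when the
acquisition window truncates the decay tail. Spine volume uses the
volume-marker channel, V = (integrated spine intensity / mean dendrite
intensity) × PSF volume, and FRAP recovery of a surface reporter is
corrected for membrane-area growth by ΔF_t/F = ΔF/F − (ΔV/V)^(2/3).
Details, defaults and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a Rab10-like sLTP experiment (sustained −5 percentage-point
binding-fraction step in the stimulated spine, two-phase volume transient),
analyze it, and summarize the standard windows:

```sh
rabflim simulate --preset rab10 --seed 7 --out run/exp
rabflim timecourse --input run/exp --out run/timecourse.csv
rabflim report --timecourse run/timecourse.csv \
    --windows transient --windows sustained_sensor --out run/windows.csv
```

The `timecourse` step first fits the pooled first frame image-wide to
determine the pulse offset and IRF width (here `t0 = 0.9963 ns,
tau_G = 0.1491 ns` against programmed values of 1.0 and 0.15), then writes
a tidy CSV of per-ROI changes. `run/windows.csv` from this exact run:

```
roi,window,start_min,end_min,delta_pad_pct_mean,delta_vol_pct_mean,n_frames
adjacent_spine,transient,1.3,4.0,1.0917699223350592,-0.7637068277670125,4
dendrite,transient,1.3,4.0,0.5399657449371973,-0.5047409127072112,4
stimulated_spine,transient,1.3,4.0,-4.4253281733805085,128.86916690523904,4
adjacent_spine,sustained_sensor,19.0,31.0,-1.1716927935788637,-0.389832440442266,5
dendrite,sustained_sensor,19.0,31.0,0.6839191766803654,0.4765693268816924,5
stimulated_spine,sustained_sensor,19.0,31.0,-6.130376373311039,80.24162610936159,5
```

Reading: the stimulated spine shows the programmed sustained Rab10
inactivation (≈ −5 percentage points of binding fraction, here −6.1 with
single-experiment shot noise of ±1–2 points) and the two-phase volume
change (+129% transient decaying toward the +80% plateau), while the
adjacent spine and dendrite fluctuate around zero — the compartmentalized
response the experiment is designed to detect. Averaging across many
seeded replicates recovers the programmed values (see
`tests/test_acceptance.py`).

The same library surface is importable (`rabflim.fit_decay_curve`,
`rabflim.roi_timecourse`, `rabflim.frap_pipeline`, ...) for notebook use,
and `rabflim frap` analyzes dual-channel FRAP CSVs.

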