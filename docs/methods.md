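# Methods

## The photophysical model

A FRET sensor for Rab-GTPase activity pairs a donor-tagged Rab with an
acceptor-tagged effector domain that binds only the GTP-loaded (active) Rab.
When bound, FRET shortens the donor lifetime from `tau_D` to `tau_AD`, so the
measured per-pixel fluorescence decay is a two-component mixture

    F(t) = F0 [ P_D H(t, t0, tau_D, tau_G) + P_AD H(t, t0, tau_AD, tau_G) ]

where `P_AD` is the bound fraction (the activity readout), `P_D = 1 − P_AD`,
`t0` the excitation-pulse offset, and `H` a single exponential convolved with
a Gaussian instrument response of width `tau_G`:

    H(t, t0, tau, tau_G) = 1/2 exp(tau_G^2/(2 tau^2) − (t − t0)/tau)
                               erfc( (tau_G^2 − tau (t − t0)) / (sqrt(2) tau tau_G) )

`H` is `tau` times an ex-Gaussian density and integrates to `tau`.

**Numerical stability.** The raw `exp * erfc` product overflows for small
`tau_G`. With `x = t − t0` and `b` the erfc argument, the identity
`a − b^2 = −x^2/(2 tau_G^2)` gives the stable form
`H = 1/2 exp(−x^2 / (2 tau_G^2)) erfcx(b)` for `b ≥ 0` (`erfcx` is the scaled
complementary error function); for `b < 0` the direct product is safe because
the exponent decays with `x`. The same identity yields a closed-form
antiderivative, `∫_{−inf}^{t} H = tau Φ((t − t0)/tau_G) − tau H(t)`, so
per-bin expected counts are exact integrals, not midpoint approximations
(midpoint evaluation systematically biases short-lifetime bins).

**Histogram geometry.** The shipped default is 64 bins spanning a
12.5 ns laser period (the standard TCSPC convention for an 80 MHz
Ti:Sapphire source); all routines are parametric in the bin edges.
Periodic wrap-around of the decay tail into the next excitation cycle is
available (`wrap_period`) but off by default, matching the model equations.

## Calibrations

Donor lifetimes are fixed, never fitted, from independent calibration:

| sensor               | tau_D (ns) | tau_AD (ns) |
|----------------------|-----------|-------------|
| mEGFP-Rab4a          | 2.46      | 1.10        |
| mEGFP-Rab10          | 2.60      | 1.10        |
| mTurquoise2-Rab10    | 4.15      | 1.60        |

(1.10 ns applies to mEGFP/mCherry pairs, 1.60 ns to mTurquoise2/mVenus.)

## Estimating the bound fraction

Two routes, mirroring 2pFLIM practice:

1. **Curve fitting** (`fit_decay_curve`). The default objective is the
   Poisson maximum likelihood, implemented as the multinomial over
   window-renormalized bin probabilities with the amplitude profiled out
   (the amplitude MLE always reproduces the observed total, so `F0` is
   recovered afterwards from the total count). Neyman-weighted least
   squares is available via `objective="wls"`. The two-stage protocol
   freezes `t0` and `tau_G` from an image-wide fit (free
   `{F0, t0, tau_G, P_AD}`) and then fits per-ROI histograms with only
   `{F0, P_AD}` free; the per-ROI path caches the two component bin
   integrals and reduces to a 1-D bounded optimization. Initialization:
   `t0` at the peak bin minus `tau_G`, `tau_G = 0.15` ns, `P_AD = 0.3` — a
   robust basin for the erfc model. Fits landing outside `[0, 1]` are
   clipped with the raw optimum retained in `FitResult.p_ad_raw`;
   non-convergence is flagged, never silent.

2. **Mean arrival time** (`mean_photon_arrival_time`,
   `binding_fraction_from_mean_lifetime`). The count-weighted mean arrival
   time `<t>` minus `t0` gives `<tau>`, and

       P_AD = tau_D (tau_D − <tau>) / [ (tau_D − tau_AD)(tau_D + tau_AD − <tau>) ]

   inverts the amplitude-weighted mean lifetime exactly. `<tau>` values at
   or beyond `tau_D + tau_AD` are outside the model's physical range and
   raise a singularity error.

**Truncation.** The closed form assumes the untruncated mean lifetime. A
12.5 ns window cuts the tail of a 2.46–4.15 ns decay, biasing the windowed
`<tau>` low and the closed-form `P_AD` high (about +0.09 at `P_AD = 0.4`
for mEGFP-Rab4a at the default geometry), which shrinks baseline-subtracted
steps by roughly 20%. Time courses therefore default to a *window-aware
inversion* (`binding_fraction_windowed`): the model's binned, truncated
mean-lifetime map — computed with the same bin centers and window as the
data — is inverted by bisection (it is strictly decreasing in `P_AD`).
This makes the estimator consistent with the measurement by construction.
The plain closed form remains available (`method="closed_form"`) and the
two agree on untruncated data.

`lifetime_map` renders per-pixel `<tau>` with pixels under `min_photons`
(default 30) masked; at typical lifetimes that keeps the per-pixel standard
error below ~0.2 ns. The photon-weighted mean of pixel `<tau>` equals the
pooled-ROI `<tau>` exactly, so maps and ROI estimates are mutually
consistent.

## Time courses and windows

Per ROI (stimulated spine, adjacent spine, dendrite) and timepoint, pixel
histograms are pooled (counts conserved exactly) and converted to `P_AD`.
Changes are reported relative to the pre-stimulus baseline — by default the
mean over all frames with `t < 0` — so the baseline-window mean of every
reported series is zero by construction:

* `ΔP_AD(t)` — absolute change in percentage points (matching
  "binding fraction change (%)" axes);
* `ΔV/V(t)` — percent change of the ROI-integrated acceptor (volume-marker)
  intensity. The known donor bleed-through into the acceptor channel is not
  corrected; donor and acceptor volume proxies follow similar time courses.

Window presets: transient = 1.3–4 min, sustained (sensor) = 19–31 min,
sustained (structural volume) = 20–35 min; endpoints inclusive, mean over
frames inside the window. Absolute spine volume uses
`V = (integrated spine intensity / mean dendrite intensity) × PSF volume`;
the PSF volume has no in-package calibration and defaults to 0.1 fL only as
a placeholder that must be replaced by the instrument's own value.

Groups of experiments are summarized as mean ± SEM (SD/√n) per timepoint on
a shared grid (a linear-interpolation resampler is provided), and
`two_sample_summary` runs a Welch t-test on per-experiment window averages.
Identical degenerate groups are flagged rather than assigned a p-value.

## FRAP exocytosis correction

After photobleaching the surface pool of a pH-sensitive surface reporter,
recovery mixes true exocytosis with membrane-area growth of the enlarging
spine. Writing `ΔF = ΔF_t + f ΔS` with `F0 = f S` the fluorescence
immediately after bleach, and taking `ΔS/S = (ΔV/V)^(2/3)`, the trafficking
component is

    ΔF_t/F = ΔF/F − (ΔV/V)^(2/3).

Two reference conventions coexist deliberately: display normalization
divides each channel by its pre-bleach mean (recovery-plot convention, and
the source of the reported post-bleach floor, typically ~0.15), while the
correction references the reporter to its post-bleach value and the volume
to its pre-bleach mean, per the derivation. For transiently shrinking
spines the surface term is extended sign-preservingly as
`sign(ΔV/V)|ΔV/V|^(2/3)`; outputs carry a flag wherever this extension was
active. Incomplete bleaching is reported (the floor) but not corrected.

## The synthetic-data generator

The generator reproduces exactly the statistical structure the analysis
assumes, with a seed that fully determines every output.

* **Photon sampler** — `t = t0 + Normal(0, tau_G) + Exponential(tau_k)`,
  component `k` drawn with probability proportional to `P_k tau_k`: under
  the amplitude convention a component's photon yield scales with its
  lifetime, so the bound-photon fraction converges to
  `P_AD tau_AD / (P_D tau_D + P_AD tau_AD)`, not `P_AD`.
* **Imaging scenarios** — a horizontal dendrite shaft with a stimulated and
  an adjacent spine (circular, non-overlapping by validation). Per frame
  and pixel, bin counts are Poisson with intensity = pixel rate × model bin
  probabilities (equivalent to sampling and binning individual photons, by
  Poisson thinning). Programmed trajectories: sustained step or
  exponentially decaying pulse in `P_AD` (stimulated spine only) and a
  two-phase volume transient `ΔV/V(t) = [A2 + (A1 − A2) e^{−t/τ_dec}]
  (1 − e^{−t/τ_rise})` with `ΔV/V(0) = 0`. Defaults (A1 = 2.5, A2 = 0.8,
  τ_dec = 2 min, τ_rise = 0.5 min, step −0.05, pulse +0.08 with 2 min
  decay, 10^4 photons per spine per frame, baseline `P_AD` 0.3 / 0.15) are
  qualitative choices resembling typical glutamate-uncaging experiments;
  recovery tests always compare against what a scenario actually
  programmed, never against literature values. Spine growth scales the
  donor photon rate and the acceptor intensity with `(1 + ΔV/V)`; the
  default keeps the footprint fixed ("intensity" mode) so ROI masks align
  exactly with the generating geometry, while "dilate" mode also grows the
  footprint as `(1 + ΔV/V)^(1/3)` in radius and pads the analysis mask so
  integrated intensity stays inside it.
* **Stimulus timelines** — uncaging scenarios use 4 baseline frames, one
  flagged frame during the 0.5 Hz × 60 s train, dense early sampling and
  sparser late frames out to 31 min; bath-application scenarios use 6 min
  baseline, 2 min application and a 32 min washout grid.
* **FRAP scenarios** — five 1-min baseline frames, bleach over [−2, 0] min
  dropping the surface brightness per area to a configurable floor (0.15),
  uncaging over [0, 1] min, post frames at 1 min intervals. The reporter is
  generated as `f S(t) + trafficked(t)` with the surface following the same
  2/3-power convention the correction assumes, so the noiseless inversion
  is exact by construction; trafficking is a saturating influx
  `amp (1 − e^{−t/1.5 min})`. Noise is additive Gaussian relative to each
  channel's pre-bleach mean.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: optical PSF blur, detector afterpulsing,
dark counts and pile-up; motion and focus drift; spine-morphology diversity
and neighbor contamination; donor bleed-through into the acceptor channel;
lateral diffusion of the surface reporter (the FRAP model contains only the
geometric surface term plus programmed trafficking). Recovery results
therefore validate the estimators against their own assumed forward model,
not against microscope physics.

## Problem sizes and tolerances

Default simulation sizes were chosen so the full test suite and the
acceptance script each complete in well under a minute of compute per
criterion on a single CPU: 32×32 px scenarios at 10^4 photons per spine per
frame and 20 frames; 50 replicates for step-recovery statistics, 20 for the
transient-vs-sustained contrast, 200 fit replicates per bound fraction at
10^5 photons, 100 chi-square runs at 2×10^4 photons. Key numerical
tolerances: closed-form inversion exact to 1e−12; `H` vs brute-force
convolution to 1e−6 relative (comparisons skipped only where both sides
underflow below 1e−280); per-bin integrals to 1e−8 relative; window
inversion bisection to 1e−12.

At `P_AD = 0.1` with 10^5 photons the fit's dispersion sits at the
Cramér–Rao bound (sd ≈ 0.010), so coverage statements at ±0.02 are near
their asymptotic 96% — worth knowing before tightening any tolerance.

## Known limitations

* The window-aware inversion needs `t0`, `tau_G` and the bin geometry; with
  a mis-specified `t0` it inherits that error like every mean-lifetime
  method.
* `ΔV/V` from a fixed ROI mask underestimates growth that escapes the mask;
  use "dilate"-mode margins or generous masks for strongly growing spines.
* Mean-intensity analyses normalize integrated intensity by the current
  mask area; no motion correction or spine tracking is provided.
* The t-test helper is a convenience; it does not replace the multi-group
  ANOVA machinery of a full statistical analysis.
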