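# pactrack

Tools for tracking contrast-agent clearance through organs with dynamic
photoacoustic tomography (PAT). PAT images optical absorption at ultrasound
resolution deep in tissue, so an injected absorbing probe can be followed
frame by frame as it perfuses into and clears from the liver or kidneys.
`pactrack` implements the computational side of such an experiment:

* **kinetics** — relative enhancement `RE(t) = 100·(PA(t) − PA(0))/PA(0)`,
  respiratory-outlier (Hampel) filtering, and a fluence-corrected empirical
  pharmacokinetic model

  ```
  RE(t) = 0                                                    0 ≤ t < t0
  RE(t) = (A / F_ratio) · (1 − e^{−α(t−t0)})^q · e^{−β(t−t0)}  t ≥ t0
  ```

  fitted by bounded multi-start nonlinear least squares, with clearance
  parameters derived from the fitted curve: the peak time `T_max`, the
  elimination half-life `T_1/2` (time after `T_max` for the curve to fall to
  half its peak), average uptake and excretion rates `U_α = 60α`,
  `E_β = 60β` (min⁻¹), and the area under the curve over a stated window.
* **fluence** — 2-D Monte Carlo photon transport on labeled optical tissue
  maps (Henyey–Greenstein scattering, weighted absorption, Russian
  roulette), the post/pre-injection fluence ratio `F_ratio` that corrects
  the model amplitude, fluence compensation of images, and
  signal-to-background quantification.
* **saft** — coherence-factor-weighted synthetic-aperture focusing of
  elevational scan stacks (virtual-detector delay-and-sum over the
  defocused hourglass beam, `PA_CFSAFT = PA_SAFT · CF`), plus zero-phase
  frequency-band separation of the refocused volume into high-frequency
  (vascular) and low-frequency (tissue/organ) components, envelope
  detection and FWHM resolution metrics.
* **tracking** — the dynamic differential-imaging pipeline: pre-injection
  baseline averaging, adaptive Wiener-type denoising, frame − baseline
  differential images, threshold suppression at a fraction of the series
  maximum, Frangi vesselness enhancement, and pseudo-color overlay.
  Quantitative ROI curves are always taken from raw frames.
* **phantom** — seeded synthetic data for every stage (defocused point
  targets, kinetic movies with breathing artifacts, optical tissue maps,
  and a minimal ring-array forward/back-projection pair), each returning
  its ground truth.

## Worked example

Simulate a noisy kinetic movie with breathing artifacts, extract the organ
ROI curve, filter, fit, and summarize:

```python
import numpy as np
from pactrack import kinetics as K, phantom, tracking

params = K.EMMParams(a=80.0, t0=5.0, alpha=0.05, beta=0.002, q=1.5)
scene = phantom.KineticScene(
    rois=(phantom.KineticROI(center=(32, 32), radius=10, params=params),),
    n_frames=620, n_baseline=20, frame_interval_s=1.0,
    breathing=phantom.BreathingSpec(), noise_sigma=1.0, seed=11,
)
series, truths, spiked = phantom.make_kinetic_movie(scene)
roi = tracking.ROIMask(mask=truths[0]["mask"])
curve = tracking.roi_timecourse(series, roi, n_baseline=20)
re = K.filter_breathing_outliers(K.relative_enhancement(curve))
fit = K.fit_emm(re, f_ratio=1.0, seed=0)
s = K.clearance_summary(fit, t_end=600.0)
print(f"alpha = {fit.params.alpha:.4f} /s   beta = {fit.params.beta:.5f} /s")
print(f"RE_max (A/F_ratio) = {s.re_max_amplitude:.1f} %   curve peak = {s.re_max_curve:.1f} %")
print(f"T_max = {s.t_max:.1f} s   T_1/2 = {s.t_half:.1f} s")
```

prints

```
alpha = 0.0479 /s   beta = 0.00213 /s
RE_max (A/F_ratio) = 76.0 %   curve peak = 62.5 %
T_max = 98.6 s   T_1/2 = 346.5 s
```

The true rates were α = 0.05 s⁻¹ and β = 0.002 s⁻¹: the fit recovers both
within a few percent despite 1-unit pixel noise and 1.5× breathing spikes
on 10 % of frames. `RE_max` is reported in both conventions — the model's
upper amplitude `A/F_ratio` and the fitted curve's actual peak, which is
strictly smaller whenever β > 0.

A command-line interface mirrors the library
(`pactrack simulate|fit-emm|saft|fluence|sbr|track`, see `pactrack --help`);
every stochastic subcommand requires an explicit `--seed`.

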