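# Methods

## Pharmacokinetic model

Dynamic photoacoustic (PA) intensity in an organ region is converted to
relative enhancement `RE(t) = 100·(PA(t) − PA(0))/PA(0)` against the mean
pre-injection baseline PA(0). The time course is modeled empirically as a
saturating uptake multiplied by exponential washout,

    RE(t) = (A / F_ratio) · (1 − e^{−α(t−t0)})^q · e^{−β(t−t0)},  t ≥ t0,

and zero before the rise time point `t0`. `A/F_ratio` is the upper
amplitude in percent; `α` (s⁻¹) the uptake rate, `β` (s⁻¹, ≥ 0) the
excretion rate, `q` (dimensionless) the early-uptake shape. `F_ratio`, the
post/pre-injection light-fluence ratio at the location, corrects the PA
amplitude for illumination changes caused by the absorbing probe itself; it
is supplied (from the Monte Carlo module or measurement) and held fixed —
fitting it jointly with `A` would be unidentifiable, since only `A/F_ratio`
enters the likelihood. The model is descriptive, not compartmental: its
parameters summarize a curve, not physiology.

**Fitting.** Bounded trust-region least squares (`scipy.optimize
.least_squares`) on (A, t0, α, β, q) with bounds A ∈ (0, 10·max RE],
t0 ∈ [0, time of peak], α ∈ (0, 100], β ∈ [0, 10], q ∈ [0.1, 10].
Initialization is data-driven: A from the peak (scaled by `F_ratio`), t0
from the first 5 %-of-peak crossing, α from the 10–90 % rise time
(ln 9 / Δt), β from the log-linear tail slope, q = 1. Up to five starts
with seeded multiplicative jitter in [0.5, 2]; best cost wins; the
optimizer's convergence status is propagated, never forced.

**Derived clearance parameters.** The curve's peak time has the closed form
`t_max = t0 + ln((qα + β)/β)/α` (from setting the log-derivative
`qα e^{−αΔ}/(1 − e^{−αΔ}) = β` to balance), clamped to the observation
window; with β = 0 the curve is nondecreasing and `t_max` is the window
end. The half-life `T_1/2` is the elapsed time after `t_max` at which the
fitted curve reaches half its peak, found by bracketed root finding
(Brent) on the decaying limb; β = 0 yields an infinite sentinel, never a
number. Rates are reported in min⁻¹ (`U_α = 60α`, `E_β = 60β`) — the
convention of the printed tables — while all internal time is seconds.
AUC integrates the fitted curve over [0, t_end] by adaptive quadrature
with a breakpoint at t0; a raw-trapezoid mode on the measured samples is
available, since which of the two a given report uses is often
unstated. `RE_max` is reported in both conventions (amplitude `A/F_ratio`
vs. actual curve maximum); they differ by the factor
`(qα/(qα+β))^q · e^{−β(t_max−t0)}`.

**Respiratory outliers.** Breathing transiently modulates the whole frame;
on ROI curves this appears as isolated spikes. A Hampel filter (centered
window 11 samples, threshold 3 scaled MADs, replacement by the running
median) removes them while leaving smooth kinetics untouched — on a
noise-free model curve the filter is an identity to < 1e−9 of the peak.
The window must stay shorter than the kinetic rise; 11 samples at ~1 Hz
framing is comfortably below any physiological uptake time here.

## Monte Carlo fluence

2-D weighted photon transport on a labeled grid of (μa, μs, g) per cell.
Hop lengths are exponential in the total interaction coefficient of the
cell where the hop starts; at each interaction the fraction μa/μt of the
photon weight is deposited and the direction is rotated by an in-plane
angle drawn from the 2-D Henyey–Greenstein density
p(θ) = (1/2π)(1−g²)/(1+g²−2g cos θ), sampled by its closed-form inverse
CDF θ = 2 atan(((1−g)/(1+g)) tan(π(u−½))). Photons below weight 1e−4
undergo Russian roulette with survival 0.1. Boundaries are
refractive-index matched; exiting weight is scored as escaped. Energy
bookkeeping (launched + roulette-created = deposited + escaped +
roulette-destroyed) closes to 1e−6 relative and is stored with every map.

Fluence is estimated from deposited weight as Φ = D/(μa·cell area); in
non-absorbing media the estimator switches automatically to track-length
scoring (weight × path length per cell, sub-sampled at quarter-cell
spacing). Letting hops cross property boundaries (rather than stopping at
each cell face) is exact in homogeneous media and a standard desk-scale
approximation in layered ones; the package's correction tests depend on
the monotone depth decay, not on interface-exact transport. Illumination
patterns: pencil (top center), uniform-top, and ring-inward (64 point
sources aimed at the grid center, a planar stand-in for a conical-lens
ring pattern).

Image compensation divides a frame by max(Φ, floor), with the floor at 1 %
of the fluence maximum by default so that near-zero-fluence pixels are not
amplified into artifacts. The signal-to-background ratio is the plain
linear ratio of ROI means. Tissue presets carry literature-typical
soft-tissue coefficients (e.g. μa 0.01–0.5 mm⁻¹, μs 5–10 mm⁻¹, g 0.9);
they are generic fixtures, not organ-calibrated values.

## Synthetic-aperture refocusing with coherence weighting

A focused transducer scanned elevationally behaves, for out-of-focus
depths, like a virtual point detector at the focus: a source at distance
`l` spreads over the elevational half-extent `z = (l − l_f)·w/(2 l_f)`
(element height `w`, focal distance `l_f`), and its echoes trace the
hyperbola `r_{i+j} = sqrt(r_i² + (j·Δz)²)` across neighboring scan lines,
where `r_i = |(n_0 − n_i)/f_s·c|` is the axial range from the focus. The
delay-and-sum aligns layer `i+j` by
`Δt_j = sign(l − l_f)·(r_{i+j} − r_i)/c` and sums over the coherent
aperture.

Design choices, all switchable:

* **Aperture extent.** `z_s = ⌊|z|/Δz⌋` counts layers per side of the
  defocus half-extent. The default aperture sums j ∈ [−z_s, +z_s], i.e.
  the entire insonified extent — the ± in the extent formula says the beam
  spreads to both sides of the target, and an aperture spanning only half
  of it (j ∈ [−z_s/2, +z_s/2], also available as `aperture="half"`)
  under-fills the synthetic aperture and leaves mildly defocused targets
  (≈5 mm past focus in the packaged geometry) refocused by well under 2×.
  With the full aperture the packaged three-target phantom shows 3.3–5.9×
  elevational FWHM recovery.
* **Delay sign.** One consistent convention is used: under the
  virtual-detector forward model the defocused echo in layer i+j arrives
  *later* than the on-axis echo for targets beyond the focus, so neighbor
  traces are read at `t + Δt_j`. Formulations that write `t − Δt_j`
  implicitly flip the sign inside Δt; the two are equivalent.
* **Coherence factor.** `CF = PA_SAFT²/(N·Σ_j PA(i+j, ·)²)` with N the
  number of terms actually summed, which by Cauchy–Schwarz bounds CF in
  [0, 1] including at stack edges where the aperture truncates. The
  alternative normalization by `z_s` (seen in print) gives
  CF = (2z_s+1)/z_s > 1 on fully coherent input; it is kept as
  `cf_norm="zs"` to document the anomaly, not as a default.
* Fractional delays use linear interpolation (nearest-neighbor
  switchable); apertures truncate at stack edges, never wrap; samples with
  z_s = 0 (at focus) pass through with CF = 1.

Band separation applies complementary zero-phase rectangular masks in the
real-FFT domain along the time axis, so low + high reconstructs the input
to machine precision and energy is partitioned exactly (Parseval). The
default cutoff of 2 MHz for a 5.5 MHz transducer splits slowly varying
tissue/organ signal from vascular detail; it is a parameter, not a
constant of nature. Envelopes are analytic-signal magnitudes (Hilbert
transform); resolution is quantified as linear-interpolated FWHM of a
single-peak profile, with a hard error when no half-maximum crossing
exists — a silent fallback would corrupt resolution statistics.

## Differential tracking pipeline

Baseline = pixelwise mean of the first `n_baseline` frames (600 at the
full acquisition rate; the phantom fixtures use 20 with the interval
scaled accordingly). Each denoised frame minus the denoised baseline gives
the signed differential image; pixels below 20 % of the *series-global*
differential maximum are zeroed (global, so late faint frames are not
renormalized; a per-frame mode exists). Denoising is the classic locally
adaptive Wiener shrinkage — pixel pulled toward its local mean by
max(0, 1 − ν/σ²_local) with ν the mean local variance — computed with
reflective boundaries so edges are not darkened by zero padding. Anatomy
is enhanced with the standard 2-D Frangi vesselness filter (bright-ridge
polarity, scales 1–4 px) and the differential signal is alpha-blended on
top through a colormap. The quantification path deliberately bypasses all
of this: ROI time courses are means of raw reconstructed pixels, and a
test pins that running the display pipeline leaves them bit-identical.

## Phantoms and what they do / do not show

The generators reproduce the geometry and noise structure the algorithms
are designed for: hourglass-beam point spreading with exact hyperbolic
arrival times, model-exact ROI kinetics with multiplicative breathing
spikes (1.5× on 10 % of frames, 0.5 s period) and additive Gaussian noise,
layered/inclusion optical maps, and an idealized single-speed-of-sound
ring array (64 elements, 10 mm radius in fixtures; real hardware is an
order of magnitude larger). They do not emulate acoustic attenuation or
heterogeneity, transducer impulse response, motion other than global
intensity spikes, spectral coloring of noise, or organ anatomy. Passing
tests therefore demonstrate the correctness of the formulas and their
implementations under controlled conditions — not in-vivo performance,
where segmentation quality, speed-of-sound error and physiological motion
dominate.

Problem sizes in the test-suite and the acceptance script (161 × 1024
stacks, 10⁶ photons, 620-frame movies, 81² ring grids) were chosen as the
smallest sizes at which each measured quantity is stable against its seed;
all generators scale up by argument.

## Known limitations

* The Monte Carlo is 2-D; absolute fluence magnitudes differ from 3-D
  transport, though depth-decay ratios (what `F_ratio` and the correction
  use) behave equivalently for the packaged geometries.
* `fit_emm` assumes a single bolus; recirculation or multi-phase uptake
  will alias into `q` and `β`.
* `t0` bounded by the empirical peak time makes fits to curves that are
  still rising at the window end (β ≈ 0) return `t_max` at the window
  boundary, by construction.
* The ring pair is a fixture-grade model (no filtered back-projection
  weighting); it localizes isolated points but does not reconstruct
  quantitative amplitudes.
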