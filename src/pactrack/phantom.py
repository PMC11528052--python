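"""Synthetic phantoms for every pipeline stage.

These generators define the study conditions the rest of the package is
exercised under:

* elevational A-scan stacks of defocused point targets under an hourglass
  beam (virtual-detector geometry) for the synthetic-aperture refocusing
  tests;
* dynamic kinetic movies whose ROI intensities follow the enhancement
  model, with seeded Gaussian noise and multiplicative breathing spikes;
* layered / inclusion tissue maps for the Monte Carlo fluence tests;
* a minimal single-speed-of-sound ring-array forward / delay-and-sum
  back-projection pair for reconstruction fixtures.

Every generator is bit-reproducible given its seed and returns its ground
truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .fluence import OpticalProperties, TissueModel
from .kinetics import EMMParams, emm_evaluate
from .saft import AScanStack, ScanGeometry
from .tracking import FrameSeries


@dataclass(frozen=True)
class PointTarget:
    """A point absorber: depth from the transducer (mm), elevational
    position along the scan axis (mm), and source amplitude."""

    depth_mm: float
    elevation_mm: float
    amplitude: float = 1.0

    def __post_init__(self):
        if self.depth_mm <= 0 or self.amplitude <= 0:
            raise ValueError("depth and amplitude must be > 0")


@dataclass(frozen=True)
class PointTargetScene:
    targets: Tuple[PointTarget, ...]
    pulse_center_hz: float = 5.5e6
    pulse_bandwidth_frac: float = 0.6
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class BreathingSpec:
    """Respiratory artifact model: multiplicative spikes of the given
    amplitude applied with the given period to a fraction of frames."""

    period_s: float = 0.5
    amplitude: float = 1.5
    affected_fraction: float = 0.1


@dataclass(frozen=True)
class KineticROI:
    """Disk ROI with its true kinetic parameters and baseline intensity."""

    center: Tuple[int, int]
    radius: int
    params: EMMParams
    baseline_intensity: float = 100.0


@dataclass(frozen=True)
class KineticScene:
    shape: Tuple[int, int] = (64, 64)
    rois: Tuple[KineticROI, ...] = ()
    frame_interval_s: float = 1.0
    n_frames: int = 620
    n_baseline: int = 20
    breathing: Optional[BreathingSpec] = None
    noise_sigma: float = 0.0
    seed: int = 0


class TargetBeyondRecordError(ValueError):
    pass


def gaussian_tone_burst(fs_hz, center_hz, bandwidth_frac, n_samples):
    """Gaussian-enveloped tone burst centered in its own window."""
    sigma_f = bandwidth_frac * center_hz / 2.355  # FWHM fraction -> sigma (Hz)
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    half = n_samples // 2
    t = (np.arange(n_samples) - half) / fs_hz
    return np.cos(2 * np.pi * center_hz * t) * np.exp(-0.5 * (t / sigma_t) ** 2)


def make_point_target_stack(
    scene: PointTargetScene,
    geometry: ScanGeometry,
    n_scans: int,
    n_samples: int,
):
    """Simulate an elevational A-scan stack of defocused point targets.

    A target at depth ``l_t`` and elevation ``e_t`` insonifies scan line
    ``i`` (elevation ``i * dz``) only within the hourglass half-width
    ``|i*dz - e_t| <= |l_t - l_f| * w / (2 l_f)``; inside it, a
    Gaussian-windowed tone burst arrives at

        t = (l_f + sign(l_t - l_f) * sqrt((l_t - l_f)^2 + (i*dz - e_t)^2)) / c,

    the virtual-detector delay through the acoustic focus.  Seeded Gaussian
    noise is added last.  Returns the stack and a ground-truth table of
    per-target arrival samples and insonified scan ranges.
    """
    g = geometry
    pulse_len = max(int(round(8 * g.fs_hz / scene.pulse_center_hz)), 32)
    pulse = gaussian_tone_burst(
        g.fs_hz, scene.pulse_center_hz, scene.pulse_bandwidth_frac, pulse_len
    )
    half_p = pulse_len // 2
    data = np.zeros((n_scans, n_samples))
    truth = []
    elevations = np.arange(n_scans) * g.dz_mm
    for tgt in scene.targets:
        dl = tgt.depth_mm - g.lf_mm
        half_width = abs(dl) * g.w_mm / (2 * g.lf_mm)
        # at focus the beam waist still spans at least one scan line
        half_width = max(half_width, g.dz_mm / 2)
        on_axis_t_us = (g.lf_mm + math.copysign(abs(dl), dl)) / g.c_mm_per_us
        on_axis_sample = on_axis_t_us * g.fs_hz * 1e-6
        if not 0 <= on_axis_sample < n_samples - half_p:
            raise TargetBeyondRecordError(
                f"target at depth {tgt.depth_mm} mm arrives at sample "
                f"{on_axis_sample:.0f}, beyond the {n_samples}-sample record"
            )
        insonified = np.abs(elevations - tgt.elevation_mm) <= half_width
        for i in np.nonzero(insonified)[0]:
            de = elevations[i] - tgt.elevation_mm
            r = math.hypot(dl, de)
            t_us = (g.lf_mm + math.copysign(r, dl) if dl != 0 else g.lf_mm) / g.c_mm_per_us
            s = t_us * g.fs_hz * 1e-6
            s0 = int(round(s)) - half_p
            lo, hi = max(s0, 0), min(s0 + pulse_len, n_samples)
            if hi <= lo:
                continue
            data[i, lo:hi] += tgt.amplitude * pulse[lo - s0 : hi - s0]
        truth.append(
            {
                "depth_mm": tgt.depth_mm,
                "elevation_mm": tgt.elevation_mm,
                "arrival_sample": on_axis_sample,
                "scan_lo": int(np.nonzero(insonified)[0][0]),
                "scan_hi": int(np.nonzero(insonified)[0][-1]),
                "half_width_mm": half_width,
            }
        )
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        data += rng.normal(0.0, scene.noise_sigma, size=data.shape)
    return AScanStack(samples=data, geometry=g), truth


def make_kinetic_movie(scene: KineticScene):
    """Simulate a dynamic frame series with model-driven ROI kinetics.

    Each ROI's pixels follow ``baseline * (1 + RE(t)/100)`` with its true
    enhancement-model parameters; background pixels stay at a constant
    baseline.  Breathing artifacts are periodic multiplicative spikes on a
    stated fraction of frames (selection seeded); Gaussian noise is added
    last.  Returns the series, the true curves, and the spiked frame list.
    """
    ny, nx = scene.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    occupied = np.zeros(scene.shape, dtype=bool)
    masks = []
    for roi in scene.rois:
        m = (yy - roi.center[0]) ** 2 + (xx - roi.center[1]) ** 2 <= roi.radius**2
        if not m.any():
            raise ValueError("ROI lies outside the grid")
        if (m & occupied).any():
            raise ValueError("overlapping ROIs with conflicting kinetics")
        occupied |= m
        masks.append(m)

    times = np.arange(scene.n_frames) * scene.frame_interval_s
    t_inject = scene.n_baseline * scene.frame_interval_s
    frames = np.full((scene.n_frames,) + scene.shape, 50.0)
    truths = []
    for roi, m in zip(scene.rois, masks):
        re = emm_evaluate(roi.params, times - t_inject)
        vals = roi.baseline_intensity * (1.0 + re / 100.0)
        frames[:, m] = vals[:, None]
        truths.append({"re_curve": re, "times": times, "mask": m, "params": roi.params})

    rng = np.random.default_rng(scene.seed)
    spiked: List[int] = []
    if scene.breathing is not None:
        b = scene.breathing
        period_frames = max(int(round(b.period_s / scene.frame_interval_s)), 1)
        candidates = np.arange(0, scene.n_frames, period_frames)
        n_spike = int(round(b.affected_fraction * scene.n_frames))
        if n_spike > 0 and candidates.size > 0:
            chosen = rng.choice(
                candidates, size=min(n_spike, candidates.size), replace=False
            )
            for f in np.sort(chosen):
                frames[f] *= b.amplitude
                spiked.append(int(f))
    if scene.noise_sigma > 0:
        frames = frames + rng.normal(0.0, scene.noise_sigma, size=frames.shape)

    series = FrameSeries(
        frames=frames, frame_interval_s=scene.frame_interval_s, pixel_mm=0.1
    )
    return series, truths, spiked


_TISSUE_PRESETS = {
    # literature-typical soft-tissue coefficients (mm^-1); not organ-specific
    "absorbing-slab": "uniform absorber, no scattering",
    "scattering-slab": "uniform scatterer with mild absorption",
    "two-layer": "low-absorbing cap over a higher-absorbing base",
    "disk-inclusion": "scattering background with a high-absorption disk",
}


def make_tissue_map(preset: str, shape: Tuple[int, int] = (60, 120),
                    spacing_mm: float = 0.1) -> TissueModel:
    """Build a labeled optical tissue map from a named preset."""
    if preset not in _TISSUE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_TISSUE_PRESETS)}")
    nx, ny = shape
    labels = np.zeros(shape, dtype=np.int32)
    if preset == "absorbing-slab":
        props = {0: OpticalProperties(mu_a=0.1, mu_s=0.0, g=0.0)}
    elif preset == "scattering-slab":
        props = {0: OpticalProperties(mu_a=0.01, mu_s=10.0, g=0.9)}
    elif preset == "two-layer":
        depth_split = ny // 3
        labels[:, depth_split:] = 1
        props = {
            0: OpticalProperties(mu_a=0.02, mu_s=5.0, g=0.9),
            1: OpticalProperties(mu_a=0.1, mu_s=10.0, g=0.9),
        }
    else:  # disk-inclusion
        a0, a1 = np.mgrid[0:nx, 0:ny]
        disk = (a0 - nx // 2) ** 2 + (a1 - ny // 2) ** 2 <= (min(nx, ny) // 6) ** 2
        labels[disk] = 1
        props = {
            0: OpticalProperties(mu_a=0.01, mu_s=5.0, g=0.9),
            1: OpticalProperties(mu_a=0.5, mu_s=5.0, g=0.9),
        }
    return TissueModel(labels=labels, properties=props, spacing_mm=spacing_mm)


def ring_forward(
    image: np.ndarray,
    ring_radius_mm: float,
    n_elements: int,
    fs_hz: float,
    c_mm_per_us: float,
    pixel_mm: float,
    n_samples: Optional[int] = None,
) -> np.ndarray:
    """Simplified ring-array forward model: per-element circular-arc sums.

    The image grid is centered on the ring center.  Each element's channel
    at sample ``n`` collects the image pixels whose distance from the
    element rounds to ``n * c / f_s`` — a discrete arc integral, linear in
    the image.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_mm
    xs = (np.arange(nx) - (nx - 1) / 2) * pixel_mm
    max_extent = math.hypot(ys[-1] if ny > 1 else 0, xs[-1] if nx > 1 else 0)
    if max_extent >= ring_radius_mm:
        raise ValueError("image extends beyond the detection ring")
    mm_per_sample = c_mm_per_us * 1e6 / fs_hz
    if n_samples is None:
        n_samples = int(math.ceil((ring_radius_mm + max_extent) / mm_per_sample)) + 2
    channels = np.zeros((n_elements, n_samples))
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    angles = 2 * np.pi * np.arange(n_elements) / n_elements
    for e, th in enumerate(angles):
        ex, ey = ring_radius_mm * math.cos(th), ring_radius_mm * math.sin(th)
        dist = np.sqrt((xx - ex) ** 2 + (yy - ey) ** 2)
        bins = np.rint(dist / mm_per_sample).astype(int)
        np.add.at(channels[e], bins.ravel(), img.ravel())
    return channels


def ring_backproject(
    channels: np.ndarray,
    ring_radius_mm: float,
    n_elements: int,
    fs_hz: float,
    c_mm_per_us: float,
    pixel_mm: float,
    grid_shape: Tuple[int, int],
) -> np.ndarray:
    """Single-speed delay-and-sum back-projection onto a centered grid.

    Each pixel sums, over elements, the channel sample at the one-way delay
    corresponding to its element distance (linear interpolation).
    """
    ch = np.asarray(channels, dtype=float)
    if ch.shape[0] != n_elements:
        raise ValueError("channel count does not match n_elements")
    n_samples = ch.shape[1]
    ny, nx = grid_shape
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_mm
    xs = (np.arange(nx) - (nx - 1) / 2) * pixel_mm
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    mm_per_sample = c_mm_per_us * 1e6 / fs_hz
    out = np.zeros(grid_shape)
    angles = 2 * np.pi * np.arange(n_elements) / n_elements
    for e, th in enumerate(angles):
        ex, ey = ring_radius_mm * math.cos(th), ring_radius_mm * math.sin(th)
        s = np.sqrt((xx - ex) ** 2 + (yy - ey) ** 2) / mm_per_sample
        lo = np.clip(np.floor(s).astype(int), 0, n_samples - 2)
        frac = np.clip(s - lo, 0.0, 1.0)
        out += ch[e, lo] * (1 - frac) + ch[e, lo + 1] * frac
    return out
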