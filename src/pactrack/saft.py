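"""Coherence-weighted synthetic-aperture refocusing of elevational scan stacks.

A focused (or virtually focused) ultrasound transducer scanned along the
elevational axis records one A-line per scan position.  A point source at
distance ``l`` from the transducer, away from the acoustic focus at ``l_f``,
radiates into the hourglass-shaped beam and therefore appears — defocused —
in the neighboring scan lines, over an elevational half-extent

    z = (l - l_f) * w / (2 * l_f)

with ``w`` the transducer element height.  Treating the focus as a virtual
point detector, the defocused echoes trace a hyperbola across neighboring
layers: a sample at axial range ``r_i`` from the focus maps in layer ``i+j``
to range ``r_{i+j} = sqrt(r_i**2 + (j*dz)**2)``, giving the inter-layer time
delay

    dt_j = sign(l - l_f) * (r_{i+j} - r_i) / c.

Delay-and-sum over the ``z_s = floor(|z|/dz)`` coherent layers refocuses the
target (SAFT).  A coherence factor

    CF = PA_SAFT**2 / (N * sum_j |PA(i+j, t - dt_j)|**2)

weights down incoherent contributions; with ``N`` the number of terms
actually summed, the Cauchy-Schwarz inequality bounds CF in [0, 1].
Normalizing instead by ``z_s`` (the "layer-count" convention sometimes seen
in print) can exceed 1 on fully coherent signals since ``N = z_s + 1`` terms
enter the sum; both conventions are available via ``cf_norm``.

After refocusing, a complementary zero-phase spectral split separates the
high-frequency (vascular) from the low-frequency (tissue/organ) components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of an elevational scan.

    Attributes
    ----------
    lf_mm : focus-to-transducer distance (mm).
    w_mm : transducer element height (mm).
    dz_mm : elevational step between scans (mm).
    fs_hz : sampling rate (Hz).
    c_mm_per_us : speed of sound in coupling medium (mm/us).
    n0 : sample index at which the focal plane arrives (one-way travel).
    """

    lf_mm: float
    w_mm: float
    dz_mm: float
    fs_hz: float
    c_mm_per_us: float
    n0: float

    def __post_init__(self):
        for name in ("lf_mm", "w_mm", "dz_mm", "fs_hz", "c_mm_per_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")

    @property
    def mm_per_sample(self) -> float:
        """One-way distance covered per time sample (mm)."""
        return self.c_mm_per_us * 1e6 / self.fs_hz


@dataclass(frozen=True)
class AScanStack:
    """2-D stack of A-lines: axis 0 elevation index, axis 1 time sample."""

    samples: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError("samples must be 2-D [elevation x time sample]")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class SAFTResult:
    """Refocused stack, coherence factor, and their product."""

    pa_saft: np.ndarray
    cf: np.ndarray
    pa_cfsaft: np.ndarray


def coherent_half_extent(l_mm: float, geometry: ScanGeometry) -> float:
    """Signed elevational half-extent z of the defocused beam at depth l.

    Positive beyond the focus, negative before it, zero at the focus.
    """
    if l_mm < 0:
        raise ValueError("depth must be >= 0")
    return (l_mm - geometry.lf_mm) * geometry.w_mm / (2.0 * geometry.lf_mm)


def coherent_layers(z_mm: float, dz_mm: float) -> int:
    """Number of coherent layers z_s = floor(|z| / dz)."""
    if dz_mm <= 0:
        raise ValueError("dz must be > 0")
    return int(math.floor(abs(z_mm) / dz_mm))


def target_range(n_i: float, geometry: ScanGeometry) -> float:
    """Axial distance (mm) between sample n_i and the focal point:
    r_i = |(n0 - n_i) / f_s * c|."""
    return abs((geometry.n0 - n_i) / geometry.fs_hz * geometry.c_mm_per_us * 1e6)


def interlayer_delay(
    r_i_mm: float, j: int, geometry: ScanGeometry, defocus_sign: int
) -> float:
    """Time delay (us) of the defocused echo in layer offset j.

    dt_j = sign(l - l_f) * (sqrt(r_i**2 + (j*dz)**2) - r_i) / c.
    """
    if r_i_mm < 0:
        raise ValueError("r_i must be >= 0")
    r_ij = math.hypot(r_i_mm, j * geometry.dz_mm)
    return defocus_sign * (r_ij - r_i_mm) / geometry.c_mm_per_us


def apply_saft(
    stack: AScanStack,
    cf_norm: str = "count",
    interp: str = "linear",
    with_cf: bool = True,
    aperture: str = "full",
) -> SAFTResult:
    """Refocus an elevational stack by coherent delay-and-sum.

    For every output sample ``(i, n)`` the axial range from the focus sets
    the defocus half-extent ``z``, hence ``z_s = floor(|z|/dz)`` coherent
    layers per side; the neighboring A-lines are read at hyperbolically
    delayed times (fractional delays resolved by ``interp``: "linear" or
    "nearest") and summed.  The aperture is truncated, never wrapped, at
    the stack edges.

    ``aperture="full"`` sums ``j`` over ``[-z_s, z_s]`` so the synthetic
    aperture spans the whole insonified extent (the defocused beam spreads
    symmetrically, +/- z, about the target); ``aperture="half"`` sums the
    narrower ``[-z_s/2, z_s/2]`` range, which under-fills the aperture and
    refocuses mildly defocused targets only weakly.

    ``cf_norm="count"`` normalizes the coherence factor by the number of
    terms actually summed (CF in [0, 1]); ``cf_norm="zs"`` uses the layer
    count ``z_s`` and can exceed 1 on coherent signals.  Where ``z_s`` is 0
    the sum has a single term and CF is 1.
    """
    if cf_norm not in ("count", "zs"):
        raise ValueError("cf_norm must be 'count' or 'zs'")
    if interp not in ("linear", "nearest"):
        raise ValueError("interp must be 'linear' or 'nearest'")
    if aperture not in ("full", "half"):
        raise ValueError("aperture must be 'full' or 'half'")
    pa = stack.samples
    g = stack.geometry
    n_scan, n_samp = pa.shape
    ns = np.arange(n_samp)

    # per-sample geometry shared by all scan lines
    r = np.abs(ns - g.n0) * g.mm_per_sample              # range from focus, mm
    z = r * g.w_mm / (2.0 * g.lf_mm)                     # |defocus half-extent|
    zs = np.floor(z / g.dz_mm).astype(int)               # coherent layers
    half = zs if aperture == "full" else zs // 2
    sign = np.sign(ns - g.n0)                            # +1 beyond focus

    pa_sum = np.zeros_like(pa)
    sq_sum = np.zeros_like(pa)
    count = np.zeros_like(pa)
    dz_samp = g.dz_mm / g.mm_per_sample                  # elevational step, samples

    r_samp = np.abs(ns - g.n0).astype(float)
    max_half = int(half.max()) if n_samp else 0
    idx_scan = np.arange(n_scan)[:, None]

    for j in range(-max_half, max_half + 1):
        active = np.abs(j) <= half                       # samples whose aperture includes j
        if not np.any(active):
            continue
        # hyperbolic delay in sample units; aligned neighbor sample index
        r_j = np.sqrt(r_samp**2 + (j * dz_samp) ** 2)
        shift = sign * (r_j - r_samp)
        src = ns + shift                                 # fractional sample in layer i+j
        if interp == "nearest":
            src_n = np.clip(np.rint(src).astype(int), 0, n_samp - 1)
            in_rec = (src >= -0.5) & (src <= n_samp - 0.5)
            vals = pa[:, src_n]
        else:
            lo = np.clip(np.floor(src).astype(int), 0, n_samp - 2)
            frac = np.clip(src - lo, 0.0, 1.0)
            in_rec = (src >= 0) & (src <= n_samp - 1)
            vals = pa[:, lo] * (1 - frac) + pa[:, lo + 1] * frac
        # contribution of layer i+j to output line i (aperture truncated at edges)
        rows = idx_scan[:, 0] + j
        row_valid = (rows >= 0) & (rows < n_scan)
        shifted = np.zeros_like(pa)
        shifted[row_valid, :] = vals[rows[row_valid], :]
        valid = row_valid[:, None] & active[None, :] & in_rec[None, :]
        shifted = np.where(valid, shifted, 0.0)
        pa_sum += shifted
        sq_sum += shifted**2
        count += valid

    if with_cf:
        if cf_norm == "count":
            norm = np.maximum(count, 1)
        else:
            norm = np.maximum(zs[None, :], 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cf = pa_sum**2 / (norm * sq_sum)
        cf = np.where(sq_sum > 0, cf, 1.0)
        single = count <= 1
        cf = np.where(single, 1.0, cf)
    else:
        cf = np.ones_like(pa_sum)
    return SAFTResult(pa_saft=pa_sum, cf=cf, pa_cfsaft=pa_sum * cf)


def band_split(volume: np.ndarray, f_c: float, f_s: float, axis: int = -1):
    """Split a signal into complementary low/high frequency bands.

    Zero-phase rectangular spectral masks along ``axis``; the two bands sum
    exactly back to the input (real FFT round trip).  Used to separate
    low-frequency tissue/organ from high-frequency vascular components.
    """
    if not (0 < f_c < f_s / 2):
        raise ValueError("cutoff must satisfy 0 < f_c < f_s/2")
    x = np.asarray(volume, dtype=float)
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=1.0 / f_s)
    spec = np.fft.rfft(x, axis=axis)
    mask_shape = [1] * x.ndim
    mask_shape[axis] = freqs.size
    low_mask = (freqs <= f_c).reshape(mask_shape)
    low = np.fft.irfft(spec * low_mask, n=n, axis=axis)
    high = x - low
    return low, high


def envelope(signal: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal along the time axis."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    if np.all(x == 0):
        return np.zeros_like(x)
    return np.abs(hilbert(x, axis=axis))


def measure_fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a sampled single-peak profile.

    Linear interpolation locates the half-maximum crossings on each side of
    the (unique) global maximum; raises if a crossing is missing.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError("profile must have a positive maximum")
    i_pk = int(np.argmax(y))
    half = 0.5 * peak

    def cross(idx_range):
        prev = i_pk
        for i in idx_range:
            if y[i] <= half:
                # interpolate between i and prev
                frac = (y[prev] - half) / (y[prev] - y[i])
                return prev + frac * (i - prev)
            prev = i
        raise ValueError("no half-maximum crossing found on one side of the peak")

    left = cross(range(i_pk - 1, -1, -1))
    right = cross(range(i_pk + 1, y.size))
    return (right - left) * spacing
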