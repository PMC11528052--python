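"""Fluence-corrected empirical pharmacokinetic model for contrast clearance.

Photoacoustic (PA) intensity in an organ region of interest tracks the local
concentration of an optically absorbing probe.  After bolus injection the
region's relative enhancement

    RE(t) = 100 * (PA(t) - PA(0)) / PA(0)   [%]

rises as the probe perfuses in and decays as it is cleared.  The time course
is described by an empirical rise-and-decay model

    RE(t) = 0                                               for 0 <= t < t0
    RE(t) = (A / F_ratio) * (1 - exp(-alpha*(t-t0)))**q
                          * exp(-beta*(t-t0))               for t >= t0

where ``A / F_ratio`` is the upper amplitude of enhancement, ``t0`` the rise
time point, ``alpha`` the uptake rate, ``beta`` the excretion rate, ``q`` a
shape exponent controlling the early-uptake slope, and ``F_ratio`` the
post-/pre-injection light-fluence ratio at the location (Monte Carlo derived;
see :mod:`pactrack.fluence`).  ``F_ratio`` is held fixed during fitting.

From the fitted curve the clearance parameters are derived: the time of
maximum enhancement ``T_max``, the elimination half-life ``T_1/2`` (elapsed
time after ``T_max`` at which the curve falls to half its peak), the average
uptake and excretion rates ``U_alpha = 60*alpha`` and ``E_beta = 60*beta``
in min^-1, and the area under the fitted curve over a stated window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize


class InvalidBaselineError(ValueError):
    """Raised when the pre-injection baseline is zero or negative."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested operation."""


class DegenerateInputError(ValueError):
    """Raised when a series carries no usable enhancement signal."""


@dataclass(frozen=True)
class ROITimeCourse:
    """Sampled PA intensity or relative enhancement of one region over time.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing.
    values : array of float
        PA intensity (arbitrary units) when ``kind`` is ``"raw-intensity"``,
        or relative enhancement in percent when ``kind`` is
        ``"relative-enhancement"``.
    baseline_value : float, optional
        Mean pre-injection PA intensity PA(0).  Required (and positive) for
        raw-intensity series.
    kind : {"raw-intensity", "relative-enhancement"}
    """

    times: np.ndarray
    values: np.ndarray
    baseline_value: Optional[float] = None
    kind: Literal["raw-intensity", "relative-enhancement"] = "raw-intensity"
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.kind == "raw-intensity":
            if self.baseline_value is not None and self.baseline_value <= 0:
                raise InvalidBaselineError(
                    "raw-intensity baseline PA(0) must be > 0 when set"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, kind="relative-enhancement", baseline_value=None):
        df = pd.read_csv(path)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise ValueError(f"CSV missing required column {col!r}")
        return cls(
            times=df["time_s"].to_numpy(),
            values=df["value"].to_numpy(),
            baseline_value=baseline_value,
            kind=kind,
        )


@dataclass(frozen=True)
class EMMParams:
    """Parameters of the fluence-corrected enhancement model.

    ``a`` is the uncorrected amplitude in RE percent units; the curve's upper
    amplitude is ``a / f_ratio``.  Rates ``alpha`` (uptake) and ``beta``
    (excretion) are in s^-1; ``q`` is the dimensionless early-uptake shape
    exponent; ``f_ratio`` the dimensionless post/pre fluence ratio.
    """

    a: float
    t0: float
    alpha: float
    beta: float
    q: float
    f_ratio: float = 1.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("amplitude a must be > 0")
        if self.alpha <= 0:
            raise ValueError("uptake rate alpha must be > 0")
        if self.beta < 0:
            raise ValueError("excretion rate beta must be >= 0")
        if self.q <= 0:
            raise ValueError("shape exponent q must be > 0")
        if self.f_ratio <= 0:
            raise ValueError("fluence ratio must be > 0")
        if self.t0 < 0:
            raise ValueError("rise time point t0 must be >= 0")


@dataclass
class EMMFit:
    """Result of a bounded least-squares fit of the enhancement model."""

    params: EMMParams
    residual_sum_of_squares: float
    n_points: int
    converged: bool
    covariance: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        p = self.params
        return {
            "A": p.a,
            "t0_s": p.t0,
            "alpha_per_s": p.alpha,
            "beta_per_s": p.beta,
            "q": p.q,
            "f_ratio": p.f_ratio,
            "converged": bool(self.converged),
            "rss": self.residual_sum_of_squares,
            "n_points": self.n_points,
        }


@dataclass
class ClearanceSummary:
    """Clearance parameters derived from a fitted enhancement curve.

    ``re_max_amplitude`` is the model's upper amplitude ``A/F_ratio``;
    ``re_max_curve`` is the actual maximum of the fitted curve (strictly
    smaller whenever ``beta > 0``).  ``t_half`` is elapsed time after
    ``t_max``; it is ``inf`` when there is no elimination phase
    (``beta == 0``).  Rates are reported in min^-1; ``auc`` integrates the
    fitted curve over ``[0, t_end]`` in %*s.
    """

    re_max_amplitude: float
    re_max_curve: float
    t_max: float
    t_half: float
    u_alpha: float
    e_beta: float
    auc: float
    t_end: float

    def to_dict(self) -> dict:
        return {
            "re_max_amplitude_pct": self.re_max_amplitude,
            "re_max_curve_pct": self.re_max_curve,
            "t_max_s": self.t_max,
            "t_half_s": self.t_half,
            "u_alpha_per_min": self.u_alpha,
            "e_beta_per_min": self.e_beta,
            "auc": self.auc,
            "t_end_s": self.t_end,
        }


def relative_enhancement(raw: ROITimeCourse) -> ROITimeCourse:
    """Convert a raw-intensity time course to relative enhancement in percent.

    RE(t) = 100 * (PA(t) - PA(0)) / PA(0), with PA(0) the stored baseline.
    """
    if raw.kind != "raw-intensity":
        raise ValueError("input must be a raw-intensity time course")
    if raw.baseline_value is None or raw.baseline_value <= 0:
        raise InvalidBaselineError("baseline PA(0) must be > 0")
    re = 100.0 * (raw.values - raw.baseline_value) / raw.baseline_value
    return ROITimeCourse(
        times=raw.times, values=re, kind="relative-enhancement", label=raw.label
    )


def filter_breathing_outliers(
    re: ROITimeCourse, window: int = 11, n_mad: float = 3.0
) -> ROITimeCourse:
    """Remove respiratory spikes with a Hampel filter.

    Each sample is compared with the median of its centered window; samples
    deviating by more than ``n_mad`` times the window's scaled median absolute
    deviation (MAD * 1.4826) are replaced by that median.  Windows are
    truncated at the series edges.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n = len(re)
    if n <= window:
        raise InsufficientDataError(
            f"series of length {n} is too short for window {window}"
        )
    half = window // 2
    x = re.values
    out = x.copy()
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        med = np.median(seg)
        mad = 1.4826 * np.median(np.abs(seg - med))
        if np.abs(x[i] - med) > n_mad * mad:
            out[i] = med
    return ROITimeCourse(
        times=re.times,
        values=out,
        baseline_value=re.baseline_value,
        kind=re.kind,
        label=re.label,
    )


def _emm_curve(t, a, t0, alpha, beta, q, f_ratio):
    dt = t - t0
    with np.errstate(over="ignore"):
        rise = -np.expm1(-alpha * np.maximum(dt, 0.0))
        curve = a / f_ratio * rise**q * np.exp(-beta * np.maximum(dt, 0.0))
    return np.where(dt < 0, 0.0, curve)


def emm_evaluate(params: EMMParams, times) -> np.ndarray:
    """Evaluate the fluence-corrected enhancement model at the given times.

    Zero before the rise time point ``t0``, continuous at ``t0``.
    """
    t = np.asarray(times, dtype=float)
    return _emm_curve(
        t, params.a, params.t0, params.alpha, params.beta, params.q, params.f_ratio
    )


def _initial_guess(t, y, f_ratio):
    ymax = float(np.max(y))
    i_peak = int(np.argmax(y))
    t_peak = t[i_peak]
    # rise point: first time the signal exceeds 5% of peak
    above = np.nonzero(y > 0.05 * ymax)[0]
    t0 = float(t[above[0]]) if above.size else float(t[0])
    # alpha from the 10-90% rise time of the leading edge
    rise_mask = (t >= t0) & (t <= t_peak)
    alpha = 0.1
    if rise_mask.sum() >= 3:
        yr = y[rise_mask]
        tr = t[rise_mask]
        try:
            t10 = tr[np.nonzero(yr >= 0.1 * ymax)[0][0]]
            t90 = tr[np.nonzero(yr >= 0.9 * ymax)[0][0]]
            if t90 > t10:
                alpha = 2.197 / (t90 - t10)  # ln(9) / rise time
        except IndexError:
            pass
    # beta from the log-linear slope of the tail
    tail = t > t_peak + 0.1 * (t[-1] - t_peak)
    beta = 1e-3
    if tail.sum() >= 3 and np.all(y[tail] > 0):
        slope = np.polyfit(t[tail], np.log(y[tail]), 1)[0]
        beta = max(-slope, 1e-6)
    return ymax * f_ratio, t0, alpha, beta, 1.0


def fit_emm(
    re: ROITimeCourse,
    f_ratio: float = 1.0,
    n_starts: int = 5,
    seed: int = 0,
) -> EMMFit:
    """Fit (A, t0, alpha, beta, q) to a relative-enhancement time course.

    Bounded trust-region nonlinear least squares with multi-start: the first
    start uses data-driven initial values (amplitude from the peak, t0 from
    the 5%-of-peak crossing, alpha from the 10-90% rise time, beta from the
    log-linear tail slope, q = 1); remaining starts jitter these initials
    with the seeded generator.  ``f_ratio`` is a known scalar, not fitted.
    """
    if re.kind != "relative-enhancement":
        raise ValueError("fit_emm expects a relative-enhancement time course")
    if len(re) < 8:
        raise InsufficientDataError("need at least 8 samples to fit 5 parameters")
    if f_ratio <= 0:
        raise ValueError("f_ratio must be > 0")
    t = re.times
    y = re.values
    if np.max(np.abs(y)) == 0:
        raise DegenerateInputError("all-zero enhancement series")

    ymax = float(np.max(y))
    if ymax <= 0:
        raise DegenerateInputError("series has no positive enhancement")
    t_peak = float(t[int(np.argmax(y))])
    lb = np.array([1e-9, 0.0, 1e-6, 0.0, 0.1])
    ub = np.array([10.0 * ymax * f_ratio, max(t_peak, t[0] + 1e-9), 100.0, 10.0, 10.0])

    def residuals(p):
        a, t0, alpha, beta, q = p
        return _emm_curve(t, a, t0, alpha, beta, q, f_ratio) - y

    rng = np.random.default_rng(seed)
    x0 = np.clip(np.array(_initial_guess(t, y, f_ratio)), lb, ub)
    best = None
    for k in range(n_starts):
        if k == 0:
            start = x0
        else:
            jitter = rng.uniform(0.5, 2.0, size=5)
            start = np.clip(x0 * jitter, lb, ub)
        try:
            sol = optimize.least_squares(
                residuals, start, bounds=(lb, ub), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    converged = bool(best.success)
    a, t0, alpha, beta, q = best.x
    params = EMMParams(
        a=float(a), t0=float(t0), alpha=float(alpha), beta=float(max(beta, 0.0)),
        q=float(q), f_ratio=float(f_ratio),
    )
    rss = float(2.0 * best.cost)
    cov = None
    try:
        jac = best.jac
        jtj = jac.T @ jac
        dof = max(len(re) - 5, 1)
        cov = np.linalg.pinv(jtj) * rss / dof
    except Exception:
        pass
    return EMMFit(
        params=params,
        residual_sum_of_squares=rss,
        n_points=len(re),
        converged=converged,
        covariance=cov,
    )


def t_max_closed_form(params: EMMParams) -> float:
    """Time of maximum of the fitted curve.

    Setting the derivative of ``(1-exp(-alpha*dt))**q * exp(-beta*dt)`` to
    zero gives ``dt = (1/alpha) * ln((q*alpha + beta) / beta)``; for
    ``beta == 0`` the curve is nondecreasing and the maximum sits at the end
    of the observation window (returned as ``inf`` here, clamped by callers).
    """
    if params.beta == 0:
        return math.inf
    return params.t0 + math.log((params.q * params.alpha + params.beta) / params.beta) / params.alpha


def clearance_summary(fit: EMMFit, t_end: float, raw: ROITimeCourse | None = None,
                      auc_mode: str = "fitted") -> ClearanceSummary:
    """Derive clearance parameters from a fitted enhancement curve.

    ``t_max`` comes from the closed form (clamped to ``t_end``); ``t_half``
    is solved by bisection of the fitted curve on ``(t_max, inf)`` and
    reported as elapsed time after ``t_max`` (``inf`` when ``beta == 0``).
    Rates convert to min^-1.  ``auc`` integrates the fitted curve over
    ``[0, t_end]`` by adaptive quadrature; ``auc_mode="raw"`` instead applies
    the trapezoid rule to the measured series ``raw``.
    """
    if not fit.converged:
        raise ValueError("cannot summarize a non-converged fit")
    p = fit.params
    if t_end <= p.t0:
        raise ValueError("t_end must exceed the rise time point t0")

    t_max = min(t_max_closed_form(p), t_end)
    peak = float(emm_evaluate(p, np.array([t_max]))[0])

    if p.beta == 0:
        t_half = math.inf
    else:
        target = 0.5 * peak

        def f(t):
            return float(emm_evaluate(p, np.array([t]))[0]) - target

        # bracket the half-peak crossing on the decaying side
        hi = t_max + 1.0 / p.beta
        while f(hi) > 0:
            hi = t_max + 2 * (hi - t_max)
        t_cross = optimize.brentq(f, t_max, hi, xtol=1e-9)
        t_half = t_cross - t_max

    if auc_mode == "fitted":
        auc, _ = integrate.quad(
            lambda t: float(emm_evaluate(p, np.array([t]))[0]),
            0.0, t_end, points=[p.t0], limit=200,
        )
    elif auc_mode == "raw":
        if raw is None:
            raise ValueError("auc_mode='raw' requires the measured series")
        mask = raw.times <= t_end
        auc = float(np.trapezoid(raw.values[mask], raw.times[mask]))
    else:
        raise ValueError(f"unknown auc_mode {auc_mode!r}")

    return ClearanceSummary(
        re_max_amplitude=p.a / p.f_ratio,
        re_max_curve=peak,
        t_max=t_max,
        t_half=t_half,
        u_alpha=60.0 * p.alpha,
        e_beta=60.0 * p.beta,
        auc=float(auc),
        t_end=float(t_end),
    )


def summary_to_json(fit: EMMFit, summary: ClearanceSummary, path) -> None:
    """Write fit parameters and clearance summary as one JSON document."""
    doc = {**fit.to_dict(), **summary.to_dict()}
    doc["t_half_s"] = None if math.isinf(doc["t_half_s"]) else doc["t_half_s"]
    Path(path).write_text(json.dumps(doc, indent=2))
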