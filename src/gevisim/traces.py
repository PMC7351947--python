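"""Fluorescence trace processing.

The routines here mirror the standard analysis applied to raw voltage-imaging
traces: an exponential photobleaching fit and correction, ΔF/F₀ relative to a
pre-stimulus window or to a moving-percentile baseline, double-exponential
kinetics fits of step responses, and fluorescence–voltage (F–V) curves from
voltage-clamp step families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .indicator import FluorescenceTrace

__all__ = [
    "BleachFit",
    "DFFTrace",
    "KineticsFit",
    "FVCurve",
    "fit_bleach",
    "compute_dff",
    "dff_from_baseline",
    "moving_percentile_baseline",
    "fit_double_exponential",
    "build_fv_curve",
]


@dataclass(frozen=True)
class BleachFit:
    """Parameters of the exponential bleaching fit ``A * exp(-t/tau) + C``."""

    amplitude: float
    tau: float  # frames; inf when no decay is detectable
    offset: float
    fallback_linear: bool = False  # exponential fit failed; linear detrend used

    def curve(self, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames, dtype=float)
        if np.isinf(self.tau):
            return np.full(n_frames, self.amplitude + self.offset)
        return self.amplitude * np.exp(-t / self.tau) + self.offset


@dataclass
class DFFTrace:
    """Fractional fluorescence change with the baseline that produced it."""

    dff: np.ndarray
    f0: Union[float, np.ndarray]
    frame_rate_hz: float = 400.0
    bleach_params: Optional[BleachFit] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if np.any(np.asarray(self.f0) <= 0):
            raise ValueError("baseline F0 must be positive")

    def __len__(self) -> int:
        return self.dff.size

    def to_fluorescence(self) -> np.ndarray:
        """Invert the ΔF/F transform: F = F0 * (1 + dff)."""
        return np.asarray(self.f0) * (1.0 + self.dff)


@dataclass(frozen=True)
class KineticsFit:
    """Double-exponential fit ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + c``.

    Time constants are in milliseconds with ``tau1 <= tau2``; amplitudes are
    in the units of the fitted trace.  ``residual`` is the RMS misfit.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    offset: float
    direction: str  # "on" or "off"
    residual: float


@dataclass
class FVCurve:
    """Steady-state ΔF/F as a function of clamped membrane voltage."""

    voltages: np.ndarray  # mV, strictly increasing
    dff_means: np.ndarray
    dff_sds: np.ndarray
    slope_sign: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


def _as_array(F) -> Tuple[np.ndarray, float]:
    if isinstance(F, FluorescenceTrace):
        return np.asarray(F.f, dtype=float), F.frame_rate_hz
    return np.asarray(F, dtype=float), 400.0


# ---------------------------------------------------------------------------
# bleaching
# ---------------------------------------------------------------------------


def fit_bleach(F, robust: bool = True) -> Tuple[np.ndarray, BleachFit]:
    """Fit ``A*exp(-t/tau) + C`` to a trace and divide the decay out.

    The corrected trace is ``F / fit * fit[0]``, preserving the initial
    brightness so downstream ΔF/F is unchanged at frame 0 — the standard
    multiplicative model of photobleaching.  A soft-L1 loss keeps sparse
    spikes from biasing the fit.  If the trace carries no measurable decay
    the input is returned unchanged (``tau = inf``); if the nonlinear fit
    fails a linear detrend is used and flagged.
    """
    y, _rate = _as_array(F)
    n = y.size
    if n < 30:
        raise ValueError("trace too short for a meaningful bleach fit (need >= 30 frames)")
    t = np.arange(n, dtype=float)

    scale = np.median(np.abs(y)) or 1.0
    drop = (np.median(y[: n // 10]) - np.median(y[-n // 10 :])) / scale
    if abs(drop) < 1e-3:
        # effectively constant; tau -> inf branch
        fit = BleachFit(amplitude=0.0, tau=np.inf, offset=float(np.median(y)))
        return y.copy(), fit

    def model(p):
        A, log_tau, C = p
        return A * np.exp(-t / np.exp(log_tau)) + C

    def resid(p):
        return model(p) - y

    A0 = y[: max(n // 20, 5)].mean() - y[-max(n // 20, 5) :].mean()
    C0 = y[-max(n // 20, 5) :].mean()
    best = None
    for tau0 in np.exp(np.linspace(np.log(n / 20), np.log(5 * n), 5)):
        try:
            sol = least_squares(
                resid,
                x0=[A0, np.log(tau0), C0],
                loss="soft_l1" if robust else "linear",
                f_scale=max(scale * 0.05, 1e-12),
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not np.isfinite(best.cost):
        # fall back to a linear detrend
        coef = np.polyfit(t, y, 1)
        line = np.polyval(coef, t)
        corrected = y / line * line[0]
        warnings.warn("bleach fit did not converge; using linear detrend", RuntimeWarning)
        fit = BleachFit(amplitude=float(coef[0] * n), tau=np.inf, offset=float(coef[1]), fallback_linear=True)
        return corrected, fit

    A, log_tau, C = best.x
    fit = BleachFit(amplitude=float(A), tau=float(np.exp(log_tau)), offset=float(C))
    curve = fit.curve(n)
    if np.any(curve <= 0):
        coef = np.polyfit(t, y, 1)
        line = np.polyval(coef, t)
        corrected = y / line * line[0]
        warnings.warn("bleach fit crossed zero; using linear detrend", RuntimeWarning)
        return corrected, BleachFit(float(coef[0] * n), np.inf, float(coef[1]), fallback_linear=True)
    corrected = y / curve * curve[0]
    return corrected, fit


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------


def compute_dff(F, baseline_window) -> DFFTrace:
    """ΔF/F₀ against a scalar baseline averaged over a frame window.

    ``baseline_window`` is either an integer (the first N frames, e.g. one
    second prior to stimulation) or a ``(start, stop)`` frame pair.
    """
    y, rate = _as_array(F)
    if isinstance(baseline_window, (int, np.integer)):
        start, stop = 0, int(baseline_window)
    else:
        start, stop = map(int, baseline_window)
    if not (0 <= start < stop <= y.size):
        raise ValueError(f"baseline window [{start}, {stop}) not contained in trace of length {y.size}")
    f0 = float(y[start:stop].mean())
    if f0 <= 0:
        raise ValueError("baseline mean F0 must be positive (check background subtraction)")
    return DFFTrace(dff=(y - f0) / f0, f0=f0, frame_rate_hz=rate)


def dff_from_baseline(F, f0: np.ndarray) -> DFFTrace:
    """ΔF/F with a per-frame baseline (e.g. from a moving percentile)."""
    y, rate = _as_array(F)
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != y.shape:
        raise ValueError("baseline must match the trace shape")
    if np.any(f0 <= 0):
        raise ValueError("per-frame baseline must be positive everywhere")
    return DFFTrace(dff=(y - f0) / f0, f0=f0, frame_rate_hz=rate)


def moving_percentile_baseline(
    F,
    window_s: float = 1.0,
    percentile: float = 10.0,
    side: str = "bottom",
    frame_rate_hz: Optional[float] = None,
) -> np.ndarray:
    """Centered moving-window percentile baseline.

    ``side="bottom"`` tracks the resting level of a positive-going indicator
    (spikes rise above baseline); ``side="top"`` does the same for a
    negative-going one.  Windows are truncated at the trace edges.
    """
    y, rate = _as_array(F)
    if frame_rate_hz is not None:
        rate = frame_rate_hz
    if side not in ("bottom", "top"):
        raise ValueError("side must be 'bottom' or 'top'")
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    w = int(round(window_s * rate))
    if w < 10:
        raise ValueError("window must span at least 10 samples")
    if w > y.size:
        raise ValueError(f"window of {w} frames exceeds trace length {y.size}")
    q = percentile if side == "bottom" else 100.0 - percentile

    half = w // 2
    n = y.size
    out = np.empty(n)
    # interior: strided windows, one percentile call
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        interior = np.percentile(sliding_window_view(y, w), q, axis=1)
        out[half : half + interior.size] = interior
    # truncated edges
    for i in range(half):
        out[i] = np.percentile(y[: i + half + 1], q)
    for i in range(half + (n - w + 1) if n >= w else 0, n):
        out[i] = np.percentile(y[i - half :], q)
    return out


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def fit_double_exponential(
    y,
    t_ms: Optional[np.ndarray] = None,
    t0: int = 0,
    frame_rate_hz: float = 3200.0,
    direction: str = "on",
    n_starts: int = 5,
) -> KineticsFit:
    """Fit ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + c`` to a step response.

    ``y`` may be a :class:`DFFTrace`, a :class:`FluorescenceTrace` or a bare
    array; fitting starts at frame ``t0`` (the step onset).  Times are in
    milliseconds.  Initialization is multi-start over log-spaced pairs of
    time constants; the best-residual solution is kept and its time constants
    returned in increasing order.  Genuinely single-exponential data come
    back with one amplitude near zero rather than an error.
    """
    if isinstance(y, DFFTrace):
        arr = y.dff
        frame_rate_hz = y.frame_rate_hz
    elif isinstance(y, FluorescenceTrace):
        arr = y.f
        frame_rate_hz = y.frame_rate_hz
    else:
        arr = np.asarray(y, dtype=float)
    arr = arr[t0:]
    if t_ms is None:
        t_ms = np.arange(arr.size) * 1000.0 / frame_rate_hz
    else:
        t_ms = np.asarray(t_ms, dtype=float)[: arr.size]
    if arr.size < 8:
        raise ValueError("step response too short to fit two exponentials")

    span = t_ms[-1] - t_ms[0] or 1.0
    total_amp = arr[0] - arr[-1]
    c0 = arr[-1]

    def model(p, t):
        a1, lt1, a2, lt2, c = p
        return a1 * np.exp(-t / np.exp(lt1)) + a2 * np.exp(-t / np.exp(lt2)) + c

    def resid(p):
        return model(p, t_ms) - arr

    taus = np.exp(np.linspace(np.log(span / 200.0), np.log(span), n_starts))
    best = None
    for i in range(n_starts):
        for j in range(i + 1, n_starts):
            x0 = [0.6 * total_amp, np.log(taus[i]), 0.4 * total_amp, np.log(taus[j]), c0]
            try:
                sol = least_squares(resid, x0=x0, max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("double-exponential fit failed to converge from any start")

    a1, lt1, a2, lt2, c = best.x
    tau1, tau2 = np.exp(lt1), np.exp(lt2)
    if tau1 > tau2:
        a1, a2 = a2, a1
        tau1, tau2 = tau2, tau1
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return KineticsFit(
        a1=float(a1), tau1=float(tau1), a2=float(a2), tau2=float(tau2),
        offset=float(c), direction=direction, residual=rms,
    )


# ---------------------------------------------------------------------------
# F–V curves
# ---------------------------------------------------------------------------


def build_fv_curve(step_dffs: Sequence[Tuple[float, Union[DFFTrace, np.ndarray, float]]],
                   steady_frac: float = 0.5) -> FVCurve:
    """Fluorescence–voltage curve from a family of voltage-step responses.

    Each entry pairs a clamped voltage (mV) with the ΔF/F response to that
    step; the steady state is taken as the mean over the final
    ``steady_frac`` of each trace.  Duplicate voltages are averaged.  The
    slope sign comes from a least-squares line through the points.
    """
    if len(step_dffs) < 2:
        raise ValueError("need at least two voltage steps")
    by_v: dict = {}
    for v, resp in step_dffs:
        if isinstance(resp, DFFTrace):
            arr = resp.dff
        else:
            arr = np.atleast_1d(np.asarray(resp, dtype=float))
        tail = arr[int(len(arr) * (1.0 - steady_frac)):] if arr.size > 1 else arr
        by_v.setdefault(float(v), []).append(tail)
    voltages = np.array(sorted(by_v))
    if voltages.size < 2:
        raise ValueError("need at least two distinct voltages")
    means = np.array([np.mean(np.concatenate(by_v[v])) for v in voltages])
    sds = np.array([np.std(np.concatenate(by_v[v])) for v in voltages])
    slope = np.polyfit(voltages, means, 1)[0]
    return FVCurve(
        voltages=voltages,
        dff_means=means,
        dff_sds=sds,
        slope_sign="positive" if slope >= 0 else "negative",
    )
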