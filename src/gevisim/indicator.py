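"""Voltage-to-fluorescence conversion for positive- and negative-going indicators.

An eFRET voltage indicator is summarized here by the two brightness levels it
visits during an action potential, ``F_min`` and ``F_max``, and its polarity.
For a positive-going indicator the resting membrane potential maps to ``F_min``
and the mean spike height to ``F_max``; a negative-going indicator is the
mirror image (bright at rest, dim at the spike peak).  Sensitivity is the
fractional response ``ΔF/F_min = (F_max - F_min) / F_min``.  Holding ``F_max``
fixed while varying ``F_min`` models a dye ligand with a fixed maximum
brightness whose dynamic range is set by the rhodopsin quencher.

The map from normalized voltage (0 = rest, 1 = mean spike height) to
fluorescence is linear — rhodopsin eFRET responses are fast and linear over
the physiological range — with optional first-order on/off kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "IndicatorParams",
    "FluorescenceTrace",
    "params_from_sensitivity",
    "voltage_to_fluorescence",
]

_POLARITIES = ("positive", "negative")


@dataclass(frozen=True)
class IndicatorParams:
    """Static description of one indicator.

    Parameters
    ----------
    polarity : {"positive", "negative"}
        Sign of the fluorescence change on depolarization.
    F_max, F_min : float
        Upper and lower bounds of the noiseless fluorescence trace, in
        arbitrary intensity counts; ``0 < F_min < F_max``.
    tau_on, tau_off : float, optional
        First-order response time constants in seconds.  When either is set,
        :func:`voltage_to_fluorescence` applies an asymmetric single-pole
        low-pass to the voltage before the range mapping.  Off by default:
        the simulated indicators respond within a frame at 400 Hz.
    """

    polarity: str
    F_max: float
    F_min: float
    tau_on: Optional[float] = None
    tau_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}, got {self.polarity!r}")
        if not (0.0 < self.F_min < self.F_max):
            raise ValueError(
                f"require 0 < F_min < F_max, got F_min={self.F_min}, F_max={self.F_max}"
            )
        for name in ("tau_on", "tau_off"):
            tau = getattr(self, name)
            if tau is not None and tau <= 0:
                raise ValueError(f"{name} must be positive when set, got {tau}")

    @property
    def sensitivity(self) -> float:
        """Fractional response per action potential, ΔF/F_min."""
        return (self.F_max - self.F_min) / self.F_min

    @property
    def has_kinetics(self) -> bool:
        return self.tau_on is not None or self.tau_off is not None


@dataclass
class FluorescenceTrace:
    """Per-frame fluorescence intensity with its sampling rate."""

    f: np.ndarray
    frame_rate_hz: float = 400.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1:
            raise ValueError("fluorescence trace must be 1-D")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    def __len__(self) -> int:
        return self.f.size


def params_from_sensitivity(
    polarity: str,
    F_max: float,
    sensitivity: float,
    tau_on: Optional[float] = None,
    tau_off: Optional[float] = None,
) -> IndicatorParams:
    """Build indicator parameters from a target sensitivity at fixed ``F_max``.

    ``F_min`` is chosen so that ``(F_max - F_min) / F_min == sensitivity``,
    i.e. ``F_min = F_max / (1 + sensitivity)``.  This is how the sensitivity
    axis of the polarity sweep is realized: the maximum brightness of the dye
    is held fixed and the resting level moves.
    """
    if F_max <= 0:
        raise ValueError(f"F_max must be positive, got {F_max}")
    if sensitivity <= 0:
        raise ValueError(f"sensitivity must be positive, got {sensitivity}")
    F_min = F_max / (1.0 + sensitivity)
    return IndicatorParams(
        polarity=polarity, F_max=F_max, F_min=F_min, tau_on=tau_on, tau_off=tau_off
    )


def _kinetics_filter(v: np.ndarray, frame_rate_hz: float, tau_on: float, tau_off: float) -> np.ndarray:
    """Asymmetric single-pole low-pass: tau_on on rising input, tau_off falling."""
    dt = 1.0 / frame_rate_hz
    a_on = 1.0 - np.exp(-dt / tau_on) if tau_on > 0 else 1.0
    a_off = 1.0 - np.exp(-dt / tau_off) if tau_off > 0 else 1.0
    out = np.empty_like(v)
    state = v[0]
    out[0] = state
    for i in range(1, v.size):
        a = a_on if v[i] > state else a_off
        state += a * (v[i] - state)
        out[i] = state
    return out


def voltage_to_fluorescence(
    v,
    params: IndicatorParams,
    frame_rate_hz: Optional[float] = None,
    clip: str = "none",
) -> FluorescenceTrace:
    """Convert a normalized voltage trace into an indicator fluorescence trace.

    Positive polarity maps rest (v=0) to ``F_min`` and the mean spike height
    (v=1) to ``F_max``; negative polarity swaps the two.

    Parameters
    ----------
    v : VoltageTrace or array-like
        Normalized activity (0 = rest, 1 = mean spike height).  A
        :class:`~gevisim.synth.VoltageTrace` provides its own frame rate.
    params : IndicatorParams
    frame_rate_hz : float, optional
        Required when ``v`` is a bare array and kinetics filtering is on.
    clip : {"none", "range"}
        How to treat subthreshold overshoot beyond the spike dynamic range.
        ``"none"`` (default) keeps the map linear — the sensor responds
        linearly over the physiological range, and subthreshold excursions
        are small.  ``"range"`` hard-saturates at ``[F_min, F_max]``; note
        that at rest this rectifies subthreshold fluctuations into one-sided
        bumps, which downstream event detectors can mistake for small spikes.
        Fluorescence is never allowed below zero in either mode.
    """
    if clip not in ("none", "range"):
        raise ValueError("clip must be 'none' or 'range'")
    rate = frame_rate_hz
    arr = v
    if hasattr(v, "v"):  # VoltageTrace duck-typing
        arr = v.v
        if rate is None:
            rate = v.spikes.frame_rate_hz
    arr = np.asarray(arr, dtype=float)
    if rate is None:
        rate = 400.0

    if params.has_kinetics:
        tau_on = params.tau_on or params.tau_off
        tau_off = params.tau_off or params.tau_on
        arr = _kinetics_filter(arr, rate, tau_on, tau_off)

    span = params.F_max - params.F_min
    if params.polarity == "positive":
        f = params.F_min + arr * span
    else:
        f = params.F_max - arr * span
    if clip == "range":
        np.clip(f, params.F_min, params.F_max, out=f)
    else:
        np.clip(f, 0.0, None, out=f)
    return FluorescenceTrace(f=f, frame_rate_hz=rate)
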