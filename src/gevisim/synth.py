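"""Ground-truthed synthetic voltage-imaging data.

This module generates everything a benchmarking run needs: per-neuron
spike trains and normalized "voltage traces", compact spatial footprints for
in-focus somata, blurred footprints with temporally shuffled spiking for
out-of-focus background neurons, and assembled fluorescence movies with
photobleaching and pixel noise.

Statistical structure of the default recording:

* spikes: Poisson-like point process with an absolute refractory period,
  calibrated so the expected count equals ``mean_spikes`` (100 per 40,000
  frames at 400 Hz by default, i.e. tonic ~1 Hz firing);
* action potential waveform: 2-frame linear rise to unit peak followed by an
  exponential decay (tau = 3 frames at 400 Hz); overlapping waveforms collapse
  by pointwise maximum, never summation;
* subthreshold activity: Ornstein–Uhlenbeck fluctuation, default SD 0.05 of
  the spike height with a 100 ms correlation time;
* bleaching: shared single-exponential curve ``exp(-t / tau_bleach)``, a
  parametric stand-in for an empirically measured dye bleaching curve;
* noise: per-pixel Gaussian, either with SD proportional to the instantaneous
  pixel signal (the default, emulating illumination/shot-type noise) or with
  a constant SD (a control that removes the brightness dependence).

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .indicator import FluorescenceTrace, IndicatorParams, voltage_to_fluorescence

__all__ = [
    "SpikeTrain",
    "VoltageTrace",
    "SpatialFootprint",
    "SimulatedRecording",
    "generate_spike_train",
    "generate_voltage_trace",
    "generate_footprint",
    "generate_background_neurons",
    "bleach_curve",
    "assemble_recording",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted ground-truth spike frame indices at a given frame rate."""

    frames: np.ndarray
    frame_rate_hz: float
    duration_frames: int

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        object.__setattr__(self, "frames", frames)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.duration_frames <= 0:
            raise ValueError("duration_frames must be positive")
        if frames.size:
            if np.any(np.diff(frames) <= 0):
                raise ValueError("spike frames must be strictly increasing")
            if frames[0] < 0 or frames[-1] >= self.duration_frames:
                raise ValueError("spike frames must lie in [0, duration_frames)")

    def __len__(self) -> int:
        return self.frames.size

    def shifted(self, offset: int) -> "SpikeTrain":
        """Circularly shift all spike times by ``offset`` frames."""
        frames = np.sort((self.frames + offset) % self.duration_frames)
        return SpikeTrain(frames, self.frame_rate_hz, self.duration_frames)


@dataclass
class VoltageTrace:
    """Normalized membrane-potential proxy: 0 at rest, 1 at mean spike height."""

    v: np.ndarray
    spikes: SpikeTrain
    duration_frames: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1 or self.v.size != self.duration_frames:
            raise ValueError("voltage trace length must equal duration_frames")


@dataclass
class SpatialFootprint:
    """Non-negative 2-D weight map of one neuron's pixels."""

    weights: np.ndarray
    centroid: Tuple[float, float]
    in_focus: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("footprint weights must be 2-D")
        if np.any(self.weights < 0):
            raise ValueError("footprint weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("footprint must have positive total weight")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.weights.shape

    def second_moment(self) -> float:
        """Trace of the spatial covariance of the weight map (px^2)."""
        w = self.weights / self.weights.sum()
        rr, cc = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
        r0 = (rr * w).sum()
        c0 = (cc * w).sum()
        return float(((rr - r0) ** 2 * w).sum() + ((cc - c0) ** 2 * w).sum())


@dataclass
class SimulatedRecording:
    """A movie plus everything needed to score spike detection against truth."""

    movie: np.ndarray  # T x H x W
    neurons: List[Tuple[VoltageTrace, SpatialFootprint, IndicatorParams]]
    background_neurons: List[Tuple[VoltageTrace, SpatialFootprint, IndicatorParams]]
    bleach_curve: np.ndarray
    noise_coeff: float
    seed: int
    frame_rate_hz: float = 400.0
    noise_model: str = "proportional"
    background_offset: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.movie.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.movie.shape[1:]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def generate_spike_train(
    duration_frames: int,
    frame_rate_hz: float,
    mean_spikes: float,
    refractory_frames: int = 4,
    seed: int = 0,
) -> SpikeTrain:
    """Sample a refractory Poisson spike train with a calibrated mean count.

    Inter-spike intervals are ``refractory_frames`` plus a geometric waiting
    time whose success probability is chosen so the mean interval equals
    ``duration_frames / mean_spikes``; the expected number of spikes per
    recording therefore equals ``mean_spikes`` up to boundary effects.
    """
    if duration_frames <= 0:
        raise ValueError("duration_frames must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if mean_spikes < 0:
        raise ValueError("mean_spikes must be non-negative")
    if refractory_frames < 1:
        raise ValueError("refractory_frames must be >= 1")
    if duration_frames <= refractory_frames:
        raise ValueError("duration_frames must exceed refractory_frames")

    if mean_spikes == 0:
        return SpikeTrain(np.empty(0, dtype=int), frame_rate_hz, duration_frames)

    mean_isi = duration_frames / mean_spikes
    if mean_isi <= refractory_frames:
        raise ValueError(
            f"mean_spikes={mean_spikes} is unattainable with a {refractory_frames}-frame "
            f"refractory period over {duration_frames} frames"
        )
    p = 1.0 / (mean_isi - refractory_frames)
    p = min(p, 1.0)

    rng = _rng(seed)
    # draw a comfortable surplus of intervals, then keep what fits
    n_draw = int(mean_spikes + 6 * np.sqrt(mean_spikes + 1) + 8)
    frames: List[int] = []
    # first spike: plain geometric wait from frame 0 (no preceding spike)
    t = int(rng.geometric(p)) - 1
    while True:
        while frames.__len__() < n_draw and t < duration_frames:
            frames.append(t)
            t += refractory_frames + int(rng.geometric(p))
        if t >= duration_frames:
            break
        n_draw *= 2
    return SpikeTrain(np.asarray(frames, dtype=int), frame_rate_hz, duration_frames)


def spike_waveform(rise_frames: int = 2, decay_tau_frames: float = 3.0, tail_eps: float = 0.01) -> np.ndarray:
    """Stereotyped unit-peak action-potential waveform.

    Linear rise over ``rise_frames`` frames to 1, then exponential decay with
    time constant ``decay_tau_frames``, truncated once below ``tail_eps``.
    The returned array's peak index is ``rise_frames``.
    """
    rise = np.linspace(0.0, 1.0, rise_frames + 1)[1:]  # exclude the 0 at rest
    n_tail = int(np.ceil(-decay_tau_frames * np.log(tail_eps)))
    tail = np.exp(-np.arange(1, n_tail + 1) / decay_tau_frames)
    tail = tail[tail >= tail_eps]
    w = np.concatenate([[0.0], rise, tail])
    return w


def generate_voltage_trace(
    spikes: SpikeTrain,
    ap_width_frames: int = 5,
    subthreshold_sd: float = 0.05,
    subthreshold_tau_frames: float = 40.0,
    seed: int = 0,
) -> VoltageTrace:
    """Render spikes into a normalized voltage trace with subthreshold noise.

    ``ap_width_frames`` is split into a fixed 2-frame rise and an exponential
    decay with time constant ``ap_width_frames - 2`` frames.  Waveforms of
    spikes closer than the waveform support are collapsed by pointwise
    maximum, so the peak amplitude of merged events stays 1.  Subthreshold
    activity is an Ornstein–Uhlenbeck process with stationary SD
    ``subthreshold_sd`` and correlation time ``subthreshold_tau_frames``.
    """
    if ap_width_frames < 1:
        raise ValueError("ap_width_frames must be >= 1")
    if subthreshold_sd < 0:
        raise ValueError("subthreshold_sd must be non-negative")

    T = spikes.duration_frames
    rise = min(2, ap_width_frames - 1) if ap_width_frames > 1 else 0
    decay_tau = max(ap_width_frames - rise, 1)
    w = spike_waveform(rise_frames=max(rise, 1), decay_tau_frames=float(decay_tau))
    peak = max(rise, 1)

    v = np.zeros(T)
    for s in spikes.frames:
        lo = s - peak
        hi = lo + w.size
        wlo = max(0, -lo)
        whi = w.size - max(0, hi - T)
        lo = max(lo, 0)
        hi = min(hi, T)
        np.maximum(v[lo:hi], w[wlo:whi], out=v[lo:hi])

    if subthreshold_sd > 0:
        rng = _rng(seed)
        tau = max(subthreshold_tau_frames, 1e-6)
        rho = np.exp(-1.0 / tau)
        innov_sd = subthreshold_sd * np.sqrt(1.0 - rho**2)
        eps = rng.normal(0.0, 1.0, size=T)
        ou = np.empty(T)
        ou[0] = subthreshold_sd * eps[0]
        for t in range(1, T):
            ou[t] = rho * ou[t - 1] + innov_sd * eps[t]
        v = v + ou

    return VoltageTrace(v=v, spikes=spikes, duration_frames=T)


def generate_footprint(
    shape: Tuple[int, int],
    centroid: Tuple[float, float],
    radius_px: float = 3.0,
    seed: int = 0,
) -> SpatialFootprint:
    """Isotropic Gaussian soma-like footprint, normalized to unit total weight.

    ``radius_px`` is interpreted as two Gaussian standard deviations (the
    visually apparent soma radius).  The ``seed`` argument is accepted for
    interface uniformity; the default footprint is deterministic.
    """
    H, W = shape
    r0, c0 = centroid
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError(f"centroid {centroid} lies outside frame {shape}")
    sigma = radius_px / 2.0
    rr, cc = np.mgrid[0:H, 0:W]
    w = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))
    w[w < 1e-10] = 0.0
    w /= w.sum()
    return SpatialFootprint(weights=w, centroid=(float(r0), float(c0)), in_focus=True)


def generate_background_neurons(
    target: SpatialFootprint,
    target_spikes: SpikeTrain,
    n_background: int = 5,
    blur_px: float = 6.0,
    seed: int = 0,
    max_shift_frac: float = 0.35,
    **voltage_kwargs,
) -> List[Tuple[VoltageTrace, SpatialFootprint]]:
    """Out-of-focus companions of one in-focus neuron.

    Each background neuron reuses the target's footprint, displaced to a
    random nearby centroid and blurred with a Gaussian of SD ``blur_px``
    (optical defocus), and fires the target's spike train circularly shifted
    by an independent random offset ("temporally shuffled": the count and the
    inter-spike-interval structure are preserved, the timing correlation with
    the target is destroyed).  Each gets its own subthreshold noise.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    if blur_px <= 0:
        raise ValueError("blur_px must be positive")
    if n_background == 0:
        return []

    H, W = target.shape
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_background)
    out: List[Tuple[VoltageTrace, SpatialFootprint]] = []
    T = target_spikes.duration_frames
    for child in children:
        rng = np.random.default_rng(child)
        dr = int(rng.integers(-int(max_shift_frac * H), int(max_shift_frac * H) + 1))
        dc = int(rng.integers(-int(max_shift_frac * W), int(max_shift_frac * W) + 1))
        shifted = np.zeros_like(target.weights)
        src_r = slice(max(0, -dr), min(H, H - dr))
        src_c = slice(max(0, -dc), min(W, W - dc))
        dst_r = slice(max(0, dr), min(H, H + dr))
        dst_c = slice(max(0, dc), min(W, W + dc))
        shifted[dst_r, dst_c] = target.weights[src_r, src_c]
        if shifted.sum() <= 0:  # shifted fully out of frame; keep in place
            shifted = target.weights.copy()
            dr = dc = 0
        blurred = ndimage.gaussian_filter(shifted, sigma=blur_px, mode="constant")
        blurred /= blurred.sum()
        fp = SpatialFootprint(
            weights=blurred,
            centroid=(target.centroid[0] + dr, target.centroid[1] + dc),
            in_focus=False,
        )
        if T > 1:
            offset = int(rng.integers(1, T))
        else:
            offset = 0
        spikes = target_spikes.shifted(offset)
        vseed = int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
        vt = generate_voltage_trace(spikes, seed=vseed, **voltage_kwargs)
        out.append((vt, fp))
    return out


def bleach_curve(n_frames: int, tau_frames: float) -> np.ndarray:
    """Single-exponential photobleaching multiplier, 1 at frame 0.

    ``tau_frames = inf`` disables bleaching.
    """
    if tau_frames <= 0:
        raise ValueError("bleach tau must be positive (use inf for no bleaching)")
    t = np.arange(n_frames, dtype=float)
    if np.isinf(tau_frames):
        return np.ones(n_frames)
    return np.exp(-t / tau_frames)


def assemble_recording(
    neurons: Sequence[Tuple[VoltageTrace, SpatialFootprint]],
    background_neurons: Sequence[Tuple[VoltageTrace, SpatialFootprint]],
    indicator: IndicatorParams,
    bleach_tau_frames: float = np.inf,
    noise_coeff: float = 0.0,
    seed: int = 0,
    noise_model: str = "proportional",
    background_offset: float = 0.0,
    dtype=np.float32,
) -> SimulatedRecording:
    """Render neurons into a T x H x W fluorescence movie.

    Each neuron's voltage trace is converted to an indicator fluorescence
    trace, multiplied by the shared bleaching curve, and spread over its
    spatial footprint; contributions are summed and a constant background
    offset added.  Pixel noise is then drawn per frame: Gaussian with SD
    ``noise_coeff * signal`` (``noise_model="proportional"``) or with constant
    SD ``noise_coeff`` in the same intensity counts
    (``noise_model="additive"``).  Negative pixels are clipped to zero.
    """
    if noise_model not in ("proportional", "additive"):
        raise ValueError("noise_model must be 'proportional' or 'additive'")
    if noise_coeff < 0:
        raise ValueError("noise_coeff must be non-negative")
    if background_offset < 0:
        raise ValueError("background_offset must be non-negative")

    all_units = list(neurons) + list(background_neurons)
    if not all_units:
        raise ValueError("at least one neuron is required")
    T = all_units[0][0].duration_frames
    shape = all_units[0][1].shape
    for vt, fp in all_units:
        if vt.duration_frames != T:
            raise ValueError("all voltage traces must have the same length")
        if fp.shape != shape:
            raise ValueError("all footprints must share the frame shape")

    bleach = bleach_curve(T, bleach_tau_frames)

    n_units = len(all_units)
    F = np.empty((n_units, T))
    W = np.empty((n_units, shape[0] * shape[1]))
    for i, (vt, fp) in enumerate(all_units):
        F[i] = voltage_to_fluorescence(vt, indicator).f * bleach
        W[i] = fp.weights.ravel()

    signal = F.T @ W  # T x P
    if background_offset:
        signal += background_offset

    rng = _rng(seed)
    if noise_coeff > 0:
        noise = rng.normal(0.0, 1.0, size=signal.shape)
        if noise_model == "proportional":
            noise *= noise_coeff * signal
        else:
            noise *= noise_coeff
        movie = signal + noise
    else:
        movie = signal
    np.clip(movie, 0.0, None, out=movie)
    movie = movie.reshape(T, *shape).astype(dtype)

    frame_rate = all_units[0][0].spikes.frame_rate_hz
    in_focus = [(vt, fp, indicator) for vt, fp in neurons]
    out_focus = [(vt, fp, indicator) for vt, fp in background_neurons]
    return SimulatedRecording(
        movie=movie,
        neurons=in_focus,
        background_neurons=out_focus,
        bleach_curve=bleach,
        noise_coeff=noise_coeff,
        seed=seed,
        frame_rate_hz=frame_rate,
        noise_model=noise_model,
        background_offset=background_offset,
    )
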