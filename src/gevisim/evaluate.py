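"""Scoring of inferred spike trains and the polarity comparison sweep.

Spike inference is scored as the intersection-over-union (IoU) of binary
per-frame spike labels at the imaging rate, without binning; the error rate is
``1 - IoU``.  The sweep simulates recordings over a grid of labeling
densities (number of in-focus neurons, each with proportional out-of-focus
background neurons, in a fixed field of view), indicator sensitivities and
both polarities, runs the end-to-end movie detector, and aggregates per-cell
error rates.  Two headline summaries are derived from the sweep:

* :func:`matched_density_ratio` — by how much denser can labeling be with the
  positive-going indicator at the same spike-detection error rate;
* :func:`fidelity_ratio` — the ratio of detection fidelity (1 - error by
  default; mean event z-score as the alternative) between polarities at the
  densest grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import detect_from_movie
from .indicator import params_from_sensitivity
from .synth import (
    SimulatedRecording,
    SpikeTrain,
    assemble_recording,
    generate_background_neurons,
    generate_footprint,
    generate_spike_train,
    generate_voltage_trace,
)

__all__ = [
    "EvaluationResult",
    "SweepResult",
    "SimConfigLike",
    "spike_iou",
    "simulate_scene",
    "run_sweep",
    "matched_density_ratio",
    "fidelity_ratio",
    "FidelityRatio",
]


@dataclass(frozen=True)
class EvaluationResult:
    """IoU-based agreement between a ground-truth and an inferred spike train."""

    iou: float
    n_true: int
    n_inferred: int
    n_intersect: int
    mean_event_z: float = float("nan")

    @property
    def error_rate(self) -> float:
        return 1.0 - self.iou


def spike_iou(truth: SpikeTrain, inferred: SpikeTrain, tolerance_frames: int = 0,
              scores: Optional[np.ndarray] = None) -> EvaluationResult:
    """Intersection-over-union of binary per-frame spike labels.

    With ``tolerance_frames == 0`` (the default, matching scoring at the
    imaging rate without binning) the intersection is the number of exactly
    shared frames.  With a positive tolerance, true and inferred spikes are
    first greedily matched nearest-first within the tolerance, each spike
    matching at most once.  Two empty trains agree perfectly (IoU = 1).
    """
    if truth.frame_rate_hz != inferred.frame_rate_hz:
        raise ValueError("spike trains must share a frame rate")
    t = np.asarray(truth.frames, dtype=int)
    i = np.asarray(inferred.frames, dtype=int)
    if t.size == 0 and i.size == 0:
        return EvaluationResult(iou=1.0, n_true=0, n_inferred=0, n_intersect=0,
                                mean_event_z=float(np.mean(scores)) if scores is not None and len(scores) else float("nan"))
    if tolerance_frames == 0:
        n_int = np.intersect1d(t, i).size
    else:
        pairs = [
            (abs(int(tf) - int(inf)), ti, ii)
            for ti, tf in enumerate(t)
            for ii, inf in enumerate(i)
            if abs(int(tf) - int(inf)) <= tolerance_frames
        ]
        pairs.sort()
        used_t: set = set()
        used_i: set = set()
        n_int = 0
        for _d, ti, ii in pairs:
            if ti in used_t or ii in used_i:
                continue
            used_t.add(ti)
            used_i.add(ii)
            n_int += 1
    union = t.size + i.size - n_int
    iou = n_int / union if union else 1.0
    mean_z = float(np.mean(scores)) if scores is not None and len(scores) else float("nan")
    return EvaluationResult(iou=float(iou), n_true=int(t.size), n_inferred=int(i.size),
                            n_intersect=int(n_int), mean_event_z=mean_z)


# ---------------------------------------------------------------------------
# scene construction and sweep
# ---------------------------------------------------------------------------


@dataclass
class SimConfigLike:
    """Simulation parameters shared by every cell of a sweep.

    Defaults reproduce the reference recording conditions: 400 Hz imaging,
    a mean of 100 spikes per 40,000-frame recording (the sweep passes reduced
    sizes explicitly), 5 out-of-focus background neurons per in-focus neuron,
    and noise with SD proportional to the pixel signal.
    """

    n_frames: int = 40_000
    frame_rate_hz: float = 400.0
    mean_spikes: float = 100.0
    refractory_frames: int = 4
    ap_width_frames: int = 5
    subthreshold_sd: float = 0.05
    subthreshold_tau_frames: float = 40.0
    fov: Tuple[int, int] = (40, 40)
    footprint_radius_px: float = 3.0
    blur_px: float = 6.0
    n_background_per_target: int = 5
    F_max: float = 100.0
    bleach_tau_frames: float = 10_000.0
    noise_coeff: float = 0.35
    noise_model: str = "proportional"
    background_offset: float = 0.0
    # detection
    threshold: float = 5.0
    min_separation: int = 4
    n_iter: int = 3
    baseline_window_s: float = 1.0
    baseline_percentile: float = 10.0
    # evaluation
    tolerance_frames: int = 0
    n_eval_targets: int = 2


def _target_centroids(n: int, fov: Tuple[int, int], rng: np.random.Generator,
                      margin: float = 5.0, min_dist: float = 7.0) -> List[Tuple[float, float]]:
    """Random in-focus soma positions with a minimum pairwise distance.

    Relaxes the distance constraint if the field is too crowded to satisfy it.
    """
    H, W = fov
    centroids: List[Tuple[float, float]] = []
    dist = min_dist
    attempts = 0
    while len(centroids) < n:
        cand = (margin + rng.random() * (H - 2 * margin), margin + rng.random() * (W - 2 * margin))
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= dist**2 for c in centroids):
            centroids.append(cand)
        attempts += 1
        if attempts > 200 * n:
            dist *= 0.8
            attempts = 0
    return centroids


def simulate_scene(
    density: int,
    sensitivity: float,
    polarity: str,
    cfg: SimConfigLike,
    seed: int,
) -> SimulatedRecording:
    """One recording of ``density`` in-focus neurons plus their background."""
    ss = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(ss.spawn(1)[0])
    centroids = _target_centroids(density, cfg.fov, place_rng)
    indicator = params_from_sensitivity(polarity, cfg.F_max, sensitivity)

    neuron_seeds = ss.spawn(density + 1)  # last one for assembly noise
    neurons = []
    backgrounds = []
    for k in range(density):
        child = neuron_seeds[k]
        s_spk, s_v, s_bg = (int(c.generate_state(1, dtype=np.uint32)[0] >> 1) for c in child.spawn(3))
        spikes = generate_spike_train(
            cfg.n_frames, cfg.frame_rate_hz, cfg.mean_spikes, cfg.refractory_frames, seed=s_spk
        )
        vt = generate_voltage_trace(
            spikes,
            ap_width_frames=cfg.ap_width_frames,
            subthreshold_sd=cfg.subthreshold_sd,
            subthreshold_tau_frames=cfg.subthreshold_tau_frames,
            seed=s_v,
        )
        fp = generate_footprint(cfg.fov, centroids[k], cfg.footprint_radius_px)
        neurons.append((vt, fp))
        backgrounds.extend(
            generate_background_neurons(
                fp,
                spikes,
                n_background=cfg.n_background_per_target,
                blur_px=cfg.blur_px,
                seed=s_bg,
                ap_width_frames=cfg.ap_width_frames,
                subthreshold_sd=cfg.subthreshold_sd,
                subthreshold_tau_frames=cfg.subthreshold_tau_frames,
            )
        )
    noise_seed = int(neuron_seeds[-1].generate_state(1, dtype=np.uint32)[0] >> 1)
    return assemble_recording(
        neurons,
        backgrounds,
        indicator,
        bleach_tau_frames=cfg.bleach_tau_frames,
        noise_coeff=cfg.noise_coeff,
        seed=noise_seed,
        noise_model=cfg.noise_model,
        background_offset=cfg.background_offset,
    )


@dataclass
class SweepResult:
    """Tidy per-(cell, replicate, neuron) records of a polarity sweep."""

    records: pd.DataFrame

    def cell_means(self) -> pd.DataFrame:
        """Mean error per grid cell: replicate-level means averaged over seeds."""
        per_rep = (
            self.records.dropna(subset=["error_rate"])
            .groupby(["polarity", "sensitivity", "density", "rep"], as_index=False)
            .agg(error_rate=("error_rate", "mean"), mean_event_z=("mean_event_z", "mean"))
        )
        return per_rep.groupby(["polarity", "sensitivity", "density"], as_index=False).agg(
            error_rate=("error_rate", "mean"),
            error_sd=("error_rate", "std"),
            mean_event_z=("mean_event_z", "mean"),
            n_reps=("rep", "nunique"),
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(records=pd.read_csv(path))

    def plot_error_curves(self, sensitivity: Optional[float] = None, ax=None):
        """Error rate vs density, one line per (polarity, sensitivity)."""
        import matplotlib.pyplot as plt

        means = self.cell_means()
        if sensitivity is not None:
            means = means[np.isclose(means["sensitivity"], sensitivity)]
        if ax is None:
            _fig, ax = plt.subplots()
        for (pol, sens), grp in means.groupby(["polarity", "sensitivity"]):
            grp = grp.sort_values("density")
            ax.errorbar(grp["density"], grp["error_rate"], yerr=grp["error_sd"],
                        marker="o", label=f"{pol}, ΔF/F_min={sens:g}")
        ax.set_xscale("log", base=2)
        ax.set_xlabel("labeled-neuron density (in-focus neurons per field)")
        ax.set_ylabel("spike detection error (1 − IoU)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def run_sweep(
    densities: Sequence[int],
    sensitivities: Sequence[float],
    polarities: Sequence[str] = ("positive", "negative"),
    n_reps: int = 20,
    sim_config: Optional[SimConfigLike] = None,
    base_seed: int = 0,
    progress: bool = False,
) -> SweepResult:
    """Simulate and score every (polarity, sensitivity, density, replicate) cell.

    Per-cell seeds derive deterministically from ``base_seed`` and the cell's
    grid coordinates, so replicates are independent and the whole sweep is
    reproducible bit-for-bit.  Detection runs on the first
    ``sim_config.n_eval_targets`` in-focus neurons of each recording (every
    in-focus neuron is statistically equivalent; scoring a fixed number keeps
    the cost of dense cells bounded).  Failures inside a cell are recorded as
    NaN rows, not raised.
    """
    if not densities or not sensitivities or not polarities:
        raise ValueError("all sweep grids must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = sim_config or SimConfigLike()

    rows = []
    for ip, polarity in enumerate(polarities):
        for isens, sens in enumerate(sensitivities):
            for idens, density in enumerate(densities):
                for rep in range(n_reps):
                    ss = np.random.SeedSequence(base_seed, spawn_key=(ip, isens, idens, rep))
                    seed = int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)
                    try:
                        rec = simulate_scene(density, sens, polarity, cfg, seed)
                        n_eval = min(density, cfg.n_eval_targets)
                        for k in range(n_eval):
                            vt, fp, _ind = rec.neurons[k]
                            det = detect_from_movie(
                                rec,
                                fp,
                                polarity=polarity,
                                baseline_window_s=cfg.baseline_window_s,
                                baseline_percentile=cfg.baseline_percentile,
                                threshold=cfg.threshold,
                                min_separation=cfg.min_separation,
                                n_iter=cfg.n_iter,
                            )
                            inferred = SpikeTrain(det.spike_frames, cfg.frame_rate_hz, cfg.n_frames)
                            ev = spike_iou(vt.spikes, inferred, cfg.tolerance_frames, scores=det.scores)
                            rows.append(dict(
                                polarity=polarity, sensitivity=sens, density=density,
                                rep=rep, seed=seed, neuron=k,
                                iou=ev.iou, error_rate=ev.error_rate,
                                n_true=ev.n_true, n_inferred=ev.n_inferred,
                                n_intersect=ev.n_intersect, mean_event_z=ev.mean_event_z,
                                failure="",
                            ))
                    except Exception as exc:  # per-cell failures are data, not fatal
                        rows.append(dict(
                            polarity=polarity, sensitivity=sens, density=density,
                            rep=rep, seed=seed, neuron=-1,
                            iou=np.nan, error_rate=np.nan, n_true=0, n_inferred=0,
                            n_intersect=0, mean_event_z=np.nan, failure=repr(exc),
                        ))
                if progress:
                    print(f"sweep: polarity={polarity} sensitivity={sens} density={density} done", flush=True)
    return SweepResult(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# headline summaries
# ---------------------------------------------------------------------------


def _crossing_density(densities: np.ndarray, errors: np.ndarray, target: float,
                      log_density: bool = True) -> float:
    """Density at which the (monotone-enforced) error curve crosses ``target``."""
    order = np.argsort(densities)
    d = np.asarray(densities, dtype=float)[order]
    e = np.maximum.accumulate(np.asarray(errors, dtype=float)[order])  # enforce monotone
    if target < e[0] or target > e[-1]:
        raise ValueError(
            f"error target {target} outside the achievable range [{e[0]:.3f}, {e[-1]:.3f}] "
            f"over densities {d[0]:g}..{d[-1]:g}"
        )
    x = np.log(d) if log_density else d
    c = float(np.interp(target, e, x))
    return float(np.exp(c)) if log_density else c


def matched_density_ratio(
    sweep: SweepResult,
    sensitivity_lo: float,
    sensitivity_hi: float,
    error_target: float = 0.5,
    log_density: bool = True,
    allow_censored: bool = False,
) -> float:
    """Fold-increase in labeling density afforded by the positive polarity.

    Interpolates each polarity's mean error-vs-density curve at
    ``sensitivity_hi`` (log-density interpolation by default) and returns
    ``density(positive) / density(negative)`` at ``error_target``.  The sweep
    must contain both polarities at both sensitivities.  If the positive
    curve never reaches the target inside the swept range the ratio is
    undefined; with ``allow_censored=True`` the largest swept density is
    substituted, making the result a lower bound.
    """
    means = sweep.cell_means()
    for s in (sensitivity_lo, sensitivity_hi):
        for pol in ("positive", "negative"):
            if means[np.isclose(means["sensitivity"], s) & (means["polarity"] == pol)].empty:
                raise ValueError(f"sweep lacks polarity={pol} at sensitivity={s}")

    hi = means[np.isclose(means["sensitivity"], sensitivity_hi)]
    crossings = {}
    for pol in ("positive", "negative"):
        grp = hi[hi["polarity"] == pol].sort_values("density")
        try:
            crossings[pol] = _crossing_density(
                grp["density"].to_numpy(), grp["error_rate"].to_numpy(), error_target, log_density
            )
        except ValueError:
            if allow_censored:
                e = np.maximum.accumulate(grp["error_rate"].to_numpy())
                if error_target > e[-1]:  # curve never gets this bad: censor high
                    crossings[pol] = float(grp["density"].max())
                else:  # curve starts above target: censor low
                    crossings[pol] = float(grp["density"].min())
            else:
                raise
    return crossings["positive"] / crossings["negative"]


class FidelityRatio(NamedTuple):
    ratio: float
    positive: float
    negative: float
    definition: str
    infinite: bool


def fidelity_ratio(
    sweep: SweepResult,
    density_hi: int,
    sensitivity_hi: float,
    definition: str = "one_minus_error",
) -> FidelityRatio:
    """Positive/negative spike-detection fidelity ratio at one grid cell.

    ``definition="one_minus_error"`` (default) uses fidelity = 1 − (1 − IoU);
    ``definition="mean_event_z"`` uses the mean event z-score of detected
    spikes instead.  A zero denominator is reported as infinite and flagged.
    """
    if definition not in ("one_minus_error", "mean_event_z"):
        raise ValueError("definition must be 'one_minus_error' or 'mean_event_z'")
    means = sweep.cell_means()
    cell = means[np.isclose(means["sensitivity"], sensitivity_hi) & (means["density"] == density_hi)]
    vals = {}
    for pol in ("positive", "negative"):
        row = cell[cell["polarity"] == pol]
        if row.empty:
            raise ValueError(f"sweep lacks polarity={pol} at density={density_hi}, sensitivity={sensitivity_hi}")
        if definition == "one_minus_error":
            vals[pol] = float(1.0 - row["error_rate"].iloc[0])
        else:
            vals[pol] = float(row["mean_event_z"].iloc[0])
    if vals["negative"] == 0:
        return FidelityRatio(float("inf"), vals["positive"], vals["negative"], definition, True)
    return FidelityRatio(vals["positive"] / vals["negative"], vals["positive"], vals["negative"], definition, False)
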