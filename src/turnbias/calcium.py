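"""Fluorescence-trace normalization and responder classification.

Raw per-neuron intensity traces over repeated light/dark trials are first
averaged across trials and normalized to dF/F = (F_t - F0) / F0, where F0
is the mean intensity over the first baseline (light) period.  A neuron is
a *responder* when its dF/F exceeds three baseline standard deviations (3S,
with S the sd of dF/F over the same baseline period) on at least three
successive frames.  Responders are split by where the qualifying excursion
begins: in a dark epoch -> light-OFF responder; in a light epoch that
follows a dark epoch -> light-ON responder; anywhere else -> "none".
Timing metrics (peak, latency, time to half-max with linear interpolation)
are measured from the stimulus transition that defines the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DffTrace",
    "ResponderCall",
    "compute_dff",
    "classify_responder",
    "response_timing",
    "cohort_response_summary",
    "classify_cohort",
    "find_first_run",
]

SIGMA_MULTIPLE = 3.0  # responder threshold in baseline standard deviations
MIN_RUN_FRAMES = 3    # successive supra-threshold frames required


@dataclass
class DffTrace:
    """Normalized trace for one neuron (trial-averaged unless stated)."""

    neuron_id: object
    dff: np.ndarray = field(repr=False)
    epoch_labels: np.ndarray = field(repr=False)
    f0: float = math.nan
    s: float = math.nan          # baseline sd of dF/F
    frame_rate_hz: float = 1.0
    n_trials_averaged: int = 1


@dataclass
class ResponderCall:
    """Classification and timing for one neuron."""

    neuron_id: object
    cls: str                     # "OFF", "ON", or "none"
    onset_frame: int = -1        # first frame of the qualifying run (-1: none)
    peak_dff: float = math.nan
    latency_s: float = math.nan
    time_to_half_max_s: float = math.nan
    returned_within_30s: bool = False
    degenerate_baseline: bool = False  # S == 0 on a nonconstant trace


def _baseline_slice(epoch_labels: np.ndarray) -> np.ndarray:
    """Frame indices of the first light epoch (the baseline period)."""
    light = np.flatnonzero(np.asarray(epoch_labels) == "light")
    if light.size == 0:
        raise ValueError("trace has no light epoch to use as baseline")
    first = light[0]
    run_end = first
    while run_end + 1 < len(epoch_labels) and epoch_labels[run_end + 1] == "light":
        run_end += 1
    return np.arange(first, run_end + 1)


def compute_dff(
    intensities,
    epoch_labels,
    neuron_id=None,
    frame_rate_hz: float = 0.96,
    average_trials: bool = True,
) -> DffTrace:
    """Normalize a raw trace to dF/F against the first-light-epoch baseline.

    Parameters
    ----------
    intensities : 1-D array (single trial) or 2-D array of shape
        (n_trials, n_frames); with ``average_trials`` the trials are
        averaged frame-wise before normalization.
    epoch_labels : per-frame "light"/"dark" labels (one trial's worth).

    F0 is the mean raw intensity over the baseline frames and must be
    positive; S is the standard deviation (ddof=1) of dF/F over the same
    frames.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    labels = np.asarray(epoch_labels)
    if arr.shape[1] != labels.size:
        raise ValueError(
            f"epoch labels ({labels.size}) do not match frame count ({arr.shape[1]})"
        )
    trace = arr.mean(axis=0) if average_trials else arr[0]
    base = _baseline_slice(labels)
    f0 = float(trace[base].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean F0 must be positive, got {f0}")
    dff = (trace - f0) / f0
    s = float(dff[base].std(ddof=1)) if base.size > 1 else 0.0
    return DffTrace(
        neuron_id=neuron_id,
        dff=dff,
        epoch_labels=labels,
        f0=f0,
        s=s,
        frame_rate_hz=frame_rate_hz,
        n_trials_averaged=arr.shape[0] if average_trials else 1,
    )


def find_first_run(mask, min_len: int = MIN_RUN_FRAMES) -> int:
    """Index of the first run of at least ``min_len`` consecutive True, or -1."""
    m = np.asarray(mask, dtype=bool)
    run = 0
    for i, v in enumerate(m):
        run = run + 1 if v else 0
        if run >= min_len:
            return i - min_len + 1
    return -1


def classify_responder(
    dff: DffTrace,
    sigma_multiple: float = SIGMA_MULTIPLE,
    min_run: int = MIN_RUN_FRAMES,
) -> ResponderCall:
    """Apply the 3S / three-successive-frames responder criterion.

    The onset is the first frame of the earliest run of ``min_run``
    consecutive frames with dF/F > ``sigma_multiple * S``.  The class is
    OFF when the onset lies in a dark epoch, ON when it lies in a light
    epoch that follows a dark epoch, and "none" otherwise (including the
    no-run case).  A zero baseline sd on a nonconstant trace leaves the
    rule defined (threshold 0) but flags the call as degenerate.
    """
    threshold = sigma_multiple * dff.s
    degenerate = dff.s == 0.0 and not np.allclose(dff.dff, 0.0)
    onset = find_first_run(dff.dff > threshold, min_run)
    if onset < 0:
        return ResponderCall(dff.neuron_id, "none", degenerate_baseline=degenerate)

    labels = dff.epoch_labels
    if labels[onset] == "dark":
        cls = "OFF"
    elif labels[onset] == "light" and "dark" in set(labels[:onset]):
        cls = "ON"
    else:
        cls = "none"  # excursion inside the baseline epoch itself
    return ResponderCall(
        dff.neuron_id, cls, onset_frame=onset, degenerate_baseline=degenerate
    )


def _stimulus_frame(dff: DffTrace, cls: str) -> int:
    """Frame of the epoch transition that defines an OFF or ON response."""
    labels = dff.epoch_labels
    prev = labels[:-1]
    nxt = labels[1:]
    if cls == "OFF":
        hits = np.flatnonzero((prev == "light") & (nxt == "dark")) + 1
    else:
        hits = np.flatnonzero((prev == "dark") & (nxt == "light")) + 1
    if hits.size == 0:
        raise ValueError(f"no stimulus transition for class {cls}")
    return int(hits[0])


def response_timing(
    dff: DffTrace,
    call: ResponderCall,
    stimulus_frame: int | None = None,
    return_window_s: float = 30.0,
) -> ResponderCall:
    """Fill in peak, latency, and time-to-half-max for a responder call.

    The peak is the maximum dF/F within the epoch initiated by the stimulus
    transition; latency is onset minus stimulus; time to half-max is the
    time from the stimulus to the first post-peak crossing of peak/2, with
    linear interpolation between the bracketing frames.  A trace that never
    falls back to half-max leaves the time NaN and
    ``returned_within_30s = False``.
    """
    if call.cls not in ("OFF", "ON"):
        raise ValueError("timing metrics are defined only for responders")
    if stimulus_frame is None:
        stimulus_frame = _stimulus_frame(dff, call.cls)
    dt = 1.0 / dff.frame_rate_hz
    labels = dff.epoch_labels
    epoch_label = labels[stimulus_frame]
    end = stimulus_frame
    while end + 1 < labels.size and labels[end + 1] == epoch_label:
        end += 1
    window = dff.dff[stimulus_frame : end + 1]
    peak_idx = int(np.argmax(window)) + stimulus_frame
    peak = float(dff.dff[peak_idx])
    half = peak / 2.0

    t_half = math.nan
    returned = False
    post = dff.dff[peak_idx:]
    below = np.flatnonzero(post <= half)
    if below.size:
        j = int(below[0])  # first post-peak frame at or below half-max
        if j == 0:
            t_cross = peak_idx * dt
        else:
            prev_v, cur_v = post[j - 1], post[j]
            frac = (prev_v - half) / (prev_v - cur_v) if prev_v != cur_v else 1.0
            t_cross = (peak_idx + j - 1 + frac) * dt
        t_half = t_cross - stimulus_frame * dt
        returned = t_half <= return_window_s

    call.peak_dff = peak
    call.latency_s = (call.onset_frame - stimulus_frame) * dt
    call.time_to_half_max_s = t_half
    call.returned_within_30s = returned
    return call


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


def cohort_response_summary(calls: list[ResponderCall]) -> dict:
    """Cohort-level responder fractions and the OFF return-within-30-s rate.

    Fractions are over all neurons; the return fraction is over OFF
    responders only.  Percentages are rounded half-up to one decimal, with
    raw counts retained so either rounding convention is recomputable.
    """
    if not calls:
        raise ValueError("at least one responder call is required")
    n = len(calls)
    n_off = sum(1 for c in calls if c.cls == "OFF")
    n_on = sum(1 for c in calls if c.cls == "ON")
    off_returned = sum(1 for c in calls if c.cls == "OFF" and c.returned_within_30s)
    times = [
        c.time_to_half_max_s
        for c in calls
        if c.cls == "OFF" and not math.isnan(c.time_to_half_max_s)
    ]
    return {
        "n_neurons": n,
        "n_off": n_off,
        "n_on": n_on,
        "n_none": n - n_off - n_on,
        "frac_off": n_off / n,
        "frac_on": n_on / n,
        "pct_off": _round_half_up(100.0 * n_off / n),
        "pct_on": _round_half_up(100.0 * n_on / n),
        "n_off_returned_30s": off_returned,
        "frac_off_returned_30s": off_returned / n_off if n_off else 0.0,
        "mean_time_to_half_max_s": float(np.mean(times)) if times else math.nan,
        "sd_time_to_half_max_s": float(np.std(times, ddof=1)) if len(times) > 1 else math.nan,
    }


def classify_cohort(
    traces: pd.DataFrame,
    epochs: pd.DataFrame,
    frame_rate_hz: float = 0.96,
    average_trials: bool = True,
    with_timing: bool = True,
) -> pd.DataFrame:
    """Classify every neuron in long-format trace/epoch tables.

    ``traces`` has columns ``neuron_id, trial, frame, intensity`` and
    ``epochs`` has ``trial, frame, label``; all trials of one neuron must
    share the epoch plan of trial 1.  Returns one row per neuron with the
    call fields of :class:`ResponderCall`.
    """
    required = {"neuron_id", "trial", "frame", "intensity"}
    if missing := required - set(traces.columns):
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    if missing := {"trial", "frame", "label"} - set(epochs.columns):
        raise ValueError(f"epoch table is missing columns: {sorted(missing)}")

    first_trial = epochs["trial"].min()
    labels = (
        epochs[epochs["trial"] == first_trial].sort_values("frame")["label"].to_numpy()
    )
    rows = []
    for neuron_id, ndf in traces.groupby("neuron_id", sort=True):
        mat = (
            ndf.pivot_table(index="trial", columns="frame", values="intensity")
            .sort_index()
            .to_numpy()
        )
        if mat.shape[1] != labels.size:
            raise ValueError(
                f"neuron {neuron_id}: {mat.shape[1]} frames do not align with "
                f"{labels.size} epoch labels"
            )
        dff = compute_dff(
            mat, labels, neuron_id=neuron_id,
            frame_rate_hz=frame_rate_hz, average_trials=average_trials,
        )
        call = classify_responder(dff)
        if with_timing and call.cls in ("OFF", "ON"):
            call = response_timing(dff, call)
        rows.append(
            {
                "neuron_id": neuron_id,
                "class": call.cls,
                "onset_frame": call.onset_frame,
                "peak_dff": call.peak_dff,
                "latency_s": call.latency_s,
                "time_to_half_max_s": call.time_to_half_max_s,
                "returned_within_30s": call.returned_within_30s,
                "degenerate_baseline": call.degenerate_baseline,
                "f0": dff.f0,
                "baseline_sd": dff.s,
            }
        )
    return pd.DataFrame(rows)
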