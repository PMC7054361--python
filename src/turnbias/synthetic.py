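"""Seeded synthetic cohorts with known ground truth.

Three generators stand in for raw tracking and imaging data:

* :func:`generate_turn_cohort` — per-larva routine-turn sequences over a
  four-trial protocol.  Each larva has a latent preferred direction; the
  first turn of every trial goes to the preferred side with probability
  ``bias_strength`` (0.5 = unbiased), and each subsequent turn repeats the
  previous direction with probability ``lock_prob`` (the Markov persistence
  the lock index encodes).  With ``bias_strength = 0.5`` the generator is
  exactly the unbiased null chain used by the Monte-Carlo test.

* :func:`generate_heading_series` — a time-stamped signed heading-change
  series for one 30-s trajectory window, with optional tracking dropouts.

* :func:`generate_calcium_cohort` — per-neuron fluorescence traces over
  repeated light/dark trials at ~0.96 Hz, with planted light-OFF and
  light-ON responders built from a linear-rise / exponential-decay kernel.

All generators derive per-larva (or per-neuron) random substreams from the
master seed, so enlarging a cohort leaves already-generated individuals
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "TraceConfig",
    "generate_turn_cohort",
    "generate_heading_series",
    "generate_calcium_cohort",
]

TRIAL_DURATION_S = 10.0  # kinematic recording window per light-off trial


def _substream(seed: int, n: int) -> list[np.random.Generator]:
    """n child generators of a master seed, stable under growth of n."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic routine-turn cohort.

    ``turn_count_model`` is either ``("fixed", k)`` or ``("poisson", lam)``;
    Poisson draws are truncated from below at ``min_turns`` (re-draw), so
    every generated larva passes the at-least-``min_turns``-per-trial
    analysis filter by construction when the Poisson model is used.
    """

    n_larvae: int
    trials_per_larva: int = 4
    turn_count_model: tuple = ("poisson", 8.0)
    min_turns: int = 3
    bias_strength: float = 0.5       # P(first turn toward preferred side)
    preferred_dir_prob: float = 0.5  # P(a larva is right-preferring)
    lock_prob: float = 0.814         # P(turn repeats the previous direction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae < 1 or self.trials_per_larva < 1:
            raise ValueError("n_larvae and trials_per_larva must be >= 1")
        if self.min_turns < 1:
            raise ValueError("min_turns must be >= 1")
        if not 0.5 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0.5, 1]")
        for name in ("preferred_dir_prob", "lock_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        kind = self.turn_count_model[0]
        if kind == "fixed":
            if int(self.turn_count_model[1]) < self.min_turns:
                raise ValueError("fixed turn count must be >= min_turns")
        elif kind == "poisson":
            if float(self.turn_count_model[1]) <= 0:
                raise ValueError("Poisson mean must be positive")
        else:
            raise ValueError(f"unknown turn_count_model {kind!r}")


def _draw_counts(rng: np.random.Generator, model: tuple, min_turns: int, size: int) -> np.ndarray:
    kind = model[0]
    if kind == "fixed":
        return np.full(size, int(model[1]), dtype=np.int64)
    counts = rng.poisson(float(model[1]), size=size)
    while np.any(counts < min_turns):  # truncate from below by re-draw
        short = counts < min_turns
        counts[short] = rng.poisson(float(model[1]), size=int(short.sum()))
    return counts


def generate_turn_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a routine-turn event table plus its ground truth.

    Returns
    -------
    turns : DataFrame with columns ``larva_id, trial, event_index,
        direction, time_s`` (direction +1 rightward / -1 leftward; event
        times uniform over the 10-s trial window).
    ground_truth : DataFrame with one row per larva — its latent preferred
        direction, realized %rightward (recomputable exactly from the
        emitted table), and per-trial turn counts.
    """
    rows_turns = []
    rows_truth = []
    for i, rng in enumerate(_substream(config.seed, config.n_larvae)):
        preferred = 1 if rng.random() < config.preferred_dir_prob else -1
        counts = _draw_counts(
            rng, config.turn_count_model, config.min_turns, config.trials_per_larva
        )
        pct_trials = []
        for trial, k in enumerate(counts, start=1):
            first_toward_pref = rng.random() < config.bias_strength
            d = preferred if first_toward_pref else -preferred
            dirs = np.empty(k, dtype=np.int64)
            dirs[0] = d
            repeats = rng.random(k - 1) < config.lock_prob
            for j in range(1, k):
                d = d if repeats[j - 1] else -d
                dirs[j] = d
            times = np.sort(rng.uniform(0.0, TRIAL_DURATION_S, size=k))
            for j in range(k):
                rows_turns.append(
                    (f"larva_{i:04d}", trial, j, int(dirs[j]), float(times[j]))
                )
            pct_trials.append(100.0 * float((dirs == 1).sum()) / k)
        rows_truth.append(
            {
                "larva_id": f"larva_{i:04d}",
                "preferred_dir": preferred,
                "mean_pct_rightward": float(np.mean(pct_trials)),
                **{f"n_turns_{t+1}": int(c) for t, c in enumerate(counts)},
            }
        )
    turns = pd.DataFrame(
        rows_turns, columns=["larva_id", "trial", "event_index", "direction", "time_s"]
    )
    return turns, pd.DataFrame(rows_truth)


def generate_heading_series(
    duration_s: float = 30.0,
    rate_hz: float = 10.0,
    mean_dtheta: float = 0.0,
    sd_dtheta: float = 12.0,
    dropouts: list[tuple[float, float]] = (),
    seed=None,
) -> pd.DataFrame:
    """Generate one heading-change time series with optional dropouts.

    Samples are taken at ``rate_hz`` over ``[0, duration_s)``; each sample's
    signed angular change is Gaussian with the given mean and sd (degrees,
    rightward positive).  ``dropouts`` is a list of ``(start_s, end_s)``
    intervals during which tracking is lost and no samples are emitted.
    Returns a DataFrame with columns ``time_s`` and ``dtheta_deg``.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and sample rate must be positive")
    if sd_dtheta < 0:
        raise ValueError("sd_dtheta must be non-negative")
    for lo, hi in dropouts:
        if not (0.0 <= lo < hi <= duration_s):
            raise ValueError(f"dropout interval ({lo}, {hi}) outside [0, {duration_s}]")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s, 1.0 / rate_hz)
    times = times[times < duration_s]
    changes = rng.normal(mean_dtheta, sd_dtheta, size=times.size)
    keep = np.ones(times.size, dtype=bool)
    for lo, hi in dropouts:
        keep &= ~((times >= lo) & (times < hi))
    return pd.DataFrame({"time_s": times[keep], "dtheta_deg": changes[keep]})


@dataclass
class TraceConfig:
    """Study-design parameters for a synthetic calcium-imaging cohort.

    The epoch plan is an ordered list of ``(label, duration_s)`` with labels
    in {"light", "dark"}; the default single light->dark cycle matches a
    60 s light / 60 s dark trial imaged at ~0.96 Hz (~115 frames).  Planted
    OFF responders fire at the first light->dark transition and ON
    responders at the first dark->light transition (so a plan with a final
    light epoch, e.g. light/dark/light, is needed when ``frac_on > 0``).
    The response kernel rises linearly over ``rise_frames`` frames to
    ``peak_dff`` (in dF/F units of the baseline) and decays exponentially
    with time constant ``decay_tau_s``.
    """

    n_neurons: int
    frame_rate_hz: float = 0.96
    epoch_plan: tuple = (("light", 60.0), ("dark", 60.0))
    n_trials: int = 3
    frac_off: float = 0.15
    frac_on: float = 0.0
    peak_dff: float = 1.0
    rise_frames: int = 2
    decay_tau_s: float = 30.0
    noise_sd: float = 2.0       # raw-intensity units
    baseline: float = 100.0     # raw-intensity units (F_base)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("n_neurons and n_trials must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if any(dur <= 0 for _, dur in self.epoch_plan):
            raise ValueError("epoch durations must be positive")
        if any(label not in ("light", "dark") for label, _ in self.epoch_plan):
            raise ValueError("epoch labels must be 'light' or 'dark'")
        if self.frac_off < 0 or self.frac_on < 0 or self.frac_off + self.frac_on > 1:
            raise ValueError("responder fractions must be >= 0 and sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.baseline <= 0 or self.peak_dff <= 0:
            raise ValueError("baseline and peak amplitude must be positive")
        if self.rise_frames < 1 or self.decay_tau_s <= 0:
            raise ValueError("rise_frames must be >= 1 and decay_tau_s positive")


def _epoch_frames(config: TraceConfig) -> tuple[np.ndarray, dict]:
    """Per-frame epoch labels and the frame index of each transition."""
    total = sum(dur for _, dur in config.epoch_plan)
    n_frames = int(math.floor(total * config.frame_rate_hz))
    t = np.arange(n_frames) / config.frame_rate_hz
    labels = np.empty(n_frames, dtype=object)
    transitions = {}
    t0 = 0.0
    prev_label = None
    for label, dur in config.epoch_plan:
        sel = (t >= t0) & (t < t0 + dur)
        labels[sel] = label
        if prev_label is not None and sel.any():
            key = f"{prev_label}->{label}"
            transitions.setdefault(key, int(np.flatnonzero(sel)[0]))
        prev_label = label
        t0 += dur
    return labels, transitions


def _kernel(config: TraceConfig, length: int) -> np.ndarray:
    """Linear rise to the peak over rise_frames, then exponential decay."""
    i = np.arange(length)
    rise = (i + 1) / config.rise_frames
    dt = 1.0 / config.frame_rate_hz
    decay = np.exp(-(i - (config.rise_frames - 1)) * dt / config.decay_tau_s)
    return config.peak_dff * np.where(i < config.rise_frames, rise, decay)


def generate_calcium_cohort(
    config: TraceConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate fluorescence traces, epoch labels, and responder ground truth.

    Returns
    -------
    traces : DataFrame ``neuron_id, trial, frame, intensity`` — baseline
        plus Gaussian noise, with the response kernel added from the planted
        onset frame for responder neurons (identical kernel every trial).
    epochs : DataFrame ``trial, frame, label``.
    truth : DataFrame ``neuron_id, true_class, onset_frame`` with class in
        {"OFF", "ON", "none"}.
    """
    labels, transitions = _epoch_frames(config)
    n_frames = labels.size
    off_onset = transitions.get("light->dark")
    on_onset = transitions.get("dark->light")
    n_off = round(config.frac_off * config.n_neurons)
    n_on = round(config.frac_on * config.n_neurons)
    if n_off > 0 and off_onset is None:
        raise ValueError("epoch plan has no light->dark transition for OFF responders")
    if n_on > 0 and on_onset is None:
        raise ValueError(
            "epoch plan has no dark->light transition; use e.g. light/dark/light "
            "when planting ON responders"
        )

    rows_traces = []
    rows_truth = []
    for i, rng in enumerate(_substream(config.seed, config.n_neurons)):
        if i < n_off:
            cls, onset = "OFF", off_onset
        elif i < n_off + n_on:
            cls, onset = "ON", on_onset
        else:
            cls, onset = "none", None
        signal = np.zeros(n_frames)
        if onset is not None:
            ker = _kernel(config, n_frames - onset)
            signal[onset:] = ker * config.baseline  # dF/F units -> raw units
        for trial in range(1, config.n_trials + 1):
            trace = config.baseline + signal + rng.normal(
                0.0, config.noise_sd, size=n_frames
            )
            for f in range(n_frames):
                rows_traces.append((f"neuron_{i:04d}", trial, f, float(trace[f])))
        rows_truth.append(
            {
                "neuron_id": f"neuron_{i:04d}",
                "true_class": cls,
                "onset_frame": -1 if onset is None else onset,
            }
        )
    traces = pd.DataFrame(rows_traces, columns=["neuron_id", "trial", "frame", "intensity"])
    epochs = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(1, config.n_trials + 1), n_frames),
            "frame": np.tile(np.arange(n_frames), config.n_trials),
            "label": np.tile(labels, config.n_trials),
        }
    )
    return traces, epochs, pd.DataFrame(rows_truth)
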