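"""Per-larva turn-bias metrics and their exclusion rules.

Two families of measures are implemented:

* **Trajectory measures** computed from heading-change time series: the net
  turn angle (NTA, the signed sum of all path direction changes in a 30-s
  window; rightward positive), the absolute NTA (sum of unsigned changes),
  a left/right classification from the trial-1 NTA sign, and the Match
  Index (fraction of trials 2-4 whose NTA sign matches trial 1).  Trials
  with less than 10 s of data are excluded.

* **Kinematic measures** computed from discrete routine-turn events: the
  per-trial percentage of rightward turns, the larva's mean %rightward over
  its four trials, classification by <33% / >66% thresholds, and the
  decomposition of bias into magnitude |%R - 50| and direction.  Larvae
  with fewer than three turns on any required trial are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialNTA",
    "compute_nta",
    "classify_lr",
    "match_index",
    "percent_rightward",
    "classify_by_percent",
    "decompose_bias",
    "select_consistent_larvae",
    "nta_cohort_table",
    "turn_cohort_table",
]

#: data-span threshold (seconds) below which a trajectory trial is excluded
MIN_DATA_SPAN_S = 10.0
#: minimum number of valid follow-up trials for a defined Match Index
MIN_VALID_FOLLOWUPS = 2


@dataclass
class TrialNTA:
    """Net turn angle for one larva on one trial.

    ``nta_deg`` is the signed sum of path direction changes (rightward
    positive), ``abs_nta_deg`` the sum of unsigned changes, ``data_span_s``
    the seconds of usable data in the recording window, and ``valid`` is
    False when the span falls below :data:`MIN_DATA_SPAN_S`.
    """

    larva_id: object = None
    trial: int = 0
    nta_deg: float = math.nan
    abs_nta_deg: float = math.nan
    data_span_s: float = 0.0
    valid: bool = False


def _data_span(times: np.ndarray) -> float:
    """Seconds of data present, robust to dropout gaps.

    The span is estimated as the sample count times the median inter-sample
    interval, so a long dropout in the middle of a window does not inflate
    it the way ``t_max - t_min`` would.
    """
    if times.size < 2:
        return 0.0
    dt = np.diff(times)
    return float(times.size * np.median(dt))


def compute_nta(
    series,
    larva_id=None,
    trial: int = 0,
    min_span_s: float = MIN_DATA_SPAN_S,
) -> TrialNTA:
    """Compute the net turn angle of one heading-change series.

    Parameters
    ----------
    series : DataFrame with columns ``time_s`` and ``dtheta_deg``, or a
        2-tuple/array-pair ``(times, changes)``.
    min_span_s : float
        Trials with less data than this are marked invalid (the NTA is still
        reported for inspection when any samples exist).

    An empty series yields ``valid=False`` with NaN angles rather than an
    exception, so cohort tables can carry missing trials.
    """
    if isinstance(series, pd.DataFrame):
        times = series["time_s"].to_numpy(dtype=float)
        changes = series["dtheta_deg"].to_numpy(dtype=float)
    else:
        times, changes = (np.asarray(a, dtype=float) for a in series)
    if times.shape != changes.shape:
        raise ValueError("times and angle changes must have equal length")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")

    if times.size == 0:
        return TrialNTA(larva_id=larva_id, trial=trial)
    span = _data_span(times)
    return TrialNTA(
        larva_id=larva_id,
        trial=trial,
        nta_deg=float(changes.sum()),
        abs_nta_deg=float(np.abs(changes).sum()),
        data_span_s=span,
        valid=span >= min_span_s,
    )


def classify_lr(trial1: TrialNTA) -> str:
    """Left/right class from the trial-1 NTA sign.

    Positive NTA -> "R", negative -> "L"; a zero NTA or an invalid trial
    leaves the larva "unclassified" (and excluded from the Match Index).
    """
    if not trial1.valid or math.isnan(trial1.nta_deg) or trial1.nta_deg == 0:
        return "unclassified"
    return "R" if trial1.nta_deg > 0 else "L"


def match_index(
    trial_ntas: list[TrialNTA],
    min_valid_followups: int = MIN_VALID_FOLLOWUPS,
) -> tuple[float, int]:
    """Fraction of valid follow-up trials whose NTA sign matches trial 1.

    Returns ``(mi, n_valid_followups)``.  The denominator counts only valid
    follow-up trials with a nonzero NTA (excluded and sign-less tied trials
    are dropped, not scored as mismatches — a tied trial carries no
    direction, and counting it against the larva would pull the null mean
    below 0.5); the Match Index is NaN when trial 1 is invalid or has zero
    NTA, or when fewer than ``min_valid_followups`` follow-ups are valid.
    """
    if len(trial_ntas) < 2:
        raise ValueError("Match Index needs trial 1 plus at least one follow-up")
    t1 = trial_ntas[0]
    followups = [
        t for t in trial_ntas[1:]
        if t.valid and not math.isnan(t.nta_deg) and t.nta_deg != 0
    ]
    n_valid = len(followups)
    if classify_lr(t1) == "unclassified" or n_valid < min_valid_followups:
        return math.nan, n_valid
    sign1 = math.copysign(1.0, t1.nta_deg)
    n_match = sum(1 for t in followups if math.copysign(1.0, t.nta_deg) == sign1)
    return n_match / n_valid, n_valid


def percent_rightward(
    trial_directions: list,
    min_turns: int = 3,
    n_trials_required: int = 4,
) -> tuple[list[float], float, bool]:
    """Per-trial and mean percentage of rightward routine turns.

    Parameters
    ----------
    trial_directions : list of per-trial direction sequences, each entry an
        iterable of +1 (rightward) / -1 (leftward) turn directions.
    min_turns, n_trials_required : the inclusion filter — a larva is
        analyzed only if it executed at least ``min_turns`` turns on each of
        the first ``n_trials_required`` trials.

    Returns
    -------
    (per_trial_pct, mean_pct, included)
        ``mean_pct`` is the unweighted mean of the per-trial percentages
        (NaN-skipping over empty trials); ``included`` is False when the
        filter fails.
    """
    if len(trial_directions) == 0:
        raise ValueError("at least one trial of turn directions is required")
    per_trial = []
    for dirs in trial_directions:
        d = np.asarray(list(dirs))
        if d.size and not np.isin(d, (-1, 1)).all():
            raise ValueError("turn directions must be -1 or +1")
        per_trial.append(100.0 * float((d == 1).sum()) / d.size if d.size else math.nan)
    required = trial_directions[:n_trials_required]
    included = len(required) == n_trials_required and all(
        len(list(d)) >= min_turns for d in required
    )
    mean_pct = float(np.nanmean(per_trial)) if not all(math.isnan(p) for p in per_trial) else math.nan
    return per_trial, mean_pct, included


def classify_by_percent(mean_pct_r: float, low: float = 33.0, high: float = 66.0) -> str:
    """Classify a larva from its mean %rightward: < low -> L, > high -> R."""
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    if math.isnan(mean_pct_r):
        return "unclassified"
    if not 0.0 <= mean_pct_r <= 100.0:
        raise ValueError("%rightward must lie in [0, 100]")
    if mean_pct_r < low:
        return "L"
    if mean_pct_r > high:
        return "R"
    return "unclassified"


def decompose_bias(mean_pct_r: float) -> tuple[float, str]:
    """Split mean %rightward into bias magnitude and direction.

    Magnitude is ``|%R - 50|`` (0-50 scale); direction is "R" above 50,
    "L" below, "none" at exactly 50.
    """
    if not 0.0 <= mean_pct_r <= 100.0:
        raise ValueError("%rightward must lie in [0, 100]")
    magnitude = abs(mean_pct_r - 50.0)
    if mean_pct_r > 50.0:
        return magnitude, "R"
    if mean_pct_r < 50.0:
        return magnitude, "L"
    return 0.0, "none"


def select_consistent_larvae(cohort: pd.DataFrame) -> pd.DataFrame:
    """Breeder-selection filter for larvae with strong, consistent bias.

    Retains larvae whose mean %rightward lies in the top or bottom quartile
    of the cohort (inclusive, linear-interpolation quantiles) *and* whose
    per-trial net directions are identical (all rightward or all leftward)
    on every trial.  ``cohort`` needs a ``mean_pct_rightward`` column and
    per-trial ``pct_rightward_1..n`` columns.
    """
    if len(cohort) < 4:
        raise ValueError("quartiles are undefined for cohorts of fewer than 4 larvae")
    mean_r = cohort["mean_pct_rightward"].to_numpy(dtype=float)
    q1, q3 = np.nanquantile(mean_r, [0.25, 0.75])
    in_outer = (mean_r <= q1) | (mean_r >= q3)

    trial_cols = sorted(
        (c for c in cohort.columns if c.startswith("pct_rightward_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not trial_cols:
        raise ValueError("cohort table lacks per-trial pct_rightward_<i> columns")
    per_trial = cohort[trial_cols].to_numpy(dtype=float)
    signs = np.sign(per_trial - 50.0)
    consistent = (signs != 0).all(axis=1) & (signs == signs[:, :1]).all(axis=1)
    return cohort.loc[in_outer & consistent]


def nta_cohort_table(
    heading: pd.DataFrame,
    window: tuple[float, float] = (0.0, 30.0),
    min_span_s: float = MIN_DATA_SPAN_S,
    min_valid_followups: int = MIN_VALID_FOLLOWUPS,
) -> pd.DataFrame:
    """Per-larva NTA summary from a long-format heading-change table.

    ``heading`` has columns ``larva_id, trial, time_s, dtheta_deg``.  Emits
    one row per larva with per-trial NTAs, the trial-1 left/right class, and
    the Match Index with its valid-follow-up count.
    """
    required = {"larva_id", "trial", "time_s", "dtheta_deg"}
    missing = required - set(heading.columns)
    if missing:
        raise ValueError(f"heading table is missing columns: {sorted(missing)}")
    lo, hi = window
    heading = heading[(heading["time_s"] >= lo) & (heading["time_s"] < hi)]

    rows = []
    for larva_id, larva_df in heading.groupby("larva_id", sort=True):
        trials = sorted(larva_df["trial"].unique())
        ntas = [
            compute_nta(
                larva_df[larva_df["trial"] == t].sort_values("time_s"),
                larva_id=larva_id,
                trial=t,
                min_span_s=min_span_s,
            )
            for t in trials
        ]
        mi, n_valid = (
            match_index(ntas, min_valid_followups) if len(ntas) >= 2 else (math.nan, 0)
        )
        row = {
            "larva_id": larva_id,
            "lr_class": classify_lr(ntas[0]) if ntas else "unclassified",
            "match_index": mi,
            "n_valid_followups": n_valid,
        }
        for i, t in enumerate(ntas, start=1):
            row[f"nta_deg_{i}"] = t.nta_deg
            row[f"abs_nta_deg_{i}"] = t.abs_nta_deg
            row[f"valid_{i}"] = t.valid
        rows.append(row)
    return pd.DataFrame(rows)


def turn_cohort_table(
    turns: pd.DataFrame,
    min_turns: int = 3,
    n_trials_required: int = 4,
    min_valid_followups: int = MIN_VALID_FOLLOWUPS,
) -> pd.DataFrame:
    """Per-larva bias summary from a long-format routine-turn event table.

    ``turns`` has columns ``larva_id, trial, event_index, direction``
    (direction in {-1, +1}); ``time_s`` is accepted and ignored.  Emits one
    row per larva with per-trial %rightward, the mean %rightward, its
    magnitude/direction decomposition, the <33/>66 classification, the
    Match Index over per-trial net directions, and per-trial turn counts.
    """
    required = {"larva_id", "trial", "event_index", "direction"}
    missing = required - set(turns.columns)
    if missing:
        raise ValueError(f"turn table is missing columns: {sorted(missing)}")
    bad = ~turns["direction"].isin((-1, 1))
    if bad.any():
        raise ValueError(
            f"turn table row {int(np.flatnonzero(bad.to_numpy())[0])}: "
            "direction must be -1 or +1"
        )

    rows = []
    for larva_id, larva_df in turns.groupby("larva_id", sort=True):
        trials = sorted(larva_df["trial"].unique())
        seqs = [
            larva_df[larva_df["trial"] == t]
            .sort_values("event_index")["direction"]
            .to_numpy()
            for t in trials
        ]
        per_trial, mean_pct, included = percent_rightward(
            seqs, min_turns=min_turns, n_trials_required=n_trials_required
        )
        magnitude, direction = (
            decompose_bias(mean_pct) if not math.isnan(mean_pct) else (math.nan, "none")
        )
        # per-trial net direction stands in for the NTA sign on event data
        ntas = [
            TrialNTA(
                larva_id=larva_id,
                trial=t,
                nta_deg=float((s == 1).sum() - (s == -1).sum()),
                abs_nta_deg=float(len(s)),
                data_span_s=math.inf,
                valid=len(s) >= min_turns,
            )
            for t, s in zip(trials, seqs)
        ]
        mi, n_valid = (
            match_index(ntas, min_valid_followups) if len(ntas) >= 2 else (math.nan, 0)
        )
        row = {
            "larva_id": larva_id,
            "mean_pct_rightward": mean_pct,
            "bias_magnitude": magnitude,
            "bias_direction": direction,
            "pct_class": classify_by_percent(mean_pct) if not math.isnan(mean_pct) else "unclassified",
            "match_index": mi,
            "n_valid_followups": n_valid,
            "included": included,
        }
        for i, (t, s) in enumerate(zip(trials, seqs), start=1):
            row[f"pct_rightward_{i}"] = per_trial[i - 1]
            row[f"n_turns_{i}"] = len(s)
        rows.append(row)
    return pd.DataFrame(rows)
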