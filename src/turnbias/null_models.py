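"""Monte-Carlo null models for turn-direction bias.

Sequential routine turns are not independent: a turn is more likely than
chance to repeat the direction of the previous turn.  The degree of
persistence is summarized by the *lock index* L on a 0-100 scale, which maps
linearly to the probability ``p_same = (100 + L) / 200`` that consecutive
turns share a direction (L = 0 means independent directions, L = 100 means a
trial never changes direction).

The null model of an *unbiased* larva is a two-state Markov chain: the first
turn of each trial is a fair coin, and every subsequent turn repeats the
previous direction with probability ``p_same``.  Simulating cohorts from this
chain — with the same larva count and the same per-trial turn counts as the
experimental data — yields the expected distribution of per-larva %rightward
turns, two-sided tail thresholds, and an empirical p-value for the observed
number of larvae beyond those thresholds.

A separate one-sample permutation test compares the cohort mean Match Index
to the chance value of 0.5 by drawing, for each larva, a Binomial(k, 0.5)/k
null Match Index over its k valid follow-up trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "lock_to_prob",
    "prob_to_lock",
    "simulate_null_cohort",
    "mc_bias_test",
    "permutation_match_test",
    "null_histogram",
    "empirical_p",
    "NullSimResult",
    "PermutationResult",
]

_SIM_CHUNK = 500  # cohorts simulated per vectorized block


def lock_to_prob(lock_index: float) -> float:
    """Convert a lock index L on the 0-100 persistence scale to p_same.

    ``p_same = (100 + L) / 200``; L = 62.8 gives 0.814, L = 13.2 gives
    0.566, and L = 0 gives independent turn directions (0.5).  Negative L
    (down to -100) encodes anti-persistence.
    """
    if not -100.0 <= lock_index <= 100.0:
        raise ValueError(f"lock index must be in [-100, 100], got {lock_index}")
    return (100.0 + lock_index) / 200.0


def prob_to_lock(p_same: float) -> float:
    """Inverse of :func:`lock_to_prob`: ``L = 200 * p_same - 100``."""
    if not 0.0 <= p_same <= 1.0:
        raise ValueError(f"p_same must be in [0, 1], got {p_same}")
    return 200.0 * p_same - 100.0


def empirical_p(n_exceed: int, n_sims: int) -> tuple[float, bool]:
    """Empirical p-value convention: ``k / n_sims`` with a bound at k = 0.

    Returns ``(p, is_bound)``.  When no simulation reaches the observed
    statistic the p-value is reported as the bound ``p < 1/n_sims``
    (e.g. "< 0.0001" at 10,000 simulations) with ``is_bound = True``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_exceed == 0:
        return 1.0 / n_sims, True
    return n_exceed / n_sims, False


def _as_count_matrix(turn_counts) -> np.ndarray:
    """Validate and coerce per-larva per-trial turn counts to a 2-D int array."""
    counts = np.asarray(turn_counts)
    if isinstance(turn_counts, pd.DataFrame):
        counts = turn_counts.to_numpy()
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.size == 0:
        raise ValueError("turn count table is empty")
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 1):
        raise ValueError("all turn counts must be integers >= 1")
    return counts.astype(np.int64)


def simulate_null_cohort(
    turn_counts,
    p_same: float,
    seed=None,
    n_cohorts: int = 1,
) -> np.ndarray:
    """Simulate unbiased cohorts and return per-larva mean %rightward turns.

    Parameters
    ----------
    turn_counts : array-like of shape (n_larvae, n_trials)
        Number of routine turns each larva produced on each trial; the
        simulation reuses these counts exactly.
    p_same : float
        Probability that each turn after the first repeats the previous
        direction (from :func:`lock_to_prob`).
    seed : int, numpy Generator, or SeedSequence, optional
    n_cohorts : int
        Number of independent cohorts to simulate.

    Returns
    -------
    ndarray of shape (n_cohorts, n_larvae)
        Each larva's statistic is the unweighted mean over trials of the
        per-trial percentage of rightward turns.
    """
    counts = _as_count_matrix(turn_counts)
    if not 0.0 <= p_same <= 1.0:
        raise ValueError(f"p_same must be in [0, 1], got {p_same}")
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    rng = np.random.default_rng(seed)

    n_larvae, n_trials = counts.shape
    k_flat = counts.reshape(-1)  # (n_larvae * n_trials,)
    k_max = int(k_flat.max())
    out = np.empty((n_cohorts, n_larvae))

    for start in range(0, n_cohorts, _SIM_CHUNK):
        stop = min(start + _SIM_CHUNK, n_cohorts)
        c = stop - start
        # first turn: fair coin, +1 right / -1 left
        first = rng.integers(0, 2, size=(c, k_flat.size)) * 2 - 1
        # subsequent turns: sign flip with probability 1 - p_same
        flips = np.where(
            rng.random(size=(c, k_flat.size, k_max - 1)) < p_same, 1, -1
        ) if k_max > 1 else np.ones((c, k_flat.size, 0), dtype=np.int64)
        dirs = np.empty((c, k_flat.size, k_max), dtype=np.int8)
        dirs[..., 0] = first
        if k_max > 1:
            np.cumprod(flips, axis=-1, out=flips)
            dirs[..., 1:] = first[..., None] * flips
        valid = np.arange(k_max)[None, :] < k_flat[:, None]  # (seq, k_max)
        n_right = np.where(valid[None, :, :], dirs == 1, False).sum(axis=-1)
        pct_r = 100.0 * n_right / k_flat[None, :]
        out[start:stop] = pct_r.reshape(c, n_larvae, n_trials).mean(axis=-1)
    return out


@dataclass
class NullSimResult:
    """Result of a Monte-Carlo tail test of per-larva turn-direction bias."""

    n_sims: int
    tail: float
    threshold_low: float
    threshold_high: float
    observed_exceedance: int
    n_larvae: int
    p_value: float
    p_is_bound: bool
    sim_exceedances: np.ndarray = field(repr=False)
    sim_pct_rightward: np.ndarray = field(repr=False)
    p_same: float = 0.5

    def to_dict(self) -> dict:
        """JSON-serializable summary (simulation draws are not included)."""
        return {
            "n_sims": self.n_sims,
            "tail": self.tail,
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
            "observed_exceedance": self.observed_exceedance,
            "n_larvae": self.n_larvae,
            "p_value": self.p_value,
            "p_is_bound": self.p_is_bound,
            "p_same": self.p_same,
            "mean_sim_exceedance": float(self.sim_exceedances.mean()),
            "threshold_convention": (
                "tail/2 and 1-tail/2 linear-interpolation quantiles of the "
                "pooled simulated per-larva %rightward distribution; larvae "
                "strictly outside the open interval count as biased"
            ),
        }


def mc_bias_test(
    observed_pct_rightward,
    turn_counts,
    p_same: float,
    n_sims: int = 10_000,
    tail: float = 0.10,
    seed=None,
) -> NullSimResult:
    """Monte-Carlo test of whether a cohort holds more biased larvae than chance.

    Simulates ``n_sims`` unbiased cohorts matched to the observed larva count
    and per-trial turn counts, derives two-sided thresholds as the tail/2 and
    1 - tail/2 quantiles of the pooled simulated per-larva %rightward
    distribution, and counts larvae strictly outside the open interval
    (threshold_low, threshold_high).  The p-value is the fraction of
    simulated cohorts whose exceedance count is at least the observed count
    (:func:`empirical_p` convention, with a "< 1/n_sims" bound at zero).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must be in (0, 1)")
    observed = np.asarray(observed_pct_rightward, dtype=float)
    counts = _as_count_matrix(turn_counts)
    if observed.shape[0] != counts.shape[0]:
        raise ValueError(
            "observed %rightward values and turn-count rows are misaligned: "
            f"{observed.shape[0]} larvae vs {counts.shape[0]} count rows"
        )

    sims = simulate_null_cohort(counts, p_same, seed=seed, n_cohorts=n_sims)
    lo, hi = np.quantile(sims.reshape(-1), [tail / 2.0, 1.0 - tail / 2.0])
    sim_exceed = ((sims < lo) | (sims > hi)).sum(axis=1)
    obs_exceed = int(((observed < lo) | (observed > hi)).sum())
    p, bound = empirical_p(int((sim_exceed >= obs_exceed).sum()), n_sims)
    return NullSimResult(
        n_sims=n_sims,
        tail=tail,
        threshold_low=float(lo),
        threshold_high=float(hi),
        observed_exceedance=obs_exceed,
        n_larvae=observed.shape[0],
        p_value=p,
        p_is_bound=bound,
        sim_exceedances=sim_exceed,
        sim_pct_rightward=sims,
        p_same=p_same,
    )


@dataclass
class PermutationResult:
    """Result of the one-sample permutation test of the mean Match Index."""

    observed_mean: float
    n_sims: int
    p_value: float
    p_is_bound: bool
    alternative: str
    null_mean: float = 0.5
    null_means: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "n_sims": self.n_sims,
            "p_value": self.p_value,
            "p_is_bound": self.p_is_bound,
            "alternative": self.alternative,
            "null_mean": self.null_mean,
        }


def permutation_match_test(
    match_indices,
    n_followups,
    n_sims: int = 100_000,
    seed=None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """One-sample permutation test of the cohort mean Match Index against 0.5.

    Under the null hypothesis each larva matches its trial-1 direction with
    probability 0.5 on each of its ``k_i`` valid follow-up trials, so its null
    Match Index is ``Binomial(k_i, 0.5) / k_i``.  The test statistic is the
    cohort mean; the two-sided p-value is the fraction of ``n_sims`` null
    cohort means at least as far from 0.5 as the observed mean (greater/less
    use the signed deviation).
    """
    mi = np.asarray(match_indices, dtype=float)
    k = np.asarray(n_followups, dtype=np.int64)
    if mi.shape != k.shape or mi.ndim != 1 or mi.size == 0:
        raise ValueError("match_indices and n_followups must be equal-length 1-D")
    if np.any((mi < 0) | (mi > 1)):
        raise ValueError("Match Index values must lie in [0, 1]")
    if np.any(k < 1):
        raise ValueError("every larva needs at least one valid follow-up trial")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")

    rng = np.random.default_rng(seed)
    observed_mean = float(mi.mean())
    null_means = (rng.binomial(k[None, :], 0.5, size=(n_sims, k.size)) / k).mean(axis=1)

    if alternative == "two-sided":
        n_exceed = int((np.abs(null_means - 0.5) >= abs(observed_mean - 0.5)).sum())
    elif alternative == "greater":
        n_exceed = int((null_means - 0.5 >= observed_mean - 0.5).sum())
    else:
        n_exceed = int((null_means - 0.5 <= observed_mean - 0.5).sum())
    p, bound = empirical_p(n_exceed, n_sims)
    return PermutationResult(
        observed_mean=observed_mean,
        n_sims=n_sims,
        p_value=p,
        p_is_bound=bound,
        alternative=alternative,
        null_means=null_means,
    )


def null_histogram(result: NullSimResult, bin_width: float = 4.0) -> pd.DataFrame:
    """Bin the pooled simulated per-larva %rightward values.

    Returns a DataFrame with columns ``bin_low``, ``bin_high`` and
    ``fraction`` (fractions sum to 1); this is the "expected distribution"
    overlay for an observed %rightward histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    pooled = result.sim_pct_rightward.reshape(-1)
    counts, edges = np.histogram(pooled, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "fraction": counts / pooled.size,
        }
    )
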