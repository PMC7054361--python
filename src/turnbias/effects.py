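"""Effect sizes reported alongside standard group tests.

The group tests themselves (t test, Mann-Whitney U, ANOVA) are delegated to
scipy/standard routines; this module owns only the effect-size arithmetic:
Cohen's d for t tests, the rank-biserial correlation r for Mann-Whitney U
tests, and partial eta-squared for ANOVAs (whose sums of squares enter as
inputs).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["cohens_d", "rank_biserial_r", "partial_eta_squared"]


def _two_samples(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < min_n or b.size < min_n:
        raise ValueError(f"both groups need at least {min_n} observations")
    return a, b


def cohens_d(a, b, sd: str = "pooled") -> float:
    """Standardized mean difference (mean_a - mean_b) / s.

    ``sd="pooled"`` (default) uses the pooled standard deviation with n-1
    denominators; ``sd="b"`` standardizes by group b's sd alone (the
    control-group convention).  Raises when the chosen sd is zero.
    """
    a, b = _two_samples(a, b, min_n=2)
    if sd == "pooled":
        na, nb = a.size, b.size
        s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        s = np.sqrt(s2)
    elif sd == "b":
        s = b.std(ddof=1)
    else:
        raise ValueError(f"unknown sd convention {sd!r}")
    if s == 0:
        raise ValueError("standardizer is zero; Cohen's d is undefined")
    return float((a.mean() - b.mean()) / s)


def rank_biserial_r(a, b) -> float:
    """Rank-biserial correlation for the Mann-Whitney U test.

    Equals the dominance statistic (#{a > b} - #{a < b}) / (n_a * n_b) over
    all cross-group pairs, with ties handled by midranks; positive r means
    group a tends to exceed group b, r = +1 at complete separation.
    """
    a, b = _two_samples(a, b, min_n=1)
    u_a = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u_a / (a.size * b.size) - 1.0)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta-squared: ss_effect / (ss_effect + ss_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta-squared is undefined when both ss are zero")
    return float(ss_effect / (ss_effect + ss_error))
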