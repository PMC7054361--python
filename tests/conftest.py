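import numpy as np
import pytest

from turnbias import synthetic


@pytest.fixture(scope="session")
def small_turn_cohort():
    """Unbiased 40-larva cohort shared by metric and pipeline tests."""
    config = synthetic.CohortConfig(n_larvae=40, seed=123)
    turns, truth = synthetic.generate_turn_cohort(config)
    return turns, truth


@pytest.fixture(scope="session")
def calcium_cohort():
    """Planted-responder cohort with a light/dark/light epoch plan."""
    config = synthetic.TraceConfig(
        n_neurons=40,
        frac_off=0.2,
        frac_on=0.1,
        epoch_plan=(("light", 60.0), ("dark", 60.0), ("light", 60.0)),
        seed=7,
    )
    return synthetic.generate_calcium_cohort(config), config


def enumerate_null_pct_r(k: int, p_same: float) -> dict[float, float]:
    """Exhaustive single-trial null: P(%rightward) over all 2^k sequences.

    Independent oracle for the Markov-chain simulator: the first turn is a
    fair coin and each later turn repeats the previous one with probability
    p_same; probabilities are accumulated by explicit sequence enumeration.
    """
    out: dict[float, float] = {}
    for code in range(2 ** k):
        dirs = [1 if (code >> i) & 1 else -1 for i in range(k)]
        prob = 0.5
        for prev, cur in zip(dirs, dirs[1:]):
            prob *= p_same if cur == prev else 1.0 - p_same
        pct = 100.0 * sum(1 for d in dirs if d == 1) / k
        out[pct] = out.get(pct, 0.0) + prob
    return out


@pytest.fixture(scope="session")
def null_pct_r_oracle():
    return enumerate_null_pct_r
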