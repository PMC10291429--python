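"""Shared fixtures: calibrated weights and full-scale simulated societies.

The heavy session fixtures run each society condition once at the default
study scale (100 replicates of 1200 updates, groups of 30) and share the
records, fitted chains, and Gini distributions across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from hierdyn import inequality, markov, society
from hierdyn.society import Inheritance

SEED = 1

CONDITIONS = {
    "mri_rank": (Inheritance.MRI_YA, True),
    "mri_norank": (Inheritance.MRI_YA, False),
    "none_rank": (Inheritance.NONE, True),
    "none_norank": (Inheritance.NONE, False),
    "primogeniture_rank": (Inheritance.PRIMOGENITURE, True),
    "correlation_rank": (Inheritance.CORRELATION, True),
}


@pytest.fixture(scope="session")
def slope() -> float:
    return inequality.calibrate_reproduction(society.DEFAULT_STEP_GINI, 30)


@pytest.fixture(scope="session")
def weights(slope):
    return inequality.reproduction_weights(30, slope)


@pytest.fixture(scope="session")
def records():
    """Default-scale simulation record for each of the six conditions."""
    out = {}
    for name, (inh, rank_effect) in CONDITIONS.items():
        cfg = society.SimConfig(
            inheritance=inh, rank_effect=rank_effect, seed=SEED, n_replicates=100
        )
        out[name] = society.run_simulation(cfg)
    return out


@pytest.fixture(scope="session")
def chains10(records):
    return {name: markov.fit_from_record(rec, queen_mode=False) for name, rec in records.items()}


@pytest.fixture(scope="session")
def chains_queen(records):
    return {name: markov.fit_from_record(rec, queen_mode=True) for name, rec in records.items()}


@pytest.fixture(scope="session")
def steady_states(chains10):
    return {
        name: markov.steady_state(chain.probabilities) for name, chain in chains10.items()
    }


@pytest.fixture(scope="session")
def gini_reports(chains_queen, weights):
    """Lifetime-RS Gini distributions for the four rank-effect variants."""
    rng = np.random.default_rng(SEED)
    conditions = ["mri_rank", "primogeniture_rank", "none_rank", "correlation_rank"]
    return {
        name: inequality.gini_report(
            chains_queen[name], weights, L=120, M=10_000, rng=rng, condition=name
        )
        for name in conditions
    }
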