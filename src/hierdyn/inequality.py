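"""Rank-dependent reproduction and inequality in lifetime reproductive success.

Reproduction is rank-dependent through a linear weight on standardized rank,
``w(s) = 1 + c s``, normalized across the group's positions into per-update
reproduction probabilities ``q``.  The slope ``c`` is calibrated so that the
Gini index of ``q`` across positions — the inequality injected at every
single reproductive step — matches a chosen value (0.19 by default, see
:mod:`hierdyn.society`).

Expected lifetime reproductive success of a hierarchy-state trajectory is
the sum, over the updates of a lifetime, of the expected per-update
reproduction probability of the occupied state.  Comparing the Gini index of
these lifetime expectations across starting states, between societies with
different social-inheritance regimes, shows how hierarchy dynamics amplify
or erode the per-step inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from . import markov

__all__ = [
    "ReproductionWeights",
    "GiniReport",
    "reproduction_weights",
    "calibrate_reproduction",
    "state_reproduction_probability",
    "state_probability_vector",
    "expected_lifetime_rs",
    "gini",
    "gini_report",
    "gini_distribution",
]


@dataclass(frozen=True)
class ReproductionWeights:
    """Linear rank-reproduction weights for a group of n positions.

    ``w[p]`` is the unnormalized weight and ``q[p]`` the per-update
    probability of reproducing for the individual at position p + 1 (index
    0 = top of the hierarchy).
    """

    w: np.ndarray
    q: np.ndarray
    c: float

    @property
    def n(self) -> int:
        return self.w.size

    @property
    def step_gini(self) -> float:
        """Gini of the per-update reproduction probabilities across positions."""
        return gini(self.q)


def reproduction_weights(n: int, c: float) -> ReproductionWeights:
    """Weights w(s) = 1 + c*s over the n positions, normalized to q."""
    if c < 0:
        raise ValueError(f"reproduction slope must be non-negative, got {c}")
    if n < 2:
        raise ValueError(f"need at least 2 positions, got {n}")
    p = np.arange(1, n + 1)
    s = (n - p) / (n - 1)
    w = 1.0 + c * s
    return ReproductionWeights(w=w, q=w / w.sum(), c=float(c))


def calibrate_reproduction(
    target_gini: float, n: int, tol: float = 1e-9, c_max: float = 1e6
) -> float:
    """Solve for the slope c whose per-step reproduction Gini hits the target.

    The map c -> Gini(q(c)) is continuous, zero at c = 0 and strictly
    increasing towards the supremum Gini of the family (that of the bare
    standardized ranks), so bisection on a bracketing interval finds the
    unique root.
    """
    if target_gini < 0:
        raise ValueError("target Gini must be non-negative")
    if target_gini == 0:
        return 0.0
    g_sup = gini(np.arange(n) / (n - 1))  # limit c -> inf: q proportional to s
    if target_gini >= g_sup:
        raise ValueError(
            f"target Gini {target_gini} unreachable: the linear family on "
            f"{n} positions is bounded below {g_sup:.4f}"
        )
    f = lambda c: reproduction_weights(n, c).step_gini - target_gini
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > c_max:
            raise ValueError("failed to bracket the calibration target")
    return float(brentq(f, 0.0, hi, xtol=tol))


def gini(values) -> float:
    """Population Gini index: mean absolute pairwise difference over twice
    the mean, G = sum_ij |x_i - x_j| / (2 n^2 xbar), no small-sample
    correction.  Ranges over [0, 1 - 1/n] for non-negative inputs."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("Gini needs at least two values")
    if np.any(x < 0):
        raise ValueError("Gini is defined here for non-negative values only")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for all-zero values")
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    # clamp float rounding on exactly-equal inputs
    return float(max(2.0 * (i * xs).sum() / (n * total) - (n + 1) / n, 0.0))


def _gini_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise population Gini of a 2-D array of non-negative values."""
    xs = np.sort(matrix, axis=1)
    n = matrix.shape[1]
    i = np.arange(1, n + 1)
    totals = xs.sum(axis=1)
    return np.maximum(2.0 * (xs * i).sum(axis=1) / (n * totals) - (n + 1) / n, 0.0)


def state_probability_vector(
    weights: ReproductionWeights, queen_mode: bool = False
) -> np.ndarray:
    """Expected per-update reproduction probability of each hierarchy state.

    A decile state maps to the mean of q over the positions it contains
    (three positions per decile at n = 30); the queen state maps to the top
    position's q.
    """
    pos_state = markov.position_states(weights.n, queen_mode)
    K = 11 if queen_mode else 10
    out = np.empty(K)
    for k in range(K):
        members = weights.q[pos_state == k]
        if members.size == 0:
            # queen mode removes position 1 from decile 10's members only if
            # the decile would otherwise be empty -- cannot happen for n >= 2
            out[k] = 0.0
        else:
            out[k] = members.mean()
    return out


def state_reproduction_probability(
    state: int, weights: ReproductionWeights, queen_mode: bool = False
) -> float:
    """Per-update reproduction probability of one hierarchy state."""
    return float(state_probability_vector(weights, queen_mode)[state])


def expected_lifetime_rs(
    state_sequence, weights: ReproductionWeights, queen_mode: bool | None = None
) -> float:
    """Expected lifetime reproductive success of a state trajectory.

    Sums the per-update reproduction probability of the occupied state over
    the L post-start steps of a length-(L + 1) sequence, so under uniform
    weights every trajectory of L steps in a group of n yields exactly L/n.
    """
    seq = np.asarray(state_sequence)
    if queen_mode is None:
        queen_mode = bool(seq.max() == markov.QUEEN)
    qvec = state_probability_vector(weights, queen_mode)
    return float(qvec[seq[1:]].sum())


@dataclass
class GiniReport:
    """Distribution of lifetime-reproductive-success Gini indices for one
    society condition."""

    condition: str
    ginis: np.ndarray  # (M,)

    @property
    def mean(self) -> float:
        return float(self.ginis.mean())

    @property
    def sd(self) -> float:
        return float(self.ginis.std())


def gini_report(
    chain: markov.TransitionMatrix,
    weights: ReproductionWeights,
    L: int = 120,
    M: int = 10_000,
    rng: np.random.Generator | None = None,
    condition: str = "",
) -> GiniReport:
    """Distribution of lifetime-RS Gini indices under one fitted chain.

    For each of M replicates, one trajectory of L transitions is drawn from
    every starting state of the chain; the expected lifetime reproductive
    success of each trajectory is computed, and the Gini index is taken
    across the starting states (unweighted: the queen state counts as one
    starting position like each decile).
    """
    if rng is None:
        rng = np.random.default_rng()
    P = chain.probabilities
    K = P.shape[0]
    queen_mode = chain.state_space.queen_mode
    qvec = state_probability_vector(weights, queen_mode)
    cum = np.cumsum(P, axis=1)
    states = np.tile(np.arange(K, dtype=np.int64), (M, 1))  # (M, K starts)
    lifetime = np.zeros((M, K))
    for _ in range(L):
        u = rng.random((M, K))
        states = (u[..., None] > cum[states]).sum(axis=-1)
        lifetime += qvec[states]
    return GiniReport(condition=condition, ginis=_gini_rows(lifetime))


def gini_distribution(
    chains_by_condition: Mapping[str, markov.TransitionMatrix],
    weights: ReproductionWeights,
    L: int = 120,
    M: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, GiniReport]:
    """Per-condition Gini distributions of expected lifetime reproductive
    success, one report per fitted chain."""
    if rng is None:
        rng = np.random.default_rng()
    return {
        name: gini_report(chain, weights, L=L, M=M, rng=rng, condition=name)
        for name, chain in chains_by_condition.items()
    }
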