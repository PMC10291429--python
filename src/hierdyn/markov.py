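"""Discrete-time Markov-chain models of hierarchy position.

Hierarchy position is discretized into ten decile states (decile 1 = lowest
10% of the hierarchy, decile 10 = highest), optionally with an eleventh
"queen" state for the single top-ranked individual.  Chains are fitted by
maximum likelihood from pooled adjacent-pair transition counts across all
recorded individual state sequences; long-run behaviour is summarized by the
steady state obtained from successive matrix powers.

States are 0-based integers internally: ``0..9`` are deciles 1..10 and
``10`` is the queen state.  :class:`StateSpace` carries the human-readable
labels (``d1..d10``, ``Q``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .society import SimRecord

__all__ = [
    "QUEEN",
    "StateSpace",
    "TransitionMatrix",
    "SteadyState",
    "TrajectorySummary",
    "ConvergenceError",
    "encode_state",
    "position_states",
    "fit_markov",
    "fit_from_record",
    "simulate_trajectories",
    "steady_state",
    "median_longrun_state",
    "summarize_trajectories",
    "representative_rank",
    "is_absorbing",
]

#: state index of the queen state in queen-mode chains
QUEEN = 10


class ConvergenceError(RuntimeError):
    """Matrix powers failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray, iterations: int):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.iterations = iterations


@dataclass(frozen=True)
class StateSpace:
    """Ordered hierarchy states, low to high: deciles 1..10, optional queen."""

    queen_mode: bool = False

    @property
    def n_states(self) -> int:
        return 11 if self.queen_mode else 10

    @property
    def labels(self) -> list[str]:
        labels = [f"d{d}" for d in range(1, 11)]
        if self.queen_mode:
            labels.append("Q")
        return labels


def encode_state(s: float, is_top: bool = False, queen_mode: bool = False) -> int:
    """Encode a standardized rank as a 0-based state index.

    Deciles follow ``min(floor(10 s), 9)`` so s = 0 is decile 1 (index 0)
    and s = 1 decile 10 (index 9).  In queen mode the top-ranked individual
    maps to the queen state instead of its decile.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"standardized rank {s} outside [0, 1]")
    if queen_mode and is_top:
        return QUEEN
    return min(int(np.floor(10.0 * s)), 9)


def position_states(n: int, queen_mode: bool = False) -> np.ndarray:
    """State index of each ordinal position 1..n (array index 0 = top).

    With n = 30 each decile contains exactly three positions.
    """
    p = np.arange(1, n + 1)
    s = (n - p) / (n - 1)
    states = np.minimum(np.floor(10.0 * s).astype(np.int8), 9)
    if queen_mode:
        states[0] = QUEEN
    return states


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities with their underlying counts."""

    counts: np.ndarray  # (K, K) int64
    probabilities: np.ndarray  # (K, K) float64, row-stochastic
    state_space: StateSpace

    @classmethod
    def from_counts(cls, counts: np.ndarray, state_space: StateSpace) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=np.int64)
        row_sums = counts.sum(axis=1)
        if row_sums.sum() == 0:
            raise ValueError("no transitions observed; cannot fit a chain")
        P = np.zeros_like(counts, dtype=float)
        for k, total in enumerate(row_sums):
            if total > 0:
                P[k] = counts[k] / total
            else:
                # unobserved state: self-loop rather than invented mobility
                warnings.warn(
                    f"state {state_space.labels[k]} never observed as a source; "
                    "assigning a self-transition",
                    stacklevel=2,
                )
                P[k, k] = 1.0
        return cls(counts=counts, probabilities=P, state_space=state_space)


def fit_markov(
    sequences: Iterable[Sequence[int]], queen_mode: bool = False
) -> TransitionMatrix:
    """Maximum-likelihood chain from pooled lag-1 transitions.

    Every adjacent pair of states within each sequence contributes one count;
    sequences are pooled (across individuals, replicates, groups).  Rows with
    no observed outgoing transition get a self-loop with a warning.
    """
    space = StateSpace(queen_mode=queen_mode)
    K = space.n_states
    counts = np.zeros((K, K), dtype=np.int64)
    for seq in sequences:
        arr = np.asarray(seq, dtype=np.int64)
        if arr.size < 2:
            continue
        if arr.min() < 0 or arr.max() >= K:
            raise ValueError(f"state outside 0..{K - 1} in sequence")
        flat = arr[:-1] * K + arr[1:]
        counts += np.bincount(flat, minlength=K * K).reshape(K, K)
    return TransitionMatrix.from_counts(counts, space)


def fit_from_record(record: "SimRecord", queen_mode: bool = False) -> TransitionMatrix:
    """Fit a chain to a simulation panel, excluding burn-in updates.

    Transitions are taken at lag 1 over each individual's recorded tenure
    (an individual contributes a count for every consecutive pair of
    post-burn-in updates at which it is alive), pooled across individuals
    and replicates.
    """
    cfg = record.config
    space = StateSpace(queen_mode=queen_mode)
    K = space.n_states
    pos_state = position_states(cfg.n, queen_mode)
    n_ids = cfg.n + cfg.n_updates
    counts = np.zeros((K, K), dtype=np.int64)
    for r in range(record.n_replicates):
        panel = record.positions[r, cfg.burn_in :]  # (T', n) ids
        T = panel.shape[0]
        state_of = np.full((T, n_ids), -1, dtype=np.int8)
        state_of[np.arange(T)[:, None], panel] = pos_state[None, :]
        a, b = state_of[:-1], state_of[1:]
        mask = (a >= 0) & (b >= 0)
        flat = a[mask].astype(np.int64) * K + b[mask]
        counts += np.bincount(flat, minlength=K * K).reshape(K, K)
    return TransitionMatrix.from_counts(counts, space)


def simulate_trajectories(
    P: np.ndarray, start_state: int, L: int, M: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw M state sequences of L transitions each from chain P.

    Returns an (M, L + 1) integer array whose first column is the start
    state.
    """
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    if not 0 <= start_state < K:
        raise ValueError(f"start state {start_state} outside 0..{K - 1}")
    cum = np.cumsum(P, axis=1)
    out = np.empty((M, L + 1), dtype=np.int8)
    states = np.full(M, start_state, dtype=np.int64)
    out[:, 0] = states
    for t in range(1, L + 1):
        u = rng.random(M)
        states = (u[:, None] > cum[states]).sum(axis=1)
        out[:, t] = states
    return out


@dataclass
class SteadyState:
    """Long-run distribution from successive matrix powers.

    ``rows`` is the converged power of the transition matrix: row k is the
    long-run distribution when starting from state k.  When all rows agree
    within the tolerance the chain is flagged ergodic and ``pi`` (the row
    average) is the steady state proper; otherwise the per-start rows carry
    the information and ``pi`` is their average, labelled non-ergodic.
    """

    rows: np.ndarray  # (K, K)
    ergodic: bool
    iterations: int
    epsilon: float

    @property
    def pi(self) -> np.ndarray:
        return self.rows.mean(axis=0)


def steady_state(
    P: np.ndarray, epsilon: float = 0.001, max_iter: int = 100_000
) -> SteadyState:
    """Iterate matrix powers until every entry changes by less than epsilon.

    Starting from the matrix itself, each iteration multiplies by P once
    more.  Convergence is entrywise on consecutive powers; ergodicity is
    declared when the rows of the limit also agree with one another within
    epsilon.
    """
    P = np.asarray(P, dtype=float)
    current = P.copy()
    for it in range(1, max_iter + 1):
        nxt = current @ P
        if np.max(np.abs(nxt - current)) < epsilon:
            rows_agree = np.max(nxt.max(axis=0) - nxt.min(axis=0)) < epsilon
            return SteadyState(rows=nxt, ergodic=bool(rows_agree), iterations=it, epsilon=epsilon)
        current = nxt
    raise ConvergenceError(
        f"matrix powers did not converge within {max_iter} iterations",
        last_iterate=current,
        iterations=max_iter,
    )


def median_longrun_state(pi: np.ndarray, state_space: StateSpace | None = None) -> int:
    """Weighted median of a long-run distribution: the lowest state (in the
    low-to-high ordering) whose cumulative probability reaches one half.

    Returns a 0-based state index (add 1 for the decile number).
    """
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("distribution must sum to 1")
    return int(np.searchsorted(np.cumsum(pi), 0.5, side="left"))


def representative_rank(states: np.ndarray) -> np.ndarray:
    """Map state indices to a representative standardized rank.

    A decile maps to its midpoint (d - 0.5) / 10; the queen state to 1.0.
    """
    states = np.asarray(states)
    return np.where(states == QUEEN, 1.0, (states + 0.5) / 10.0)


@dataclass
class TrajectorySummary:
    """Per-step mean and standard deviation of representative rank."""

    mean: np.ndarray  # (L + 1,)
    sd: np.ndarray  # (L + 1,)


def summarize_trajectories(sequences: np.ndarray) -> TrajectorySummary:
    """Summarize an (M, L + 1) array of state sequences step by step."""
    ranks = representative_rank(np.asarray(sequences))
    return TrajectorySummary(mean=ranks.mean(axis=0), sd=ranks.std(axis=0))


def is_absorbing(P: np.ndarray, state: int) -> bool:
    """Whether a state can never be left (self-transition probability exactly 1)."""
    return float(np.asarray(P)[state, state]) == 1.0
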