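"""Standardized ranks and the active/passive decomposition of rank change.

A dominance hierarchy observed repeatedly over time changes for two
qualitatively different reasons.  *Active* dynamics are changes in which an
individual reverses a previously established dyadic order — it overtakes, or
is overtaken by, a group-mate that is present in both observations.
*Passive* dynamics are changes caused purely by demography: deaths above an
individual pull it up the hierarchy, recruits inserted above push it down,
without any dyadic order being reversed.  The two components are defined so
that they always sum to the total observed change.

Positions are expressed as standardized ranks ``s`` in [0, 1], with 1 the
top of the hierarchy and 0 the bottom, so that groups of different sizes are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalHierarchy",
    "DynamicsEntry",
    "standardize_ranks",
    "decompose_dynamics",
    "decompose_hierarchy",
    "reconstruct_component_sequence",
    "net_displacement",
    "generate_fixture_hierarchy",
]


@dataclass
class LongitudinalHierarchy:
    """Ordered rosters of one social group over successive periods.

    ``periods`` maps a period label (int) to the ordered roster for that
    period, index 0 being the highest-ranking individual.
    """

    group: str
    periods: dict[int, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for period, roster in self.periods.items():
            if len(set(roster)) != len(roster):
                raise ValueError(
                    f"group {self.group!r}, period {period}: duplicate ids in roster"
                )

    @property
    def period_labels(self) -> list[int]:
        return sorted(self.periods)


@dataclass(frozen=True)
class DynamicsEntry:
    """Decomposed rank change of one individual over one period pair."""

    id: Hashable
    total: float
    active: float
    passive: float


def standardize_ranks(order: Sequence[Hashable]) -> dict[Hashable, float]:
    """Map each individual in an ordered roster to its standardized rank.

    For a roster of size ``n`` and 1-based top-down position ``p``,
    ``s = (n - p) / (n - 1)``: the top individual gets 1, the bottom 0.  A
    singleton roster gets s = 1 (its only member is the top).
    """
    n = len(order)
    if n == 0:
        raise ValueError("cannot standardize an empty roster")
    if n == 1:
        return {order[0]: 1.0}
    return {ind: (n - p) / (n - 1) for p, ind in enumerate(order, start=1)}


def decompose_dynamics(
    order_t: Sequence[Hashable], order_t1: Sequence[Hashable]
) -> list[DynamicsEntry]:
    """Decompose rank change between two observations into active + passive.

    For each individual present in both rosters, the total change is the
    difference of standardized ranks.  The active component counts dyadic
    reversals among co-present individuals: ``a_plus`` group-mates that were
    above the focal individual before and below it after, minus ``a_minus``
    for the opposite direction, converted to standardized units by dividing
    by ``n_t1 - 1`` (the later period's group size anchors the conversion).
    The passive component is the remainder, so ``total == active + passive``
    holds exactly for every entry.

    Individuals present in only one of the two rosters yield no entry.
    """
    s_t = standardize_ranks(order_t)
    s_t1 = standardize_ranks(order_t1)
    common = [ind for ind in order_t if ind in s_t1]
    if not common:
        return []

    # ranks restricted to co-present individuals, for reversal counting
    idx_t = {ind: k for k, ind in enumerate(order_t)}
    idx_t1 = {ind: k for k, ind in enumerate(order_t1)}
    denom = len(order_t1) - 1
    entries = []
    for i in common:
        a_plus = a_minus = 0
        for j in common:
            if j is i or j == i:
                continue
            before_above = idx_t[j] < idx_t[i]
            after_above = idx_t1[j] < idx_t1[i]
            if before_above and not after_above:
                a_plus += 1
            elif not before_above and after_above:
                a_minus += 1
        total = s_t1[i] - s_t[i]
        active = (a_plus - a_minus) / denom if denom > 0 else 0.0
        entries.append(DynamicsEntry(id=i, total=total, active=active, passive=total - active))
    return entries


def decompose_hierarchy(hierarchy: LongitudinalHierarchy) -> pd.DataFrame:
    """Decompose every consecutive period pair of a longitudinal hierarchy.

    Returns a tidy frame with columns
    ``group, id, period_from, period_to, total, active, passive``.
    """
    rows = []
    labels = hierarchy.period_labels
    for t_from, t_to in zip(labels[:-1], labels[1:]):
        for e in decompose_dynamics(hierarchy.periods[t_from], hierarchy.periods[t_to]):
            rows.append(
                {
                    "group": hierarchy.group,
                    "id": e.id,
                    "period_from": t_from,
                    "period_to": t_to,
                    "total": e.total,
                    "active": e.active,
                    "passive": e.passive,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "id", "period_from", "period_to", "total", "active", "passive"]
    )


def reconstruct_component_sequence(
    start_s: float, deltas: Sequence[float]
) -> np.ndarray:
    """Rebuild the rank sequence an individual would have followed under one
    component of its dynamics only.

    Starting from ``start_s``, the per-period deltas are accumulated and the
    running position clamped into [0, 1] (a component on its own can push a
    reconstructed position out of range).  The output has length
    ``len(deltas) + 1`` and includes the starting position.
    """
    if not 0.0 <= start_s <= 1.0:
        raise ValueError(f"start position {start_s} outside [0, 1]")
    out = np.empty(len(deltas) + 1)
    out[0] = start_s
    pos = start_s
    for k, d in enumerate(deltas, start=1):
        pos = min(1.0, max(0.0, pos + d))
        out[k] = pos
    return out


def net_displacement(sequence: Sequence[float]) -> float:
    """Absolute net change in standardized rank over a trajectory."""
    seq = np.asarray(sequence, dtype=float)
    if seq.size < 1:
        raise ValueError("trajectory must contain at least one position")
    return float(abs(seq[-1] - seq[0]))


def generate_fixture_hierarchy(
    n_periods: int,
    n_individuals: int,
    reversal_rate: float,
    turnover_rate: float,
    rng: np.random.Generator,
    group: str = "fixture",
) -> tuple[LongitudinalHierarchy, pd.DataFrame]:
    """Build a synthetic longitudinal hierarchy with known dynamics.

    Each period-to-period step applies a known set of *disjoint* adjacent-pair
    swaps (pure active dynamics: every swap reverses exactly one dyad and no
    other) followed by removals and compensating insertions of new
    individuals (pure passive dynamics: no surviving dyad is reversed).
    Because the two kinds of edits are structurally separated, the
    construction log is an exact ground-truth decomposition, returned as a
    frame with the same columns as :func:`decompose_hierarchy`.

    ``reversal_rate`` is the per-step probability that any given adjacent
    pair slot is swapped; ``turnover_rate`` the per-individual probability of
    being replaced.
    """
    if not (0.0 <= reversal_rate <= 1.0 and 0.0 <= turnover_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    roster = [f"i{k}" for k in range(n_individuals)]
    next_id = n_individuals
    periods: dict[int, list] = {0: list(roster)}
    truth_rows = []
    for t in range(1, n_periods):
        prev = list(roster)
        n = len(roster)
        # disjoint adjacent swaps: walk the pair slots left to right
        swap_pairs: list[tuple[Hashable, Hashable]] = []  # (mover-up, mover-down)
        k = 0
        while k < n - 1:
            if rng.random() < reversal_rate:
                hi, lo = roster[k], roster[k + 1]
                roster[k], roster[k + 1] = lo, hi
                swap_pairs.append((lo, hi))
                k += 2  # keep swaps disjoint
            else:
                k += 1
        # turnover: replace individuals, preserving surviving dyad orders
        n_out = int(rng.binomial(n, turnover_rate))
        for _ in range(n_out):
            roster.pop(int(rng.integers(len(roster))))
        for _ in range(n_out):
            roster.insert(int(rng.integers(len(roster) + 1)), f"i{next_id}")
            next_id += 1
        periods[t] = list(roster)

        s_prev = standardize_ranks(prev)
        s_now = standardize_ranks(roster)
        denom = len(roster) - 1
        # a reversal is active only if both dyad members survive the period
        swapped: dict[Hashable, int] = {}
        for up, down in swap_pairs:
            if up in s_now and down in s_now:
                swapped[up] = +1
                swapped[down] = -1
        for ind in prev:
            if ind not in s_now:
                continue
            total = s_now[ind] - s_prev[ind]
            active = swapped.get(ind, 0) / denom if denom > 0 else 0.0
            truth_rows.append(
                {
                    "group": group,
                    "id": ind,
                    "period_from": t - 1,
                    "period_to": t,
                    "total": total,
                    "active": active,
                    "passive": total - active,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["group", "id", "period_from", "period_to", "total", "active", "passive"],
    )
    return LongitudinalHierarchy(group=group, periods=periods), truth
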