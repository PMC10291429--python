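"""End-to-end orchestration of the simulated-society analysis.

:func:`reproduce` runs the full experiment: six society specifications
(maternal rank inheritance with and without rank effects on reproduction,
random placement with and without rank effects, primogeniture, and
parent–offspring rank correlation), each with the configured number of
replicates.  For every condition it fits a ten-state decile chain and an
eleven-state queen-mode chain, computes steady states and median long-run
states, summarizes expected lifetime trajectories, and — for the four
rank-effect inheritance variants — the distribution of Gini indices of
expected lifetime reproductive success.  All outputs land in one directory
with a manifest recording seeds and checksums.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, inequality, io, markov, society

__all__ = ["CONDITIONS", "GINI_CONDITIONS", "ConditionResult", "run_condition", "reproduce"]

logger = logging.getLogger(__name__)

#: the six society specifications: name -> (inheritance regime, rank effect)
CONDITIONS: dict[str, tuple[society.Inheritance, bool]] = {
    "mri_rank": (society.Inheritance.MRI_YA, True),
    "mri_norank": (society.Inheritance.MRI_YA, False),
    "none_rank": (society.Inheritance.NONE, True),
    "none_norank": (society.Inheritance.NONE, False),
    "primogeniture_rank": (society.Inheritance.PRIMOGENITURE, True),
    "correlation_rank": (society.Inheritance.CORRELATION, True),
}

#: conditions entering the reproductive-inequality comparison (rank effects on)
GINI_CONDITIONS = ["mri_rank", "primogeniture_rank", "none_rank", "correlation_rank"]


@dataclasses.dataclass
class ConditionResult:
    """Everything computed for one society specification."""

    name: str
    record: society.SimRecord
    chain10: markov.TransitionMatrix
    chain_queen: markov.TransitionMatrix
    steady10: markov.SteadyState
    steady_queen: markov.SteadyState
    median_decile: int  # 1-based decile of the 10-state steady state
    queen_absorbing: bool
    trajectory_summary: markov.TrajectorySummary | None = None
    gini: inequality.GiniReport | None = None


def run_condition(
    name: str,
    inheritance: society.Inheritance,
    rank_effect: bool,
    config: io.RunConfig,
    seed: int,
    with_gini: bool = False,
    summary_start: int | None = None,
    epsilon: float | None = None,
) -> ConditionResult:
    """Simulate one condition, fit its chains, and summarize the long run."""
    eps = config.epsilon if epsilon is None else epsilon
    sim_cfg = society.SimConfig(
        n=config.n,
        inheritance=inheritance,
        rank_effect=rank_effect,
        n_updates=config.n_updates,
        burn_in=config.burn_in,
        n_replicates=config.n_replicates,
        seed=seed,
        reproduction_slope=config.reproduction_slope,
    )
    logger.info("condition %s: simulating %d replicates", name, sim_cfg.n_replicates)
    record = society.run_simulation(sim_cfg)
    chain10 = markov.fit_from_record(record, queen_mode=False)
    chain_queen = markov.fit_from_record(record, queen_mode=True)
    steady10 = markov.steady_state(chain10.probabilities, epsilon=eps)
    steady_queen = markov.steady_state(chain_queen.probabilities, epsilon=eps)
    median = markov.median_longrun_state(steady10.pi) + 1
    absorbing = markov.is_absorbing(chain_queen.probabilities, markov.QUEEN)

    result = ConditionResult(
        name=name,
        record=record,
        chain10=chain10,
        chain_queen=chain_queen,
        steady10=steady10,
        steady_queen=steady_queen,
        median_decile=median,
        queen_absorbing=absorbing,
    )
    if with_gini:
        weights = inequality.reproduction_weights(config.n, sim_cfg.resolved_slope())
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed).spawn(1)[0]))
        result.gini = inequality.gini_report(
            chain_queen,
            weights,
            L=config.trajectory_length,
            M=config.n_trajectories,
            rng=rng,
            condition=name,
        )
        logger.info(
            "condition %s: mean lifetime-RS Gini %.4f (sd %.4f)",
            name,
            result.gini.mean,
            result.gini.sd,
        )
    if summary_start is not None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed).spawn(2)[1]))
        seqs = markov.simulate_trajectories(
            chain_queen.probabilities,
            summary_start,
            L=config.trajectory_length,
            M=config.n_trajectories,
            rng=rng,
        )
        result.trajectory_summary = markov.summarize_trajectories(seqs)
    return result


def reproduce(config: io.RunConfig) -> io.RunManifest:
    """Run the full six-condition analysis and write all artifacts.

    Deterministic given ``config.seed``: per-condition seeds are spawned
    from the master seed in a fixed order, so two runs with the same config
    produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    condition_seeds = {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(CONDITIONS, master.spawn(len(CONDITIONS)))
    }
    manifest = io.RunManifest(
        config=dataclasses.asdict(config),
        package_version=__version__,
        stage_seeds=condition_seeds,
    )

    rows = []
    for name, (inheritance, rank_effect) in CONDITIONS.items():
        res = run_condition(
            name,
            inheritance,
            rank_effect,
            config,
            seed=condition_seeds[name],
            with_gini=name in GINI_CONDITIONS,
        )
        io.write_transition_matrix(res.chain10, out / f"{name}.chain10")
        io.write_transition_matrix(res.chain_queen, out / f"{name}.chainQ")
        io.write_steady_state(res.steady10, res.chain10.state_space, out / f"{name}.steady10.json")
        io.write_steady_state(
            res.steady_queen, res.chain_queen.state_space, out / f"{name}.steadyQ.json"
        )
        row = {
            "condition": name,
            "inheritance": inheritance.value,
            "rank_effect": rank_effect,
            "median_longrun_decile": res.median_decile,
            "ergodic_10state": res.steady10.ergodic,
            "queen_absorbing": res.queen_absorbing,
            "mean_gini": res.gini.mean if res.gini else np.nan,
            "sd_gini": res.gini.sd if res.gini else np.nan,
        }
        if res.gini is not None:
            pd.DataFrame(
                {
                    "condition": name,
                    "replicate": np.arange(res.gini.ginis.size),
                    "gini": res.gini.ginis,
                }
            ).to_csv(out / f"{name}.gini.csv", index=False, float_format=io.FLOAT_FORMAT)
        rows.append(row)

    results = pd.DataFrame(rows)
    results_path = out / "results.csv"
    results.to_csv(results_path, index=False, float_format=io.FLOAT_FORMAT)
    (out / "config.yaml").write_text(config.to_yaml())

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest.checksums[path.name] = io.file_sha256(path)
    manifest.write(out / "manifest.json")
    return manifest
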