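"""Unified optimizer driver for the de novo design benchmark.

Every optimizer consumes objective evaluations through the budget ledger
and halts when the budget is exhausted; the run emits the ledger, the
best/25th-best trajectories and a config snapshot sufficient for an exact
re-run.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from typing import Callable, Optional, Sequence

import numpy as np

from ..benchmarks import BudgetExhausted, EvaluationLedger, trajectory
from .bo import Acquisition, BOConfig, run_gp_bo
from .fss import random_baseline
from .graph_ga import GAConfig, ScoredMolecule, graph_ga_generation
from .selfies_ga import selfies_ga_generation

OPTIMIZERS = ("graph_ga", "selfies_ga", "gp_bo_ucb", "gp_bo_ei", "random")


def initial_population(dataset: tuple[Sequence[str], Sequence[float]],
                       size: int, mode: str = "best",
                       seed: int = 0) -> list[ScoredMolecule]:
    """Seed a GA population from the dataset: best-by-objective or random."""
    smiles, values = list(dataset[0]), list(dataset[1])
    if mode == "best":
        order = np.argsort(np.asarray(values, dtype=float), kind="stable")[:size]
    elif mode == "random":
        order = np.random.default_rng(seed).choice(len(smiles),
                                                   size=min(size, len(smiles)),
                                                   replace=False)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return [ScoredMolecule(smiles=smiles[i], value=float(values[i])) for i in order]


def run_optimizer(name: str,
                  dataset: tuple[Sequence[str], Sequence[float]],
                  objective_fn: Callable[[str], float],
                  budget: int,
                  seed: int = 0,
                  ga_config: Optional[GAConfig] = None,
                  bo_config: Optional[BOConfig] = None,
                  init_mode: str = "best") -> dict:
    """Run one baseline under a fresh ledger and return run artifacts.

    ``objective_fn`` maps SMILES to a value (lower better); it is wrapped by
    the ledger so cache hits are free and the budget is enforced.  The
    returned dict holds the ledger, trajectories for k = 1 and 25, and the
    config snapshot.
    """
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {OPTIMIZERS}")
    ledger = EvaluationLedger(budget=budget)

    def budgeted(smiles: str) -> float:
        return ledger.evaluate(smiles, objective_fn)

    config_snapshot: dict = {"optimizer": name, "budget": budget, "seed": seed,
                             "init_mode": init_mode}
    try:
        if name == "random":
            for smi in random_baseline(list(dataset[0]),
                                       min(budget, len(dataset[0])), seed=seed):
                budgeted(smi)
        elif name in ("graph_ga", "selfies_ga"):
            config = ga_config or GAConfig(seed=seed)
            config_snapshot["ga"] = asdict(config)
            rng = np.random.default_rng(seed)
            population = initial_population(dataset, config.population_size,
                                            init_mode, seed)
            step = graph_ga_generation if name == "graph_ga" else selfies_ga_generation
            stall = 0
            while ledger.unique_calls < budget and stall < 50:
                before = ledger.unique_calls
                population = step(population, config, budgeted, rng)
                stall = stall + 1 if ledger.unique_calls == before else 0
        else:
            acq = Acquisition.EI if name == "gp_bo_ei" else Acquisition.UCB
            config = bo_config or BOConfig(seed=seed)
            if config.acquisition is not acq:
                from dataclasses import replace
                config = replace(config, acquisition=acq)
            config_snapshot["bo"] = {**asdict(config),
                                     "acquisition": config.acquisition.value,
                                     "fingerprint_kind": config.fingerprint_kind.value}
            n_iter = math.ceil(budget / config.batch_size) + 1
            run_gp_bo(dataset, budgeted, n_iterations=n_iter, config=config)
    except BudgetExhausted:
        pass
    return {
        "ledger": ledger,
        "best": ledger.best(),
        "trajectory_best": trajectory(ledger, k=1),
        "trajectory_25": trajectory(ledger, k=25),
        "config": config_snapshot,
    }
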