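"""Bayesian optimization with a Tanimoto-kernel GP surrogate.

The GP is trained once on a subset of the dataset (the points with the
smallest objective values plus a random complement); hyperparameters stay
fixed afterwards.  Each iteration proposes a batch of new molecules by
maximizing an acquisition function — upper confidence bound (mu + beta *
sigma) or expected improvement — over candidates generated with the graph
GA's variation operators on the acquisition surface.  Because objectives
are minimized, the GP models the *negated* objective, so "maximize
mu + beta * sigma" applies literally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.stats import norm

from ..chemspace import FingerprintKind, fingerprint, fingerprint_array
from .gp import GPHyperparams, TanimotoGPState, gp_fit
from .graph_ga import _rank_probabilities, make_child

logger = logging.getLogger(__name__)


class Acquisition(Enum):
    UCB = "ucb"
    EI = "ei"


@dataclass(frozen=True)
class BOConfig:
    acquisition: Acquisition = Acquisition.UCB
    beta: float = 10.0
    batch_size: int = 5
    n_best_train: int = 2000
    n_random_train: int = 3000
    inner_ga_offspring: int = 1000
    inner_ga_generations: int = 25
    seed: int = 0
    fingerprint_kind: FingerprintKind = FingerprintKind.PATH6


def bo_training_subset(smiles: Sequence[str], values: Sequence[float],
                       config: BOConfig) -> list[int]:
    """Indices of the GP training subset: best-n plus random-n from the rest.

    Falls back to the whole dataset (with a log record) when it is smaller
    than the requested subset.
    """
    n = len(smiles)
    want = config.n_best_train + config.n_random_train
    if n < want:
        logger.warning("dataset of %d smaller than requested subset %d; using all", n, want)
        return list(range(n))
    vals = np.asarray(values, dtype=float)
    order = np.argsort(vals, kind="stable")
    best = list(order[:config.n_best_train])
    rest = order[config.n_best_train:]
    rng = np.random.default_rng(config.seed)
    randoms = rng.choice(rest, size=config.n_random_train, replace=False)
    return sorted(best + list(randoms))


def ucb(mean: np.ndarray, std: np.ndarray, beta: float) -> np.ndarray:
    return mean + beta * std


def expected_improvement(mean: np.ndarray, std: np.ndarray, best: float) -> np.ndarray:
    """EI of exceeding ``best`` for a maximized quantity, closed form."""
    std = np.maximum(std, 1e-12)
    z = (mean - best) / std
    return (mean - best) * norm.cdf(z) + std * norm.pdf(z)


def _acquisition_values(state: TanimotoGPState, fps_arr: np.ndarray,
                        config: BOConfig) -> np.ndarray:
    mean, var = state.predict(fps_arr)
    std = np.sqrt(var)
    if config.acquisition is Acquisition.UCB:
        return ucb(mean, std, config.beta)
    return expected_improvement(mean, std, float(state.y.max()))


def bo_select_batch(state: TanimotoGPState, evaluated: set[str],
                    seed_population: list[tuple[str, float]],
                    config: BOConfig,
                    rng: np.random.Generator) -> list[str]:
    """Propose ``batch_size`` distinct, not-yet-evaluated molecules.

    The acquisition surface is explored with the graph GA's variation
    operators (crossover + mutation), batch-scoring each generation's
    offspring with the GP.  If the search surfaces too few new molecules,
    the batch is filled with the best unevaluated individuals seen.
    """
    population = [(s, a) for s, a in seed_population]
    seen: dict[str, float] = dict(population)

    for _ in range(config.inner_ga_generations):
        mols, acqs = [], []
        for smi, acq in population:
            mol = Chem.MolFromSmiles(smi)
            if mol is not None:
                mols.append(mol)
                acqs.append(acq)
        if not mols:
            break
        probs = _rank_probabilities(-np.asarray(acqs))  # maximize acquisition
        children = []
        for _ in range(config.inner_ga_offspring):
            smi = make_child(mols, probs, mutation_rate=0.05, rng=rng)
            if smi is not None and smi not in seen:
                children.append(smi)
        children = sorted(set(children))
        if not children:
            continue
        fps = fingerprint_array([fingerprint(s, config.fingerprint_kind)
                                 for s in children])
        values = _acquisition_values(state, fps, config)
        for smi, val in zip(children, values):
            seen[smi] = float(val)
        population = sorted(seen.items(), key=lambda kv: -kv[1])[:50]

    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
    batch = [s for s, _ in ranked if s not in evaluated][:config.batch_size]
    if len(batch) < config.batch_size:
        logger.warning("acquisition search yielded only %d new molecules", len(batch))
    return batch


def run_gp_bo(dataset: tuple[Sequence[str], Sequence[float]],
              objective: Callable[[str], float],
              n_iterations: int,
              config: BOConfig = BOConfig(),
              init: GPHyperparams = GPHyperparams(amplitude=1.0, noise=0.1),
              stop: Optional[Callable[[], bool]] = None) -> dict:
    """Full GP-BO loop: subset, single hyperparameter fit, batched proposals.

    ``objective`` is the budgeted evaluation function (it may raise to end
    the run); the GP models the negated objective.  Returns a summary with
    the fitted hyperparameters and all proposed molecules.
    """
    smiles, values = list(dataset[0]), list(dataset[1])
    rng = np.random.default_rng(config.seed)
    subset = bo_training_subset(smiles, values, config)
    sub_smiles = [smiles[i] for i in subset]
    sub_y = np.array([-values[i] for i in subset])  # negate: GP maximizes
    fps = fingerprint_array([fingerprint(s, config.fingerprint_kind)
                             for s in sub_smiles])
    params = gp_fit(fps, sub_y, replace(init, constant_mean=float(sub_y.mean())))
    state = TanimotoGPState(params, fps, sub_y)
    evaluated: set[str] = set(sub_smiles)
    proposed: list[tuple[str, float]] = []

    seed_pop = sorted(zip(sub_smiles, sub_y), key=lambda kv: -kv[1])[:50]
    seed_acq = [(s, float(v)) for s, v in seed_pop]

    for _ in range(n_iterations):
        if stop is not None and stop():
            break
        batch = bo_select_batch(state, evaluated, seed_acq, config, rng)
        if not batch:
            break
        new_fps, new_y = [], []
        try:
            for smi in batch:
                val = objective(smi)
                evaluated.add(smi)
                proposed.append((smi, val))
                if math.isfinite(val):
                    new_fps.append(fingerprint(smi, config.fingerprint_kind))
                    new_y.append(-val)
        finally:
            if new_fps:
                state.add(fingerprint_array(new_fps), np.array(new_y))
    return {"hyperparams": params, "proposed": proposed}
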