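"""Mutation-only genetic algorithm on robust token strings.

Each child differs from its parent by exactly one token edit (insert,
delete, or replace); because the representation is robust, every edit
decodes to a valid molecule.  Selection is the same elitist scheme as the
graph GA.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from . import selfies_lite as sl
from .graph_ga import GAConfig, ScoredMolecule, _rank_probabilities


def mutate_tokens(tokens: list[str], rng: np.random.Generator,
                  alphabet: Optional[list[str]] = None) -> list[str]:
    """Apply exactly one random token edit."""
    alphabet = alphabet or sl.default_alphabet()
    out = list(tokens)
    op = int(rng.integers(3))
    if op == 0 and len(out) > 1:          # delete
        out.pop(int(rng.integers(len(out))))
    elif op == 1:                          # insert
        out.insert(int(rng.integers(len(out) + 1)),
                   alphabet[int(rng.integers(len(alphabet)))])
    else:                                  # replace (always with a different token)
        pos = int(rng.integers(len(out)))
        choices = [t for t in alphabet if t != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return out


def selfies_ga_generation(population: list[ScoredMolecule], config: GAConfig,
                          objective: Callable[[str], float],
                          rng: Optional[np.random.Generator] = None
                          ) -> list[ScoredMolecule]:
    """One generation of the token GA (single-edit mutation, elitist survival).

    Molecules that cannot be encoded in the robust grammar are skipped when
    sampled as parents.
    """
    if not population:
        raise ValueError("empty population")
    rng = rng or np.random.default_rng(config.seed)
    values = np.array([m.value for m in population])
    probs = _rank_probabilities(values)
    alphabet = sl.default_alphabet()

    pool = {m.smiles: m.value for m in population}
    for _ in range(config.offspring_size):
        parent = population[int(rng.choice(len(population), p=probs))]
        try:
            tokens = sl.encode(parent.smiles)
        except sl.EncodingError:
            continue
        child = sl.decode(mutate_tokens(tokens, rng, alphabet))
        if child is None or child in pool:
            continue
        pool[child] = objective(child)
    survivors = sorted(pool.items(), key=lambda kv: (kv[1], kv[0]))[:config.population_size]
    return [ScoredMolecule(smiles=s, value=v) for s, v in survivors]
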