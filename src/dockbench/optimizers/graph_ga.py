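"""Graph-based genetic algorithm over molecules.

Offspring are produced by fragment recombination (each parent is cut at a
random acyclic single bond and complementary fragments are joined) followed
by an optional point mutation on the molecular graph (element swap, atom
insertion/deletion, bond-order change).  Survivor selection is elitist:
the best ``population_size`` of parents plus children carry over, so the
best objective value never worsens across generations.  Every emitted
SMILES is a valid, single-fragment molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from rdkit import Chem, RDLogger

# variation operators probe chemically invalid edits by design; silence the
# per-attempt sanitize errors RDKit would otherwise print
RDLogger.DisableLog("rdApp.error")

MAX_HEAVY_ATOMS = 60
_MUTATION_ELEMENTS = ["C", "N", "O", "F", "S", "Cl"]
_VALENCE_CAP = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 250
    offspring_size: int = 25
    mutation_rate: float = 0.01
    seed: int = 0


@dataclass(frozen=True)
class ScoredMolecule:
    smiles: str
    value: float


def canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _sanitized(rw: Chem.RWMol) -> Optional[Chem.Mol]:
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if mol.GetNumAtoms() == 0 or len(Chem.GetMolFrags(mol)) != 1:
        return None
    if sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1) > MAX_HEAVY_ATOMS:
        return None
    return mol


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------

def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    out = []
    for bond in mol.GetBonds():
        if (bond.GetBondType() == Chem.BondType.SINGLE and not bond.IsInRing()
                and bond.GetBeginAtom().GetAtomicNum() > 1
                and bond.GetEndAtom().GetAtomicNum() > 1):
            out.append(bond.GetIdx())
    return out


def _cut_fragments(mol: Chem.Mol, bond_idx: int) -> Optional[list[Chem.Mol]]:
    try:
        frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True,
                                    dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    except Exception:
        return None
    return list(pieces) if len(pieces) == 2 else None


def _join_fragments(fa: Chem.Mol, fb: Chem.Mol) -> Optional[Chem.Mol]:
    combo = Chem.RWMol(Chem.CombineMols(fa, fb))
    dummies = [a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 2:
        return None
    anchors = []
    for d in dummies:
        nbrs = combo.GetAtomWithIdx(d).GetNeighbors()
        if len(nbrs) != 1:
            return None
        anchors.append(nbrs[0].GetIdx())
    combo.AddBond(anchors[0], anchors[1], Chem.BondType.SINGLE)
    for d in sorted(dummies, reverse=True):
        combo.RemoveAtom(d)
    return _sanitized(combo)


def crossover(parent_a: Chem.Mol, parent_b: Chem.Mol,
              rng: np.random.Generator, max_tries: int = 10) -> Optional[Chem.Mol]:
    """Recombine two parents by cutting each at an acyclic single bond.

    Returns ``None`` when no valid child could be built (callers then fall
    back to cloning a parent)."""
    bonds_a, bonds_b = _cuttable_bonds(parent_a), _cuttable_bonds(parent_b)
    if not bonds_a or not bonds_b:
        return None
    for _ in range(max_tries):
        fa = _cut_fragments(parent_a, int(rng.choice(bonds_a)))
        fb = _cut_fragments(parent_b, int(rng.choice(bonds_b)))
        if fa is None or fb is None:
            continue
        child = _join_fragments(fa[int(rng.integers(2))], fb[int(rng.integers(2))])
        if child is not None:
            return child
    return None


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def _mut_swap_element(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    idxs = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() > 1]
    if not idxs:
        return False
    atom = rw.GetAtomWithIdx(int(rng.choice(idxs)))
    choices = [e for e in _MUTATION_ELEMENTS
               if e != atom.GetSymbol()
               and _VALENCE_CAP[e] >= atom.GetTotalValence() - atom.GetTotalNumHs()]
    if not choices:
        return False
    atom.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(
        str(rng.choice(choices))))
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)
    return True


def _mut_append_atom(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    idxs = [a.GetIdx() for a in rw.GetAtoms()
            if a.GetAtomicNum() > 1 and a.GetTotalNumHs() > 0]
    if not idxs:
        return False
    anchor = int(rng.choice(idxs))
    new = rw.AddAtom(Chem.Atom(str(rng.choice(["C", "N", "O", "F"]))))
    rw.AddBond(anchor, new, Chem.BondType.SINGLE)
    return True


def _mut_delete_atom(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    idxs = [a.GetIdx() for a in rw.GetAtoms()
            if a.GetAtomicNum() > 1
            and sum(1 for n in a.GetNeighbors() if n.GetAtomicNum() > 1) == 1]
    if len(idxs) == 0 or rw.GetNumAtoms() <= 2:
        return False
    rw.RemoveAtom(int(rng.choice(idxs)))
    return True


def _mut_bond_order(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    bonds = [b.GetIdx() for b in rw.GetBonds()
             if b.GetBeginAtom().GetAtomicNum() > 1
             and b.GetEndAtom().GetAtomicNum() > 1
             and not b.GetIsAromatic()]
    if not bonds:
        return False
    bond = rw.GetBondWithIdx(int(rng.choice(bonds)))
    if bond.GetBondType() == Chem.BondType.SINGLE:
        ok = (bond.GetBeginAtom().GetTotalNumHs() > 0
              and bond.GetEndAtom().GetTotalNumHs() > 0)
        if not ok:
            return False
        bond.SetBondType(Chem.BondType.DOUBLE)
    elif bond.GetBondType() == Chem.BondType.DOUBLE:
        bond.SetBondType(Chem.BondType.SINGLE)
    else:
        return False
    return True


_MUTATIONS = [_mut_swap_element, _mut_append_atom, _mut_delete_atom, _mut_bond_order]


def mutate(mol: Chem.Mol, rng: np.random.Generator, max_tries: int = 10) -> Optional[Chem.Mol]:
    """One random graph edit; returns a valid molecule or ``None``."""
    for _ in range(max_tries):
        rw = Chem.RWMol(mol)
        op = _MUTATIONS[int(rng.integers(len(_MUTATIONS)))]
        try:
            if not op(rw, rng):
                continue
        except Exception:
            continue
        child = _sanitized(rw)
        if child is not None:
            return child
    return None


# ---------------------------------------------------------------------------
# Generation step
# ---------------------------------------------------------------------------

def _rank_probabilities(values: np.ndarray) -> np.ndarray:
    # fitness-proportional on rank-transformed scores (minimization: rank 0 = best)
    order = np.argsort(values, kind="stable")
    weights = np.empty(len(values))
    weights[order] = len(values) - np.arange(len(values), dtype=float)
    return weights / weights.sum()


def make_child(parents: list[Chem.Mol], probs: np.ndarray, mutation_rate: float,
               rng: np.random.Generator) -> Optional[str]:
    """Crossover of two sampled parents plus an optional mutation."""
    i, j = rng.choice(len(parents), size=2, p=probs)
    child = crossover(parents[i], parents[j], rng)
    if child is None:
        child = Chem.Mol(parents[i])  # bounded retries failed: clone the parent
    if rng.random() < mutation_rate:
        mutated = mutate(child, rng)
        if mutated is not None:
            child = mutated
    return Chem.MolToSmiles(child)


def graph_ga_generation(population: list[ScoredMolecule], config: GAConfig,
                        objective: Callable[[str], float],
                        rng: Optional[np.random.Generator] = None
                        ) -> list[ScoredMolecule]:
    """Advance the population by one generation.

    ``objective`` maps a canonical SMILES to a value (lower is better) and
    may enforce an evaluation budget by raising.  Children duplicating an
    existing population member are re-scored through the objective (callers
    typically cache) but never duplicated in the survivor list.
    """
    if not population:
        raise ValueError("empty population")
    rng = rng or np.random.default_rng(config.seed)
    parents = [Chem.MolFromSmiles(m.smiles) for m in population]
    keep = [i for i, m in enumerate(parents) if m is not None]
    parents = [parents[i] for i in keep]
    values = np.array([population[i].value for i in keep])
    probs = _rank_probabilities(values)

    pool = {m.smiles: m.value for m in population}
    for _ in range(config.offspring_size):
        smi = make_child(parents, probs, config.mutation_rate, rng)
        if smi is None or smi in pool:
            continue
        pool[smi] = objective(smi)
    survivors = sorted(pool.items(), key=lambda kv: (kv[1], kv[0]))[:config.population_size]
    return [ScoredMolecule(smiles=s, value=v) for s, v in survivors]
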