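"""Chemical-space tooling: fingerprints, Jaccard DBSCAN clustering, generic
Murcko scaffolds, cluster-respecting train/test splits, and druglikeness
profiles.

Cluster splitting exists because chemical datasets are full of close
analogues: a random split puts near-duplicates on both sides and inflates
test performance.  Splitting whole density clusters (or scaffold groups)
avoids that leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import (Crippen, Descriptors, Lipinski, QED,
                        rdFingerprintGenerator, rdMolDescriptors)
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import DBSCAN


class FingerprintKind(Enum):
    PATH6 = "PATH6"            # RDKit path fingerprint, max path length 6
    MORGAN2_1024 = "MORGAN2_1024"  # 1024-bit Morgan, radius 2


_MORGAN1024 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    kind: FingerprintKind
    nbits: int


def fingerprint(smiles: str, kind: FingerprintKind = FingerprintKind.PATH6) -> Fingerprint:
    """Binary fingerprint of a molecule; invariant to input atom ordering."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if kind is FingerprintKind.PATH6:
        bv = Chem.RDKFingerprint(mol, maxPath=6, fpSize=2048)
    else:
        bv = _MORGAN1024.GetFingerprint(mol)
    bits = frozenset(bv.GetOnBits())
    if not bits:
        # bondless molecules (single heavy atom) set one element-derived bit
        # so identity distance is 0 but distinct atoms stay distinguishable
        mol_no_h = Chem.RemoveHs(mol)
        anum = mol_no_h.GetAtomWithIdx(0).GetAtomicNum() if mol_no_h.GetNumAtoms() else 1
        bits = frozenset({anum % bv.GetNumBits()})
    return Fingerprint(bits=bits, kind=kind, nbits=bv.GetNumBits())


def fingerprint_array(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense float32 matrix (n x nbits) for vectorized similarity math."""
    if not fps:
        return np.zeros((0, 0), dtype=np.float32)
    n, m = len(fps), fps[0].nbits
    arr = np.zeros((n, m), dtype=np.float32)
    for i, fp in enumerate(fps):
        arr[i, list(fp.bits)] = 1.0
    return arr


def jaccard_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a&b| / |a|b|; 0 iff equal bitsets, 1 for disjoint non-empty sets."""
    if a.kind is not b.kind:
        raise ValueError("fingerprint kinds differ")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return 1.0 - len(a.bits & b.bits) / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between rows of two binary matrices."""
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-molecule integer; -1 = noise

    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0


def dbscan_jaccard(fps: Sequence[Fingerprint], eps: float = 0.25,
                   min_core_neighbors: int = 5) -> ClusterLabels:
    """Density clustering under the Jaccard metric.

    ``min_core_neighbors`` follows the usual DBSCAN ``min_samples``
    convention: a molecule is a core point when at least that many molecules
    (itself included) lie within ``eps``.  Cluster ids are relabelled to be
    contiguous from 0 in order of first appearance; noise keeps label -1.
    """
    if not fps:
        raise ValueError("empty fingerprint list")
    arr = fingerprint_array(fps)
    dist = 1.0 - tanimoto_matrix(arr, arr)
    np.clip(dist, 0.0, 1.0, out=dist)
    raw = DBSCAN(eps=eps, min_samples=min_core_neighbors,
                 metric="precomputed").fit_predict(dist)
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab == -1:
            labels[i] = -1
        else:
            labels[i] = remap.setdefault(lab, len(remap))
    return ClusterLabels(labels=labels)


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldKey:
    generic_scaffold: str  # canonical SMILES; empty for acyclic molecules


def generic_murcko_scaffold(smiles: str) -> ScaffoldKey:
    """Generic Bemis-Murcko scaffold key.

    The molecule is reduced to its ring systems plus the linkers between
    them; every heavy atom is then replaced by carbon and every bond by a
    single bond, so decorated analogues and heteroaromatic variants share a
    key.  Acyclic molecules map to the empty scaffold.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        return ScaffoldKey(generic_scaffold="")
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return ScaffoldKey(generic_scaffold=Chem.MolToSmiles(generic))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

class DegenerateClusteringError(ValueError):
    """Raised when a split is requested on a single-cluster labelling."""


def cluster_split(labels: ClusterLabels, test_fraction: float,
                  seed: int = 0) -> tuple[list[int], list[int]]:
    """Partition molecule indices so no cluster straddles the split.

    Cluster ids (noise points count as singleton groups) are shuffled by the
    seed and assigned whole to the test side until its share reaches the
    requested fraction.  The realized share stays within a few points of the
    request whenever no single cluster dominates.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labs = labels.labels
    n = len(labs)
    groups: dict[object, list[int]] = {}
    for i, lab in enumerate(labs):
        key = ("noise", i) if lab == -1 else ("cluster", int(lab))
        groups.setdefault(key, []).append(i)
    if len(groups) < 2:
        raise DegenerateClusteringError(
            "all molecules fall in one cluster; a cluster split is not possible")
    order = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    target = test_fraction * n
    test: list[int] = []
    for key in order:
        if len(test) >= target:
            break
        test.extend(groups[key])
    test_set = set(test)
    train = [i for i in range(n) if i not in test_set]
    return train, sorted(test)


# ---------------------------------------------------------------------------
# Druglikeness profile
# ---------------------------------------------------------------------------

def property_profile(smiles: str) -> dict:
    """logP, MW, H-bond donors/acceptors, rotatable bonds, QED and the
    Lipinski rule-of-five verdict for one molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    hbd = Lipinski.NumHDonors(mol)
    hba = Lipinski.NumHAcceptors(mol)
    return {
        "logP": logp,
        "MW": mw,
        "HBD": hbd,
        "HBA": hba,
        # non-strict convention: any acyclic single bond between two
        # non-terminal heavy atoms; consistent with the ligand torsion tree
        "RB": rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.NonStrict),
        "QED": QED.qed(mol),
        "lipinski_pass": bool(mw <= 500 and logp <= 5 and hbd <= 5 and hba <= 10),
    }
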