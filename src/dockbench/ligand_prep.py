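"""Ligand preparation: SMILES -> validated, protonated, 3D-embedded, charged record.

The pipeline mirrors standard docking practice: sanity checks (single
fragment, no radicals), (de)protonation of ionizable groups at physiological
pH, a single ETKDG conformer refined with MMFF94, Gasteiger partial charges,
and serialization to the AutoDock PDBQT dialect with a torsion tree.  Every
step is deterministic given (input SMILES, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms  # noqa: F401  (transforms used by docking)


class RejectionCode(Enum):
    UNPARSEABLE = "UNPARSEABLE"
    MULTI_FRAGMENT = "MULTI_FRAGMENT"
    RADICAL = "RADICAL"
    EMBED_FAILED = "EMBED_FAILED"
    REFINE_FAILED = "REFINE_FAILED"


@dataclass(frozen=True)
class RejectionReason:
    code: RejectionCode
    detail: str = ""


@dataclass
class PreparedLigand:
    """A molecule ready for docking.

    Coordinates are in Angstrom; partial charges in units of the elementary
    charge.  ``mol`` carries the underlying RDKit molecule (explicit
    hydrogens, one conformer) used for PDBQT serialization.
    """

    input_smiles: str
    canonical_smiles: str
    atom_elements: list[str]
    coords: np.ndarray
    partial_charges: np.ndarray
    net_charge: int
    seed: int
    mol: Chem.Mol = field(repr=False, compare=False, default=None)


PrepOutcome = Union[PreparedLigand, RejectionReason]


def validate_ligand(smiles: str) -> Optional[RejectionReason]:
    """Sanity-check a SMILES string.

    Returns ``None`` when the ligand is acceptable, otherwise a
    :class:`RejectionReason`.  Rejection is a value, never an exception:
    multi-fragment inputs and radical species are refused up front because
    docking a salt or an open-shell species is not meaningful.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return RejectionReason(RejectionCode.UNPARSEABLE, f"RDKit could not parse {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        return RejectionReason(
            RejectionCode.MULTI_FRAGMENT,
            f"{len(Chem.GetMolFrags(mol))} fragments",
        )
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()):
        return RejectionReason(RejectionCode.RADICAL, "radical electrons present")
    return None


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

class ProtonationEngine:
    """Interface for pH-dependent protonation adjustment.

    The default implementation is a fixed, documented transform table; any
    engine with an ``adjust(smiles, ph)`` method may be swapped in.
    """

    def adjust(self, smiles: str, ph: float) -> str:  # pragma: no cover - interface
        raise NotImplementedError


# Each rule: (SMARTS, index of the atom to (de)protonate within the match,
# pKa, "acid" | "base").  An acid rule fires when pKa < pH (deprotonate);
# a base rule fires when pKa > pH (protonate).  Patterns are written so they
# do not match the already-transformed product, which makes the table
# idempotent by construction.
_PROTONATION_RULES: list[tuple[str, int, float, str]] = [
    # carboxylic acids -> carboxylate
    ("[CX3](=O)[OX2H1]", 2, 4.8, "acid"),
    # sulfonic acids -> sulfonate
    ("[SX4](=O)(=O)[OX2H1]", 3, -1.0, "acid"),
    # phosphate / phosphonate first deprotonation
    ("[PX4](=O)[OX2H1]", 2, 2.0, "acid"),
    # tetrazole N-H -> tetrazolate
    ("[nX3H1]1nnnc1", 0, 4.9, "acid"),
    # aryl thiol -> thiolate (aliphatic thiols, pKa ~ 8.3, stay neutral)
    ("[SX2H1][c]", 0, 6.6, "acid"),
    # amidines / guanidines: protonate the imine nitrogen
    ("[NX3;!$(N-C=O)][CX3](=[NX2;!$(N-C=O)])", 2, 12.5, "base"),
    # aliphatic amines (not amide, not aniline, only C/H neighbours)
    (
        "[NX3;H2,H1,H0;+0;!$(N-[!#6;!#1]);!$(N-c);!$(N-C=[O,S,N]);!$(N=*);!$(N#*)]",
        0,
        10.6,
        "base",
    ),
]


class RuleTableProtonation(ProtonationEngine):
    """Fixed SMARTS transform table applied at a given pH.

    Covers the ionizable groups that dominate druglike chemistry:
    carboxylic, sulfonic and phosphonic acids, tetrazoles, aryl thiols,
    aliphatic amines and amidines/guanidines.  A group is switched to its
    majority microstate when its tabulated pKa is on the far side of the pH.
    """

    def __init__(self) -> None:
        self._compiled = [
            (Chem.MolFromSmarts(smarts), idx, pka, kind)
            for smarts, idx, pka, kind in _PROTONATION_RULES
        ]

    def adjust(self, smiles: str, ph: float) -> str:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        rw = Chem.RWMol(mol)
        handled: set[int] = set()
        for patt, pos, pka, kind in self._compiled:
            if kind == "acid" and not pka < ph:
                continue
            if kind == "base" and not pka > ph:
                continue
            for match in rw.GetSubstructMatches(patt):
                aidx = match[pos]
                if aidx in handled:
                    continue
                atom = rw.GetAtomWithIdx(aidx)
                if kind == "acid":
                    if atom.GetTotalNumHs() < 1 or atom.GetFormalCharge() != 0:
                        continue
                    atom.SetFormalCharge(-1)
                    atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - 1)
                                          if atom.GetNumExplicitHs() > 0 else 0)
                    atom.SetNoImplicit(True)
                else:
                    if atom.GetFormalCharge() != 0:
                        continue
                    atom.SetFormalCharge(1)
                    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                    atom.SetNoImplicit(True)
                handled.add(aidx)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
        return Chem.MolToSmiles(product)


_DEFAULT_ENGINE = RuleTableProtonation()


def adjust_protonation(smiles: str, ph: float = 7.4,
                       engine: Optional[ProtonationEngine] = None) -> str:
    """Return a canonical SMILES reflecting the majority microstate at ``ph``.

    Idempotent: applying the transform to its own output is a no-op.
    """
    return (engine or _DEFAULT_ENGINE).adjust(smiles, ph)


# ---------------------------------------------------------------------------
# Conformer embedding
# ---------------------------------------------------------------------------

def _stable_hash(text: str) -> int:
    """Process-independent 31-bit hash (python's hash() is salted)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2 ** 31)


def _assign_undefined_stereocenters(mol: Chem.Mol) -> None:
    """Fix undefined stereocenters pseudo-randomly but reproducibly.

    The RNG is seeded from a content hash of the canonical SMILES so the
    assignment does not depend on the conformer seed, library ordering, or
    the process.  Defined stereocenters are never touched.
    """
    centers = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    undefined = [idx for idx, tag in centers if tag == "?"]
    if not undefined:
        return
    rng = np.random.default_rng(_stable_hash(Chem.MolToSmiles(mol)))
    for idx in sorted(undefined):
        tag = (Chem.ChiralType.CHI_TETRAHEDRAL_CW
               if rng.integers(0, 2) == 0
               else Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        mol.GetAtomWithIdx(idx).SetChiralTag(tag)


def embed_conformer(smiles: str, seed: int = 0,
                    max_iters: int = 1000) -> Union[Chem.Mol, RejectionReason]:
    """Generate one 3D conformation: ETKDG embedding + MMFF94 refinement.

    Returns an RDKit molecule with explicit hydrogens and a single conformer,
    or a :class:`RejectionReason` (EMBED_FAILED / REFINE_FAILED).  Identical
    (smiles, seed) pairs yield bitwise-identical coordinates.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return RejectionReason(RejectionCode.UNPARSEABLE, smiles)
    _assign_undefined_stereocenters(mol)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31)
    params.enforceChirality = True
    if AllChem.EmbedMolecule(mol, params) != 0:
        return RejectionReason(RejectionCode.EMBED_FAILED, "distance-geometry embedding failed")
    try:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            return RejectionReason(RejectionCode.REFINE_FAILED, "no MMFF94 parameters")
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        e0 = ff.CalcEnergy()
        converged = ff.Minimize(maxIts=max_iters, forceTol=1e-4) == 0
        e1 = ff.CalcEnergy()
        # Non-convergence alone is tolerated if the energy went down.
        if not converged and not (e0 - e1 > 1e-6):
            return RejectionReason(RejectionCode.REFINE_FAILED,
                                   "minimization did not converge or reduce energy")
    except Exception as exc:  # force-field setup failures
        return RejectionReason(RejectionCode.REFINE_FAILED, str(exc))
    return mol


def assign_partial_charges(mol: Chem.Mol) -> np.ndarray:
    """Gasteiger partial charges, one per atom (including hydrogens).

    The iterative partial-equalization scheme conserves the molecular net
    charge, so the per-atom charges sum to the net formal charge.
    """
    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise ValueError("Gasteiger charge computation produced non-finite values")
    return charges


def prepare_ligand(smiles: str, ph: float = 7.4, seed: int = 0,
                   engine: Optional[ProtonationEngine] = None) -> PrepOutcome:
    """Run the full preparation pipeline on one SMILES string."""
    verdict = validate_ligand(smiles)
    if verdict is not None:
        return verdict
    try:
        adjusted = adjust_protonation(smiles, ph, engine)
    except ValueError as exc:
        return RejectionReason(RejectionCode.UNPARSEABLE, str(exc))
    mol = embed_conformer(adjusted, seed)
    if isinstance(mol, RejectionReason):
        return mol
    charges = assign_partial_charges(mol)
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x,
                        conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    return PreparedLigand(
        input_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)),
        atom_elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        partial_charges=charges,
        net_charge=Chem.GetFormalCharge(mol),
        seed=seed,
        mol=mol,
    )


# ---------------------------------------------------------------------------
# PDBQT serialization
# ---------------------------------------------------------------------------

def _autodock_type(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if sym == "C":
        return "A" if atom.GetIsAromatic() else "C"
    if sym == "N":
        return "N" if atom.GetTotalNumHs() > 0 else "NA"
    if sym == "O":
        return "OA"
    if sym == "S":
        return "SA"
    if sym == "H":
        heavy = [n for n in atom.GetNeighbors()]
        if heavy and heavy[0].GetSymbol() in ("N", "O", "S"):
            return "HD"
        return "H"
    return sym


def rotatable_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Rotatable bonds on the heavy-atom graph (explicit Hs allowed).

    A bond is rotatable when it is a non-ring single bond between two heavy
    atoms, each with at least two heavy neighbours, neither involved in a
    triple bond — the same convention as the standard rotatable-bond count.
    """
    def heavy_deg(a: Chem.Atom) -> int:
        return sum(1 for n in a.GetNeighbors() if n.GetAtomicNum() > 1)

    def in_triple(a: Chem.Atom) -> bool:
        return any(b.GetBondType() == Chem.BondType.TRIPLE for b in a.GetBonds())

    out = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if heavy_deg(a) < 2 or heavy_deg(b) < 2:
            continue
        if in_triple(a) or in_triple(b):
            continue
        out.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return out


def ligand_to_pdbqt(ligand: PreparedLigand) -> str:
    """Serialize a prepared ligand to AutoDock PDBQT with a torsion tree.

    The rigid core (largest fragment after cutting all rotatable bonds) is
    emitted as ROOT; each rotatable bond opens a nested BRANCH.  TORSDOF is
    the number of active torsions.
    """
    mol = ligand.mol
    if mol is None or mol.GetNumConformers() == 0:
        raise ValueError("ligand record has no embedded conformer")
    conf = mol.GetConformer()
    rot = rotatable_bonds(mol)
    rotset = {frozenset(b) for b in rot}

    # Rigid components: connected components of the graph minus rotatable bonds
    n = mol.GetNumAtoms()
    comp = [-1] * n
    ncomp = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        stack = [start]
        comp[start] = ncomp
        while stack:
            u = stack.pop()
            for nb in mol.GetAtomWithIdx(u).GetNeighbors():
                v = nb.GetIdx()
                if comp[v] == -1 and frozenset((u, v)) not in rotset:
                    comp[v] = ncomp
                    stack.append(v)
        ncomp += 1

    sizes = [0] * ncomp
    for c in comp:
        sizes[c] += 1
    root_comp = int(np.argmax(sizes))

    # Component adjacency via rotatable bonds
    comp_edges: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(ncomp)}
    for (u, v) in rot:
        comp_edges[comp[u]].append((comp[v], u, v))
        comp_edges[comp[v]].append((comp[u], v, u))

    serial: dict[int, int] = {}
    lines: list[str] = []
    counter = [0]

    def emit_atoms(c: int) -> None:
        for idx in range(n):
            if comp[idx] != c:
                continue
            counter[0] += 1
            serial[idx] = counter[0]
            atom = mol.GetAtomWithIdx(idx)
            pos = conf.GetAtomPosition(idx)
            name = f"{atom.GetSymbol()}{counter[0]}"[:4]
            q = ligand.partial_charges[idx]
            lines.append(
                f"ATOM  {counter[0]:>5} {name:<4} LIG A   1    "
                f"{pos.x:8.3f}{pos.y:8.3f}{pos.z:8.3f}  0.00  0.00    "
                f"{q:6.3f} {_autodock_type(atom):<2}"
            )

    visited = {root_comp}
    lines.append("ROOT")
    emit_atoms(root_comp)
    lines.append("ENDROOT")

    def emit_branches(c: int) -> None:
        for (child, u, v) in sorted(comp_edges[c], key=lambda t: (t[1], t[2])):
            if child in visited:
                continue
            visited.add(child)
            lines.append(f"BRANCH {serial[u]:>3} {'':>0}".rstrip())
            placeholder = len(lines) - 1
            emit_atoms(child)
            lines[placeholder] = f"BRANCH {serial[u]:>4} {serial[v]:>4}"
            emit_branches(child)
            lines.append(f"ENDBRANCH {serial[u]:>4} {serial[v]:>4}")

    emit_branches(root_comp)
    lines.append(f"TORSDOF {len(rot)}")
    return "\n".join(lines) + "\n"


def pdbqt_heavy_atom_count(text: str) -> int:
    """Count heavy atoms in ligand/receptor PDBQT text."""
    count = 0
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            adtype = line[77:79].strip() if len(line) > 77 else line.split()[-1]
            if adtype not in ("H", "HD", "HS"):
                count += 1
    return count


def pdbqt_torsion_count(text: str) -> int:
    """Active torsions declared in a ligand PDBQT (TORSDOF record)."""
    for line in text.splitlines():
        if line.startswith("TORSDOF"):
            return int(line.split()[1])
    return 0
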