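"""A compact robust molecular string representation in the spirit of SELFIES.

Molecules are written as token sequences — atoms (with the bond order to
the preceding atom), branch open/close markers, and ring-closure tokens —
and the decoder enforces valence as it derives the graph: a requested bond
order is capped by the free valence of both endpoints, and tokens that
cannot be applied (a closing marker with no open branch, a ring closure to
a saturated or nonexistent atom) are simply skipped.  As a result *every*
token sequence over the alphabet decodes to a valid molecule, which is the
property mutation-based genetic algorithms rely on.

The grammar covers neutral organic molecules over C, N, O, S, F, Cl, Br
(the druglike subset the synthetic libraries use); charged or exotic inputs
are rejected at encoding time.  Stereochemistry is not represented.
"""

from __future__ import annotations

import re
from typing import Optional

from rdkit import Chem

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

_ATOM_RE = re.compile(r"^\[([=#]?)(C|N|O|S|F|Cl|Br)\]$")
_RING_RE = re.compile(r"^\[([=#]?)Ring(\d+)\]$")

BRANCH = "[Branch]"
POP = "[Pop]"


def atom_token(element: str, bond_order: int = 1) -> str:
    return f"[{_BOND_PREFIX[bond_order]}{element}]"


def ring_token(k: int, bond_order: int = 1) -> str:
    return f"[{_BOND_PREFIX[bond_order]}Ring{k}]"


def default_alphabet(max_ring: int = 8) -> list[str]:
    """Token alphabet used for random edits."""
    tokens = [BRANCH, POP]
    for el, cap in _VALENCE.items():
        for order in (1, 2, 3):
            if order <= cap:
                tokens.append(atom_token(el, order))
    for k in range(1, max_ring + 1):
        tokens.append(ring_token(k, 1))
        tokens.append(ring_token(k, 2))
    return tokens


# ---------------------------------------------------------------------------
# Decoding (total: any token list yields a valid molecule or the empty one)
# ---------------------------------------------------------------------------

def decode(tokens: list[str]) -> Optional[str]:
    """Derive a molecule from a token sequence.

    Returns a canonical SMILES, or ``None`` only for sequences containing
    no applicable atom token at all.
    """
    rw = Chem.RWMol()
    free: list[int] = []        # remaining valence per atom
    order: list[int] = []       # atom indices in creation order
    stack: list[int] = []
    cur: Optional[int] = None

    def bond_used(idx: int, amount: int) -> None:
        free[idx] -= amount

    for tok in tokens:
        if tok == BRANCH:
            if cur is not None:
                stack.append(cur)
            continue
        if tok == POP:
            if stack:
                cur = stack.pop()
            continue
        m = _ATOM_RE.match(tok)
        if m:
            want = _PREFIX_BOND[m.group(1)]
            el = m.group(2)
            cap = _VALENCE[el]
            if cur is None:
                idx = rw.AddAtom(Chem.Atom(el))
                free.append(cap)
                order.append(idx)
                cur = idx
                continue
            eff = min(want, free[cur], cap)
            if eff < 1:
                continue  # current atom saturated: skip token
            idx = rw.AddAtom(Chem.Atom(el))
            free.append(cap)
            order.append(idx)
            rw.AddBond(cur, idx, _BOND_TYPE[eff])
            bond_used(cur, eff)
            bond_used(idx, eff)
            cur = idx
            continue
        m = _RING_RE.match(tok)
        if m:
            if cur is None:
                continue
            want = _PREFIX_BOND[m.group(1)]
            k = int(m.group(2))
            pos = len(order) - 1 - k
            if pos < 0:
                pos = 0
            partner = order[pos]
            if partner == cur or rw.GetBondBetweenAtoms(cur, partner) is not None:
                continue
            eff = min(want, free[cur], free[partner])
            if eff < 1:
                continue
            rw.AddBond(cur, partner, _BOND_TYPE[eff])
            bond_used(cur, eff)
            bond_used(partner, eff)
            continue
        raise ValueError(f"unknown token {tok!r}")

    if rw.GetNumAtoms() == 0:
        return None
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class EncodingError(ValueError):
    pass


def encode(smiles: str) -> list[str]:
    """Tokenize a neutral organic molecule; round-trips through decode.

    Raises :class:`EncodingError` for unsupported elements, charges or
    radicals (the robust grammar intentionally covers only the druglike
    neutral subset).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _VALENCE:
            raise EncodingError(f"unsupported element {atom.GetSymbol()}")
        if atom.GetFormalCharge() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise EncodingError("charged or radical atoms are not encodable")
        heavy_valence = sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())
        if heavy_valence > _VALENCE[atom.GetSymbol()]:
            raise EncodingError(
                f"{atom.GetSymbol()} exceeds grammar valence cap {_VALENCE[atom.GetSymbol()]}")

    tokens: list[str] = []
    pos: dict[int, int] = {}  # atom idx -> creation position
    visited: set[int] = set()

    def bond_order(a: int, b: int) -> int:
        return int(mol.GetBondBetweenAtoms(a, b).GetBondTypeAsDouble())

    def visit(idx: int, parent: Optional[int]) -> None:
        visited.add(idx)
        pos[idx] = len(pos)
        tokens.append(atom_token(mol.GetAtomWithIdx(idx).GetSymbol(),
                                 1 if parent is None else bond_order(parent, idx)))
        nbrs = sorted(n.GetIdx() for n in mol.GetAtomWithIdx(idx).GetNeighbors())
        # ring closures back to already-visited atoms; the decoder's current
        # atom is idx exactly here (children below are Branch/Pop-wrapped)
        for nb in nbrs:
            if nb != parent and nb in visited and (min(idx, nb), max(idx, nb)) not in closed:
                closed.add((min(idx, nb), max(idx, nb)))
                tokens.append(ring_token(pos[idx] - pos[nb], bond_order(idx, nb)))
        for nb in nbrs:
            if nb in visited:  # includes atoms reached through a sibling's cycle
                continue
            tokens.append(BRANCH)
            visit(nb, idx)
            tokens.append(POP)

    frags = Chem.GetMolFrags(mol)
    if len(frags) != 1:
        raise EncodingError("multi-fragment molecules are not encodable")
    closed: set[tuple[int, int]] = set()
    visit(0, None)
    return tokens
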