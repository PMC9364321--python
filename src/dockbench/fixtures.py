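"""Synthetic data generation: druglike SMILES libraries, correlated mock
score targets, and a miniature receptor fixture.

Everything here is generated programmatically and deterministically so the
whole pipeline — preparation, docking, clustering, benchmarks, optimizers —
can be exercised with no downloads and no docking binary.  The library
emulates the profile of a curated bioactivity dataset: druglike molecules
built by decorating a pool of common ring scaffolds, most of which satisfy
Lipinski's rules.  Mock targets emulate the empirically observed docking
behaviour: scores in the [-13, -4] range, driven by molecular size and
lipophilicity, with a configurable inter-target correlation (kinase pairs
in real score matrices correlate strongly, e.g. rho = 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .benchmarks import ScoreMatrix
from .docking import SCORE_RANGE, descriptor_vector
from .target_prep import (BoxParams, NullAdapter, PreparedTarget,
                          derive_search_box, prepare_target,
                          reference_ligand_coords)

SCAFFOLD_POOL = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "C1CCNCC1", "C1CNCCN1", "C1COCCN1",
    "C1CCCCC1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1", "c1c[nH]cn1",
    "c1ccc2[nH]ccc2c1", "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "c1ccc2[nH]cnc2c1",
    "c1cn[nH]c1", "c1ocnc1", "C1CCOCC1", "C1CCNC1", "C1CCCC1",
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "N(C)C", "F", "Cl", "Br",
    "C(F)(F)F", "C(=O)O", "C(=O)N", "C#N", "SC", "CO", "C(=O)C", "OCC",
    "c1ccccc1",
]

LINKERS = ["", "C", "CC", "O", "N", "C(=O)N", "OC", "S"]

PLANTED_RADICALS = ["[CH3]", "[CH2]CC", "C[CH]C", "[CH2]c1ccccc1", "CC(C)[CH2]"]
PLANTED_MULTIFRAGMENT = ["CC.Cl", "c1ccccc1.O", "CCN.OC(=O)C", "CCO.CCO",
                         "c1ccncc1.Cl"]


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    n_molecules: int = 1000
    seed: int = 0
    scaffold_pool_size: int = len(SCAFFOLD_POOL)
    decoration_rate: float = 2.0  # mean substituents per molecule
    n_radicals: int = 0           # planted defects, appended at the end
    n_multi_fragment: int = 0


def _attach(core: Chem.Mol, substituent: str, rng: np.random.Generator) -> Optional[Chem.Mol]:
    sub = Chem.MolFromSmiles(substituent)
    sites = [a.GetIdx() for a in core.GetAtoms()
             if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0]
    if not sites or sub is None:
        return None
    rw = Chem.RWMol(Chem.CombineMols(core, sub))
    anchor = int(rng.choice(sites))
    rw.AddBond(anchor, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def _build_molecule(rng: np.random.Generator, scaffolds: Sequence[str],
                    decoration_rate: float) -> Optional[str]:
    core = Chem.MolFromSmiles(str(rng.choice(scaffolds)))
    # occasionally join two scaffolds through a short linker
    if rng.random() < 0.3:
        second = str(rng.choice(scaffolds))
        linker = str(rng.choice(LINKERS))
        joined = _attach(core, linker + second if linker else second, rng)
        if joined is not None:
            core = joined
    n_dec = int(rng.poisson(decoration_rate))
    for _ in range(n_dec):
        grown = _attach(core, str(rng.choice(SUBSTITUENTS)), rng)
        if grown is not None:
            core = grown
    try:
        return Chem.MolToSmiles(core)
    except Exception:
        return None


def generate_library(spec: SyntheticLibrarySpec = SyntheticLibrarySpec()) -> list[str]:
    """Deterministic synthetic SMILES library.

    Molecules are scaffold decorations; duplicates are skipped.  Planted
    defects (radicals, multi-fragment salts) are appended at the end so
    rejection accounting is exact.
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(spec.seed)
    scaffolds = SCAFFOLD_POOL[:max(1, spec.scaffold_pool_size)]
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.n_molecules and attempts < 50 * spec.n_molecules:
        attempts += 1
        smi = _build_molecule(rng, scaffolds, spec.decoration_rate)
        if smi and smi not in seen:
            seen.add(smi)
            out.append(smi)
    for i in range(spec.n_radicals):
        out.append(PLANTED_RADICALS[i % len(PLANTED_RADICALS)])
    for i in range(spec.n_multi_fragment):
        out.append(PLANTED_MULTIFRAGMENT[i % len(PLANTED_MULTIFRAGMENT)])
    return out


# ---------------------------------------------------------------------------
# Mock score targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockTargetSpec:
    name: str
    seed: int = 0
    correlation_to: Optional[tuple[str, float]] = None  # (other target, rho)

    def __post_init__(self) -> None:
        if self.correlation_to is not None and abs(self.correlation_to[1]) > 1:
            raise ValueError("requested correlation must lie in [-1, 1]")


def _squash(z: np.ndarray) -> np.ndarray:
    lo, hi = SCORE_RANGE
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return mid - half * np.tanh(z / 2.5)


def generate_mock_targets(specs: Sequence[MockTargetSpec], library: Sequence[str],
                          receptor: Optional[PreparedTarget] = None
                          ) -> tuple[ScoreMatrix, dict[str, PreparedTarget]]:
    """Build mock targets with controlled pairwise score correlations.

    Feature statistics are estimated on the library; each target's weight
    vector lives in the whitened principal-component space of the
    standardized descriptors, so the pre-squash score correlation between
    two targets equals the inner product of their direction vectors exactly,
    and a requested rho is realized to within the small attenuation of the
    bounded squashing map.

    Returns the full molecules x targets :class:`ScoreMatrix` and prepared
    targets whose metadata carries the mock scoring model.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    receptor = receptor or make_mini_target_fixture()
    Phi = np.array([descriptor_vector(s) for s in library])
    mu = Phi.mean(axis=0)
    sigma = np.maximum(Phi.std(axis=0), 1e-6)
    Z = (Phi - mu) / sigma
    # whitening basis: unit-variance projections of the standardized features
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    keep = S > 1e-8 * S[0]
    V = Vt[keep].T                                   # d x r
    scale = np.sqrt(len(library)) / S[keep]          # r

    directions: dict[str, np.ndarray] = {}
    columns: dict[str, np.ndarray] = {}
    targets: dict[str, PreparedTarget] = {}
    r = V.shape[1]
    for spec in specs:
        rng = np.random.default_rng(spec.seed + 7919)
        if spec.correlation_to is None:
            u = rng.standard_normal(r)
            u /= np.linalg.norm(u)
        else:
            other, rho = spec.correlation_to
            if other not in directions:
                raise ValueError(f"correlation target {other!r} must be defined first")
            ua = directions[other]
            v = rng.standard_normal(r)
            v -= (v @ ua) * ua
            v /= np.linalg.norm(v)
            u = rho * ua + np.sqrt(max(0.0, 1 - rho ** 2)) * v
        directions[spec.name] = u
        w = V @ (scale * u)                          # weights on standardized features
        z = Z @ w
        columns[spec.name] = _squash(z)
        targets[spec.name] = PreparedTarget(
            name=spec.name,
            receptor_pdbqt=receptor.receptor_pdbqt,
            box=receptor.box,
            metadata={"mock": {"weights": w.tolist(), "mu": mu.tolist(),
                               "sigma": sigma.tolist()}},
        )
    frame = pd.DataFrame(columns, index=list(library))
    return ScoreMatrix(frame=frame), targets


# ---------------------------------------------------------------------------
# Miniature receptor fixture
# ---------------------------------------------------------------------------

def synthetic_helix_pdb(n_residues: int = 8) -> str:
    """PDB text for a small synthetic poly-alanine alpha-helix.

    Backbone atoms (N, CA, C, O, CB and the amide hydrogen) are placed on an
    ideal helical parametrization (rise 1.5 angstrom, 100 degrees per
    residue).  Geometry is idealized, not energy-minimized: the fixture
    exists to exercise parsing, conversion and box logic.
    """
    lines = []
    serial = 0
    atom_specs = [  # (name, element, radial offset, angular offset, z offset)
        ("N", "N", 1.6, -0.55, -0.9), ("H", "H", 2.2, -0.70, -1.1),
        ("CA", "C", 2.3, 0.00, 0.0), ("CB", "C", 3.6, 0.25, -0.4),
        ("C", "C", 1.7, 0.60, 0.9), ("O", "O", 2.1, 0.95, 1.5),
    ]
    for res in range(1, n_residues + 1):
        theta = np.deg2rad(100.0) * (res - 1)
        zc = 1.5 * (res - 1)
        for (name, element, rad, dth, dz) in atom_specs:
            serial += 1
            x = rad * np.cos(theta + dth)
            y = rad * np.sin(theta + dth)
            z = zc + dz
            lines.append(
                f"ATOM  {serial:>5} {name:<4} ALA A{res:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def synthetic_reference_ligand_pdb() -> str:
    """A small synthetic ligand coordinate file near the helix axis."""
    coords = [("C1", "C", 0.0, 0.0, 4.0), ("C2", "C", 1.4, 0.0, 4.2),
              ("O1", "O", 2.1, 1.0, 4.5), ("N1", "N", -0.8, 1.1, 4.4),
              ("C3", "C", -0.5, -1.3, 3.6)]
    lines = []
    for i, (name, element, x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"HETATM{i:>5} {name:<4} LIG B   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_mini_target_fixture(name: str = "MINI",
                             box_params: BoxParams = BoxParams()) -> PreparedTarget:
    """Prepared miniature receptor with a box derived from its reference ligand."""
    pdb = synthetic_helix_pdb()
    ref = reference_ligand_coords(synthetic_reference_ligand_pdb())
    return prepare_target(pdb, adapter=NullAdapter(), ref_coords=ref,
                          name=name, box_params=box_params)
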