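"""Receptor preparation: search-box derivation and PDB -> PDBQT conversion.

The docking search box is derived from the coordinates of a reference
ligand bound in the pocket: the axis-aligned bounding box of the ligand is
padded on all sides, and any side shorter than a minimum length is clamped
up to it.  Receptor standardization (hydrogen addition, format conversion)
is delegated to an external-tool adapter; the built-in NullAdapter performs
a minimal native conversion so the pipeline is testable without external
binaries.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

Coords = Sequence[tuple[float, float, float]]


@dataclass(frozen=True)
class BoxParams:
    """Padding (Å, each side) and minimum per-axis box length (Å)."""
    padding: float = 12.5
    min_side: float = 30.0

    def __post_init__(self) -> None:
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.min_side <= 0:
            raise ValueError("min_side must be > 0")


@dataclass(frozen=True)
class SearchBox:
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("box sizes must be positive")


@dataclass
class PreparedTarget:
    name: str
    receptor_pdbqt: str
    box: SearchBox
    metadata: dict = field(default_factory=dict)


def derive_search_box(ref_coords: Coords, params: BoxParams = BoxParams()) -> SearchBox:
    """Axis-aligned docking box around a reference ligand.

    Per axis: ``size = max(span + 2 * padding, min_side)`` and
    ``center = (max + min) / 2``.  With the default parameters every side is
    at least 30 Å, which keeps poses unconstrained for druglike ligands.
    """
    pts = np.asarray(ref_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 3:
        raise ValueError("ref_coords must be a non-empty list of (x, y, z) points")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    size = np.maximum(hi - lo + 2 * params.padding, params.min_side)
    center = (hi + lo) / 2
    return SearchBox(center=tuple(center.tolist()), size=tuple(size.tolist()))


# ---------------------------------------------------------------------------
# PDB / PDBQT text handling
# ---------------------------------------------------------------------------

# two-letter element symbols that appear in receptor files with upper-case
# element fields (metal ions, halogens); anything else is taken verbatim
_ELEMENT_FIXUPS = {
    "ZN": "Zn", "MG": "Mg", "MN": "Mn", "FE": "Fe", "CA": "Ca", "NA": "Na",
    "CU": "Cu", "NI": "Ni", "CO": "Co", "CD": "Cd", "HG": "Hg", "CL": "Cl",
    "BR": "Br", "SE": "Se", "K": "K",
}


def normalize_element(raw: str) -> str:
    """Normalize a PDB element field (e.g. ``"ZN"`` -> ``"Zn"``)."""
    sym = raw.strip()
    if not sym:
        return sym
    fixed = _ELEMENT_FIXUPS.get(sym.upper())
    if fixed:
        return fixed
    return sym[0].upper() + sym[1:].lower()


def parse_pdb_atoms(pdb_text: str) -> list[dict]:
    """Parse ATOM/HETATM records from PDB (or PDBQT) text.

    Coordinates are read from the fixed Å columns as-is; the element is
    taken from columns 77–78 when present, otherwise inferred from the atom
    name.
    """
    atoms = []
    for line in pdb_text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element or element in ("0.", "-0"):  # PDBQT puts charge/type there
            element = "".join(c for c in name if c.isalpha())[:2]
            if len(element) == 2 and element.upper() not in _ELEMENT_FIXUPS:
                element = element[0]
        atoms.append({
            "record": line[0:6].strip(),
            "name": name,
            "resname": line[17:20].strip(),
            "chain": line[21:22],
            "resseq": line[22:26].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "element": normalize_element(element),
        })
    return atoms


def reference_ligand_coords(text: str) -> list[tuple[float, float, float]]:
    """All atom coordinates from a reference-ligand PDB/PDBQT file."""
    return [(a["x"], a["y"], a["z"]) for a in parse_pdb_atoms(text)]


def heavy_atom_count(pdb_text: str) -> int:
    return sum(1 for a in parse_pdb_atoms(pdb_text) if a["element"] not in ("H", "D"))


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------

class ReceptorToolAdapter:
    """Contract for external receptor-preparation tools."""

    def to_pdbqt(self, pdb_text: str) -> str:  # pragma: no cover - interface
        raise NotImplementedError


_AD_RECEPTOR_TYPES = {
    "C": "C", "N": "NA", "O": "OA", "S": "SA", "H": "HD", "P": "P",
    "Zn": "Zn", "Mg": "Mg", "Mn": "Mn", "Fe": "Fe", "Ca": "Ca",
    "Cl": "Cl", "Br": "Br", "F": "F", "I": "I",
}


class NullAdapter(ReceptorToolAdapter):
    """Minimal native PDB -> PDBQT conversion.

    Keeps every atom (heavy atoms and any hydrogens already present in the
    input), normalizes element symbols, assigns zero partial charges and a
    coarse AutoDock atom type.  Suitable for fixtures and tests; real
    receptor preparation should use an external-tool adapter.
    """

    def to_pdbqt(self, pdb_text: str) -> str:
        atoms = parse_pdb_atoms(pdb_text)
        if not atoms:
            raise ValueError("no ATOM/HETATM records found in receptor input")
        lines = []
        for i, a in enumerate(atoms, start=1):
            adtype = _AD_RECEPTOR_TYPES.get(a["element"])
            if adtype is None:
                raise ValueError(f"unrecognized element {a['element']!r} after normalization")
            lines.append(
                f"ATOM  {i:>5} {a['name']:<4}{a['resname']:>4} {a['chain'] or 'A'}"
                f"{int(a['resseq'] or 1):>4}    {a['x']:8.3f}{a['y']:8.3f}{a['z']:8.3f}"
                f"  0.00  0.00    {0.0:6.3f} {adtype:<2}"
            )
        return "\n".join(lines) + "\n"


class CommandAdapter(ReceptorToolAdapter):
    """Run an external conversion command (e.g. Open Babel) via subprocess.

    The command must read PDB on stdin and write PDBQT on stdout, e.g.
    ``["obabel", "-ipdb", "-", "-opdbqt", "-xr"]``.
    """

    def __init__(self, argv: Sequence[str]):
        self.argv = list(argv)

    def to_pdbqt(self, pdb_text: str) -> str:
        proc = subprocess.run(self.argv, input=pdb_text, capture_output=True,
                              text=True, check=False)
        if proc.returncode != 0 or not proc.stdout.strip():
            raise RuntimeError(
                f"receptor tool failed (exit {proc.returncode}): {proc.stderr.strip()[:500]}")
        return proc.stdout


def prepare_target(pdb_text: str,
                   adapter: Optional[ReceptorToolAdapter] = None,
                   box: Optional[SearchBox] = None,
                   ref_coords: Optional[Coords] = None,
                   name: str = "TARGET",
                   box_params: BoxParams = BoxParams()) -> PreparedTarget:
    """Produce a docking-ready receptor with an attached search box.

    The box comes either from an explicit :class:`SearchBox` (manual entry,
    as used for pockets set upon visual examination) or from reference-ligand
    coordinates via :func:`derive_search_box`.
    """
    if (box is None) == (ref_coords is None):
        raise ValueError("provide exactly one of box= or ref_coords=")
    adapter = adapter or NullAdapter()
    n_heavy_in = heavy_atom_count(pdb_text)
    pdbqt = adapter.to_pdbqt(pdb_text)
    n_heavy_out = heavy_atom_count(pdbqt)
    if n_heavy_out < n_heavy_in:
        raise RuntimeError(
            f"receptor conversion dropped heavy atoms ({n_heavy_in} -> {n_heavy_out})")
    if box is None:
        box = derive_search_box(ref_coords, box_params)
    return PreparedTarget(name=name, receptor_pdbqt=pdbqt, box=box,
                          metadata={"adapter": type(adapter).__name__,
                                    "padding": box_params.padding,
                                    "min_side": box_params.min_side})


def box_to_text(name: str, box: SearchBox) -> str:
    """Sidecar box file: name then six floats (center xyz, size xyz)."""
    c, s = box.center, box.size
    return (f"name {name}\n"
            f"center {c[0]:.3f} {c[1]:.3f} {c[2]:.3f}\n"
            f"size {s[0]:.3f} {s[1]:.3f} {s[2]:.3f}\n")


def box_from_text(text: str) -> tuple[str, SearchBox]:
    fields = {}
    for line in text.splitlines():
        parts = line.split()
        if parts:
            fields[parts[0]] = parts[1:]
    return fields["name"][0], SearchBox(
        center=tuple(float(v) for v in fields["center"]),
        size=tuple(float(v) for v in fields["size"]))
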