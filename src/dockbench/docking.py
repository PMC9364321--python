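"""Docking through a pluggable backend.

Two backends are provided.  ``VinaBackend`` shells out to an AutoDock Vina
executable with an explicit seed so runs are reproducible and
binary-version independent.  ``MockBackend`` is a deterministic stand-in
for download-free testing and benchmark development: it scores molecules
with a smooth function of physicochemical descriptors, squashed onto the
realistic docking-score range [-13, -4], and the correlation between two
mock targets is controlled by the angle between their weight vectors.
Scores are on a kcal/mol scale but treated as unitless downstream; lower
is better.
"""

from __future__ import annotations

import hashlib
import logging
import os
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

from .ligand_prep import (PreparedLigand, RejectionReason, ligand_to_pdbqt,
                          prepare_ligand)
from .target_prep import PreparedTarget

logger = logging.getLogger(__name__)

SCORE_RANGE = (-13.0, -4.0)  # realistic docking-score range emulated by the mock


@dataclass(frozen=True)
class DockingParams:
    exhaustiveness: int = 8
    num_modes: int = 9
    energy_range: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_modes < 1:
            raise ValueError("num_modes must be >= 1")


@dataclass
class Pose:
    coords: np.ndarray
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class DockingResult:
    poses: list[Pose]
    target_name: str
    ligand_smiles: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("a docking result must contain at least one pose")
        scores = [p.score for p in self.poses]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("pose scores must be non-decreasing")


def best_score(result: DockingResult) -> float:
    """Lowest (best) score across poses; the benchmark score of a molecule."""
    if not result.poses:
        raise ValueError("empty docking result")
    score = min(p.score for p in result.poses)
    if score > 0:
        logger.info("constrained pose: positive best score %.2f for %s vs %s",
                    score, result.ligand_smiles, result.target_name)
    return score


class DockingError(RuntimeError):
    """Backend failure with captured diagnostics."""


class BackendRejection(RuntimeError):
    """Ligand failed preparation; carries the structured reason."""

    def __init__(self, reason: RejectionReason):
        super().__init__(f"ligand rejected: {reason.code.value} ({reason.detail})")
        self.reason = reason


class DockingBackend:
    """Contract all benchmark modules rely on."""

    def dock_prepared(self, target: PreparedTarget, ligand: PreparedLigand,
                      params: DockingParams) -> DockingResult:  # pragma: no cover
        raise NotImplementedError


def dock(target: PreparedTarget, smiles: str, params: DockingParams,
         backend: DockingBackend, ph: float = 7.4) -> DockingResult:
    """Prepare the ligand and dock it against a prepared target.

    Ligand rejections are raised as :class:`BackendRejection` before the
    backend is invoked; identical inputs and seed give identical results.
    """
    outcome = prepare_ligand(smiles, ph=ph, seed=params.seed)
    if isinstance(outcome, RejectionReason):
        raise BackendRejection(outcome)
    return backend.dock_prepared(target, outcome, params)


# ---------------------------------------------------------------------------
# Descriptors and the mock scoring model
# ---------------------------------------------------------------------------

N_FP_FEATURES = 10
DESCRIPTOR_DIM = 6 + N_FP_FEATURES

# coarse druglike location/scale used to standardize descriptors when no
# library-derived statistics are supplied
DEFAULT_MU = np.array([3.0, 2.5, 2.5, 1.5, 4.0, 5.0] + [0.5] * N_FP_FEATURES)
DEFAULT_SIGMA = np.array([1.2, 1.5, 1.3, 1.2, 2.0, 2.5] + [0.5] * N_FP_FEATURES)

_MORGAN64 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=64)


def descriptor_vector(smiles: str) -> np.ndarray:
    """Physicochemical + hashed-fingerprint descriptors for mock scoring.

    Components: MW/100, cLogP, ring count, HBD, HBA, rotatable bonds, then
    ``N_FP_FEATURES`` binary Morgan-fingerprint bits.  Raises ``ValueError``
    on unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = _MORGAN64.GetFingerprint(mol)
    bits = [float(fp.GetBit(i * 6 + 1)) for i in range(N_FP_FEATURES)]
    return np.array([
        Descriptors.MolWt(mol) / 100.0,
        Crippen.MolLogP(mol),
        mol.GetRingInfo().NumRings(),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
        Lipinski.NumRotatableBonds(mol),
        *bits,
    ])


def mock_score(descriptors: np.ndarray, target_weights: np.ndarray,
               mu: Optional[np.ndarray] = None,
               sigma: Optional[np.ndarray] = None) -> float:
    """Smooth deterministic mock docking score in (-13, -4).

    ``z = w . (phi - mu) / sigma`` is squashed with a tanh onto the observed
    docking-score range; the sample correlation of two targets' scores over
    a library is governed by the angle between their weight vectors.
    """
    d = np.asarray(descriptors, dtype=float)
    w = np.asarray(target_weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError(f"dimension mismatch: {d.shape} vs {w.shape}")
    mu = DEFAULT_MU if mu is None else np.asarray(mu, dtype=float)
    sigma = DEFAULT_SIGMA if sigma is None else np.asarray(sigma, dtype=float)
    z = float(w @ ((d - mu) / sigma))
    lo, hi = SCORE_RANGE
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return mid - half * np.tanh(z / 2.5)


def _stable_seed(*parts: object) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def default_mock_weights(target_name: str, dim: int = DESCRIPTOR_DIM) -> np.ndarray:
    """Unit weight vector derived deterministically from the target name."""
    rng = np.random.default_rng(_stable_seed("mock-target", target_name))
    w = rng.standard_normal(dim)
    # bias toward the classic docking confounders: size and lipophilicity
    w[0] += 1.0
    w[1] += 0.5
    return w / np.linalg.norm(w)


class MockBackend(DockingBackend):
    """Deterministic descriptor-based scoring backend.

    Target weight vectors and standardization statistics are taken from
    ``target.metadata["mock"]`` when present (as written by the fixtures
    module), otherwise derived from the target name.
    """

    def _model(self, target: PreparedTarget) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        meta = target.metadata.get("mock") if target.metadata else None
        if meta:
            return (np.asarray(meta["weights"]), np.asarray(meta["mu"]),
                    np.asarray(meta["sigma"]))
        return default_mock_weights(target.name), DEFAULT_MU, DEFAULT_SIGMA

    def score_smiles(self, target: PreparedTarget, smiles: str) -> float:
        """Fast path: best score without 3D embedding (used by benchmarks)."""
        w, mu, sigma = self._model(target)
        return mock_score(descriptor_vector(smiles), w, mu, sigma)

    def dock_prepared(self, target: PreparedTarget, ligand: PreparedLigand,
                      params: DockingParams) -> DockingResult:
        best = self.score_smiles(target, ligand.canonical_smiles)
        rng = np.random.default_rng(
            _stable_seed("mock-dock", target.name, ligand.canonical_smiles, params.seed))
        scores = [best]
        while len(scores) < params.num_modes:
            nxt = scores[-1] + rng.uniform(0.1, 0.6)
            if nxt - best > params.energy_range:
                break
            scores.append(nxt)
        center = np.asarray(target.box.center)
        base = ligand.coords - ligand.coords.mean(axis=0) + center
        poses = []
        for s in scores:
            jitter = rng.normal(scale=0.3, size=base.shape)
            poses.append(Pose(coords=base + jitter, score=float(s)))
        return DockingResult(poses=poses, target_name=target.name,
                             ligand_smiles=ligand.canonical_smiles,
                             metadata={"backend": "mock"})


# ---------------------------------------------------------------------------
# AutoDock Vina adapter
# ---------------------------------------------------------------------------

class VinaBackend(DockingBackend):
    """Subprocess adapter around an AutoDock Vina executable.

    The executable is invoked with an explicit ``--seed``; scores are parsed
    from the output poses file (``REMARK VINA RESULT`` records), keeping the
    adapter independent of the binary version, which is recorded in the
    result metadata.
    """

    def __init__(self, executable: str = "vina"):
        self.executable = executable

    @staticmethod
    def available(executable: str = "vina") -> bool:
        return shutil.which(executable) is not None

    def version(self) -> str:
        try:
            out = subprocess.run([self.executable, "--version"],
                                 capture_output=True, text=True, check=False)
            return (out.stdout or out.stderr).strip().splitlines()[0]
        except OSError:
            return "unknown"

    def dock_prepared(self, target: PreparedTarget, ligand: PreparedLigand,
                      params: DockingParams) -> DockingResult:
        with tempfile.TemporaryDirectory(prefix="dockbench-vina-") as tmp:
            receptor = os.path.join(tmp, "receptor.pdbqt")
            lig = os.path.join(tmp, "ligand.pdbqt")
            out = os.path.join(tmp, "out.pdbqt")
            with open(receptor, "w") as fh:
                fh.write(target.receptor_pdbqt)
            with open(lig, "w") as fh:
                fh.write(ligand_to_pdbqt(ligand))
            c, s = target.box.center, target.box.size
            argv = [self.executable,
                    "--receptor", receptor, "--ligand", lig, "--out", out,
                    "--center_x", str(c[0]), "--center_y", str(c[1]),
                    "--center_z", str(c[2]),
                    "--size_x", str(s[0]), "--size_y", str(s[1]),
                    "--size_z", str(s[2]),
                    "--exhaustiveness", str(params.exhaustiveness),
                    "--num_modes", str(params.num_modes),
                    "--energy_range", str(params.energy_range),
                    "--seed", str(params.seed)]
            proc = subprocess.run(argv, capture_output=True, text=True, check=False)
            if proc.returncode != 0:
                raise DockingError(f"vina failed (exit {proc.returncode}): "
                                   f"{proc.stderr.strip()[:1000]}")
            with open(out) as fh:
                poses = parse_vina_poses(fh.read())
        if not poses:
            raise DockingError("vina produced no poses")
        return DockingResult(poses=poses, target_name=target.name,
                             ligand_smiles=ligand.canonical_smiles,
                             metadata={"backend": "vina", "version": self.version()})


_VINA_RESULT_RE = re.compile(r"REMARK VINA RESULT:\s+(-?\d+\.?\d*)")


def parse_vina_poses(pdbqt_text: str) -> list[Pose]:
    """Parse MODEL-separated poses from a Vina output PDBQT."""
    poses: list[Pose] = []
    score: Optional[float] = None
    coords: list[list[float]] = []
    for line in pdbqt_text.splitlines():
        if line.startswith("MODEL"):
            score, coords = None, []
        elif line.startswith("REMARK VINA RESULT"):
            m = _VINA_RESULT_RE.search(line)
            if m:
                score = float(m.group(1))
        elif line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif line.startswith("ENDMDL") and score is not None:
            poses.append(Pose(coords=np.array(coords), score=score))
    return poses


def poses_to_pdbqt(result: DockingResult, elements: Sequence[str]) -> str:
    """Serialize poses as a MODEL-separated multi-pose PDBQT-style file."""
    blocks = []
    for i, pose in enumerate(result.poses, start=1):
        lines = [f"MODEL {i}", f"REMARK VINA RESULT: {pose.score:8.3f}"]
        for j, (el, (x, y, z)) in enumerate(zip(elements, pose.coords), start=1):
            lines.append(f"ATOM  {j:>5} {el + str(j):<4} LIG A   1    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  0.00  0.00    "
                         f"{0.0:6.3f} {el:<2}")
        lines.append("ENDMDL")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"
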