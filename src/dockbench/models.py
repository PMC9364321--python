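"""Ranker adapters for the virtual-screening benchmark.

The screening benchmark only needs a model that can *rank* molecules by
predicted docking score.  Any object with ``predict(smiles) -> scores``
plugs in; three built-ins cover the common cases: a seeded random ranker
(the no-information control), an oracle ranker that queries the scoring
backend directly (the ceiling), and an L2-regularized linear model on
fingerprints as a simple trainable baseline.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .benchmarks import Ranker
from .chemspace import FingerprintKind, fingerprint, fingerprint_array
from .docking import MockBackend
from .ligand_prep import validate_ligand


class RandomRanker(Ranker):
    """Assigns i.i.d. pseudo-scores; expected enrichment factor is 1."""

    def __init__(self, seed: int = 0):
        self.seed = seed

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.standard_normal(len(smiles))


class OracleRanker(Ranker):
    """Ranks by the true backend score (currently mock-backend only)."""

    def __init__(self, backend: MockBackend, target):
        self.backend = backend
        self.target = target

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        out = np.empty(len(smiles))
        for i, smi in enumerate(smiles):
            out[i] = (np.inf if validate_ligand(smi) is not None
                      else self.backend.score_smiles(self.target, smi))
        return out


class RidgeFingerprintRanker(Ranker):
    """L2-regularized linear regression on binary fingerprints."""

    def __init__(self, alpha: float = 1.0,
                 kind: FingerprintKind = FingerprintKind.PATH6):
        self.alpha = alpha
        self.kind = kind
        self._model: Optional[Ridge] = None

    def _features(self, smiles: Sequence[str]) -> np.ndarray:
        return fingerprint_array([fingerprint(s, self.kind) for s in smiles])

    def fit(self, smiles: Sequence[str], y: Sequence[float]) -> "RidgeFingerprintRanker":
        self._model = Ridge(alpha=self.alpha)
        self._model.fit(self._features(smiles), np.asarray(y, dtype=float))
        return self

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("ranker is not fitted")
        valid = [i for i, s in enumerate(smiles) if validate_ligand(s) is None]
        out = np.full(len(smiles), np.inf)
        if valid:
            feats = self._features([smiles[i] for i in valid])
            out[valid] = self._model.predict(feats)
        return out
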