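"""Fingerprint similarity search and the random library baseline."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..chemspace import Fingerprint, fingerprint_array, tanimoto_matrix


def fss_rank(library_fps: Sequence[Fingerprint],
             reference_fps: Sequence[Fingerprint],
             reference_active: Sequence[bool],
             top_k: int = 5000) -> list[int]:
    """Nearest-neighbour label transfer followed by similarity ranking.

    Each library molecule inherits the active/inactive flag of its
    Tanimoto-nearest reference (flags typically derive from a docking-score
    cutoff).  Predicted-inactive molecules are discarded; the survivors are
    sorted by similarity to their nearest reference, descending, and the
    indices of the top ``top_k`` are returned.  Ties break on library index
    for determinism.
    """
    if len(reference_fps) == 0:
        raise ValueError("empty reference set")
    if len(reference_fps) != len(reference_active):
        raise ValueError("reference flags length mismatch")
    L = fingerprint_array(list(library_fps))
    R = fingerprint_array(list(reference_fps))
    sim = tanimoto_matrix(L, R)
    nearest = sim.argmax(axis=1)
    best_sim = sim[np.arange(len(library_fps)), nearest]
    active = np.asarray(reference_active, dtype=bool)[nearest]
    survivors = [(float(-best_sim[i]), i) for i in range(len(library_fps)) if active[i]]
    survivors.sort()
    return [i for _, i in survivors[:top_k]]


def random_baseline(library: Sequence[str], n: int, seed: int = 0) -> list[str]:
    """Uniform sample without replacement, deterministic per seed."""
    if n > len(library):
        raise ValueError(f"cannot sample {n} from a library of {len(library)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(library), size=n, replace=False)
    return [library[i] for i in idx]
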