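"""Benchmark suites built on docking scores.

Three settings are covered:

* **Regression** — predict docking scores; scored by R², MSE, MAE.
* **Virtual screening** — rank a library, dock the top-k, label actives by a
  score threshold, report the enrichment factor (EF): the active rate in the
  selection over the active rate in the library.
* **De novo design** — minimize a docking-based objective with a QED
  druglikeness penalty under a fixed budget of objective evaluations,
  tracked by an append-only ledger.

The three shipped objectives: a single-target task (F2, thrombin), a
promiscuity task (worst score across the three PPAR nuclear receptors), and
a selectivity task (bind JAK2, avoid the off-target kinase LCK, whose score
is anchored at its dataset median so that being merely average on LCK is
not rewarded).  All objectives are minimized; lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .chemspace import property_profile
from .docking import BackendRejection, DockingParams, MockBackend, best_score, dock
from .ligand_prep import validate_ligand

# published 0.1-percentile activity thresholds (docking score units) for the
# screening targets; estimated once from a large commercial library and
# served from config rather than recomputed
SCREENING_THRESHOLDS = {"KIT": -10.7, "PARP1": -12.1, "PGR": -10.1}
REGRESSION_TARGETS = ["PARP1", "F2", "KIT", "ESR2", "PGR"]
SCREENING_TARGETS = ["PARP1", "KIT", "PGR"]

DEFAULT_BUDGET = 5000
DEFAULT_TOP_K = 5000
DEFAULT_BASE_RATE = 1e-3
QED_PENALTY_WEIGHT = 10.0
LCK_ANCHOR = -8.1


# ---------------------------------------------------------------------------
# Score matrix
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Molecules x targets table of docking scores (NaN = missing)."""

    frame: pd.DataFrame  # index = molecule ids (SMILES), columns = gene symbols

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate molecule ids in score matrix")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def targets(self) -> list[str]:
        return list(self.frame.columns)

    def scores(self, target: str) -> pd.Series:
        return self.frame[target]

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index_label="smiles")

    @classmethod
    def from_csv(cls, path: str) -> "ScoreMatrix":
        return cls(pd.read_csv(path, index_col="smiles"))


# ---------------------------------------------------------------------------
# Regression metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionMetrics:
    r2: Optional[float]  # None when y_true has zero variance
    mse: float
    mae: float


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> RegressionMetrics:
    """R² (1 - SSres/SStot), MSE and MAE.

    With zero-variance truth the coefficient of determination is undefined
    and reported as ``None`` rather than an arbitrary number.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    residual = yt - yp
    mse = float(np.mean(residual ** 2))
    mae = float(np.mean(np.abs(residual)))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(residual ** 2)) / ss_tot
    return RegressionMetrics(r2=r2, mse=mse, mae=mae)


# ---------------------------------------------------------------------------
# Virtual screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningResult:
    threshold: float
    n_selected: int
    n_active: int
    ef: float


def score_threshold(scores: Sequence[float], percentile: float = 0.1) -> float:
    """Lower-tail order statistic: the score at rank ceil(p/100 * n).

    With the default 0.1 percentile the rank is 1 per 1000 scores, matching
    an active base rate of 10^-3 when used as an activity cutoff.
    """
    arr = np.sort(np.asarray(scores, dtype=float))
    if arr.size == 0:
        raise ValueError("empty score vector")
    rank = max(1, math.ceil(percentile / 100.0 * arr.size))
    return float(arr[rank - 1])


def enrichment_factor(n_selected: int, n_active_selected: int, base_rate: float) -> float:
    """(active rate in selection) / (active rate in library)."""
    if n_selected <= 0:
        raise ValueError("n_selected must be positive")
    if not 0 < base_rate <= 1:
        raise ValueError("base_rate must lie in (0, 1]")
    if not 0 <= n_active_selected <= n_selected:
        raise ValueError("n_active_selected out of range")
    return (n_active_selected / n_selected) / base_rate


class Ranker:
    """Model-adapter contract for screening: predict scores for SMILES."""

    def predict(self, smiles: Sequence[str]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def run_screen(ranker: Ranker, library: Sequence[str], target, backend,
               top_k: int = DEFAULT_TOP_K,
               threshold: Optional[float] = None,
               base_rate: float = DEFAULT_BASE_RATE,
               params: Optional[DockingParams] = None) -> ScreeningResult:
    """Rank the library, dock the top-k, and compute the enrichment factor.

    Molecules are labelled active when their actual best docking score is
    below the threshold (default: the published per-target constant).  Ties
    at the top-k boundary are broken by canonical SMILES order for
    determinism.  Prep-rejected molecules are excluded from the selection;
    other backend failures are logged and count as inactive.
    """
    if top_k > len(library):
        raise ValueError(f"top_k={top_k} exceeds library size {len(library)}")
    if threshold is None:
        threshold = SCREENING_THRESHOLDS[target.name]
    params = params or DockingParams()
    preds = np.asarray(ranker.predict(list(library)), dtype=float)
    order = sorted(range(len(library)), key=lambda i: (preds[i], library[i]))
    selected = [library[i] for i in order[:top_k]]
    n_active = 0
    n_selected = 0
    fast = isinstance(backend, MockBackend)
    for smi in selected:
        try:
            if fast:
                if validate_ligand(smi) is not None:
                    continue
                score = backend.score_smiles(target, smi)
            else:
                score = best_score(dock(target, smi, params, backend))
        except BackendRejection:
            continue
        except Exception:  # backend failure: counted, labelled inactive
            n_selected += 1
            continue
        n_selected += 1
        if score < threshold:
            n_active += 1
    return ScreeningResult(threshold=threshold, n_selected=n_selected,
                           n_active=n_active,
                           ef=enrichment_factor(n_selected, n_active, base_rate))


# ---------------------------------------------------------------------------
# De novo objectives
# ---------------------------------------------------------------------------

class ObjectiveKind(Enum):
    F2 = "f2"
    PROMISCUOUS_PPAR = "promiscuous_ppar"
    SELECTIVE_JAK2 = "selective_jak2"


_OBJECTIVE_TARGETS = {
    ObjectiveKind.F2: ("F2",),
    ObjectiveKind.PROMISCUOUS_PPAR: ("PPARA", "PPARD", "PPARG"),
    ObjectiveKind.SELECTIVE_JAK2: ("JAK2", "LCK"),
}


@dataclass(frozen=True)
class ObjectiveSpec:
    kind: ObjectiveKind
    lck_anchor: float = LCK_ANCHOR
    penalty_weight: float = QED_PENALTY_WEIGHT

    @property
    def targets(self) -> tuple[str, ...]:
        return _OBJECTIVE_TARGETS[self.kind]


def qed_penalty(qed: float, weight: float = QED_PENALTY_WEIGHT) -> float:
    """Druglikeness penalty ``weight * (1 - QED)``: 0 for a perfectly
    druglike molecule, ``weight`` for a hopeless one."""
    if not 0 <= qed <= 1:
        raise ValueError("QED must lie in [0, 1]")
    return weight * (1.0 - qed)


def objective_value(spec: ObjectiveSpec, scores: dict[str, float], qed: float) -> float:
    """Evaluate a de novo objective from per-target docking scores and QED.

    * F2: ``s(F2) + penalty``
    * Promiscuous PPAR: ``max(s(PPARA), s(PPARD), s(PPARG)) + penalty`` —
      the worst of the three, so all must bind.
    * Selective JAK2: ``s(JAK2) - min(s(LCK), anchor) + penalty`` — the LCK
      score is anchored at its median (-8.1): scoring worse than the median
      on the off-target brings no extra reward.

    Lower is better throughout.
    """
    missing = [t for t in spec.targets if t not in scores]
    if missing:
        raise KeyError(f"missing target scores: {missing}")
    pen = qed_penalty(qed, spec.penalty_weight)
    if spec.kind is ObjectiveKind.F2:
        return scores["F2"] + pen
    if spec.kind is ObjectiveKind.PROMISCUOUS_PPAR:
        return max(scores[t] for t in spec.targets) + pen
    return scores["JAK2"] - min(scores["LCK"], spec.lck_anchor) + pen


# ---------------------------------------------------------------------------
# Budget ledger and trajectories
# ---------------------------------------------------------------------------

class BudgetExhausted(RuntimeError):
    pass


@dataclass
class EvaluationLedger:
    """Append-only accounting of objective evaluations.

    The budget counts *unique* molecules; re-evaluating a known molecule is
    served from the cache and consumes nothing.  Failed preparations consume
    budget with value +inf, so an optimizer cannot probe for free.
    """

    budget: int = DEFAULT_BUDGET
    calls: list[tuple[str, float]] = field(default_factory=list)
    cache: dict[str, float] = field(default_factory=dict)

    @property
    def unique_calls(self) -> int:
        return len(self.cache)

    def record(self, smiles: str, value: float) -> float:
        if smiles in self.cache:
            self.calls.append((smiles, self.cache[smiles]))
            return self.cache[smiles]
        if self.unique_calls >= self.budget:
            raise BudgetExhausted(f"budget of {self.budget} unique evaluations exhausted")
        self.cache[smiles] = value
        self.calls.append((smiles, value))
        return value

    def evaluate(self, smiles: str, fn: Callable[[str], float]) -> float:
        """Evaluate ``fn`` under budget accounting (cache first)."""
        if smiles in self.cache:
            return self.record(smiles, self.cache[smiles])
        if self.unique_calls >= self.budget:
            raise BudgetExhausted(f"budget of {self.budget} unique evaluations exhausted")
        try:
            value = fn(smiles)
        except BackendRejection:
            value = math.inf
        except ValueError:
            value = math.inf
        return self.record(smiles, value)

    def best(self) -> float:
        finite = [v for _, v in self.calls if math.isfinite(v)]
        return min(finite) if finite else math.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, columns=["smiles", "objective"])


def make_objective_fn(spec: ObjectiveSpec, backend, targets: dict,
                      params: Optional[DockingParams] = None) -> Callable[[str], float]:
    """Bind an ObjectiveSpec to a backend and prepared targets.

    With the mock backend the descriptor-level fast path is used; otherwise
    each constituent target is docked in full.
    """
    params = params or DockingParams()
    fast = isinstance(backend, MockBackend)

    def fn(smiles: str) -> float:
        verdict = validate_ligand(smiles)
        if verdict is not None:
            return math.inf
        qed = property_profile(smiles)["QED"]
        scores = {}
        for t in spec.targets:
            tgt = targets[t]
            if fast:
                scores[t] = backend.score_smiles(tgt, smiles)
            else:
                scores[t] = best_score(dock(tgt, smiles, params, backend))
        return objective_value(spec, scores, qed)

    return fn


def evaluate_with_budget(ledger: EvaluationLedger, spec: ObjectiveSpec,
                         smiles: str, backend, targets: dict,
                         params: Optional[DockingParams] = None) -> float:
    """One budgeted objective evaluation (cache hits are free)."""
    return ledger.evaluate(smiles, make_objective_fn(spec, backend, targets, params))


def trajectory(ledger: EvaluationLedger, k: int = 1) -> list[Optional[float]]:
    """k-th best objective value after each call.

    Entry ``i`` is the k-th smallest objective among calls ``1..i+1``;
    ``None`` while fewer than ``k`` calls have been made.  ``k=1`` is the
    running minimum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    import heapq
    heap: list[float] = []  # max-heap (negated) of the k smallest so far
    out: list[Optional[float]] = []
    for _, value in ledger.calls:
        if len(heap) < k:
            heapq.heappush(heap, -value)
        elif value < -heap[0]:
            heapq.heapreplace(heap, -value)
        out.append(-heap[0] if len(heap) == k else None)
    return out
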