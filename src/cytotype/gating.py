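"""Reverse-engineering sorting gates for annotated populations.

Once cell types are annotated in silico, physically sorting them needs a
sequence of one-sided per-marker thresholds a cytometer operator can draw.
``fit_gate`` searches for such an axis-aligned conjunction by greedy
forward selection: at each step every (marker, direction, threshold)
candidate on a per-marker quantile grid is scored by the F-beta measure of
the gated set against the target population, the best refinement is added
while it still improves, and a coordinate-wise re-optimization pass then
fine-tunes each threshold.  Steps come out ordered from most to least
important, ready to be transcribed into sequential rectangle gates.

Populations with no marker whose distribution rises above every other
type's gate poorly -- there is no positive threshold to anchor the gate --
which mirrors the practical failure mode seen when sorting precursor
populations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventTable

log = logging.getLogger(__name__)

__all__ = ["GateStep", "GateDefinition", "fit_gate", "apply_gate"]

GE = ">="
LE = "<="


@dataclass(frozen=True)
class GateStep:
    marker: str
    direction: str  # ">=" or "<="
    threshold: float

    def mask(self, events: EventTable) -> np.ndarray:
        col = events.column(self.marker)
        return col >= self.threshold if self.direction == GE else col <= self.threshold


@dataclass
class GateDefinition:
    """Ordered threshold steps selecting one population.

    Step order is importance order (first step added first); ``achieved``
    holds F1/accuracy/precision/recall on the data the gate was fit to.
    """

    target: str
    steps: list[GateStep]
    achieved: dict[str, float] = field(default_factory=dict)
    #: F-beta after each forward-selection step; nondecreasing by construction
    selection_scores: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "target": self.target,
            "steps": [
                {"marker": s.marker, "direction": s.direction, "threshold": s.threshold}
                for s in self.steps
            ],
            "achieved": self.achieved,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "GateDefinition":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            target=d["target"],
            steps=[GateStep(s["marker"], s["direction"], s["threshold"]) for s in d["steps"]],
            achieved=d.get("achieved", {}),
        )

    def to_table(self) -> pd.DataFrame:
        """Human-readable ordered threshold table for manual gate entry."""
        return pd.DataFrame(
            [
                {"order": i + 1, "marker": s.marker, "direction": s.direction,
                 "threshold": s.threshold}
                for i, s in enumerate(self.steps)
            ]
        )


def _confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    tn = float(np.sum(~pred & ~truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "F1": f1,
        "accuracy": (tp + tn) / len(pred),
        "precision": precision,
        "recall": recall,
    }


def _fbeta(pred: np.ndarray, truth: np.ndarray, beta: float) -> float:
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    b2 = beta * beta
    denom = (1 + b2) * tp + b2 * fn + fp
    return (1 + b2) * tp / denom if denom > 0 else 0.0


def fit_gate(
    events: EventTable,
    target: str,
    beta: float = 1.0,
    quantile_grid: int = 100,
    label_col: str = "final_label",
    min_cells: int = 50,
    min_improvement: float = 1e-4,
    max_steps: int | None = None,
) -> GateDefinition:
    """Greedy F-beta threshold search for one target population.

    Candidate thresholds sit on a ``quantile_grid``-point per-marker
    quantile grid.  Forward selection adds the best (marker, direction,
    threshold) while F-beta improves by more than ``min_improvement``;
    coordinate-wise re-optimization passes then re-tune each threshold
    until nothing moves.  By construction F-beta never decreases across
    steps.
    """
    if events.obs is None or label_col not in events.obs.columns:
        raise ValueError(f"events.obs lacks a {label_col!r} column")
    truth = events.obs[label_col].to_numpy() == target
    if not truth.any():
        raise ValueError(f"target population {target!r} not present")
    if truth.sum() < min_cells:
        raise ValueError(
            f"target population {target!r} has {int(truth.sum())} cells, "
            f"fewer than min_cells={min_cells}"
        )
    X = events.intensities
    qs = np.linspace(0.0, 1.0, quantile_grid)
    thresholds = np.quantile(X, qs, axis=0)  # (Q, M)

    used: dict[str, tuple[str, float]] = {}  # marker -> (direction, threshold)

    def gate_mask(exclude: str | None = None) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for m, (d, t) in used.items():
            if m == exclude:
                continue
            col = X[:, events.marker_index(m)]
            mask &= col >= t if d == GE else col <= t
        return mask

    def best_candidate(base: np.ndarray, markers: Sequence[str]) -> tuple[float, str, str, float]:
        best = (-1.0, "", GE, 0.0)
        for m in markers:
            col = X[:, events.marker_index(m)]
            for t in thresholds[:, events.marker_index(m)]:
                for d, pred in ((GE, col >= t), (LE, col <= t)):
                    score = _fbeta(base & pred, truth, beta)
                    if score > best[0]:
                        best = (score, m, d, float(t))
        return best

    current_score = _fbeta(gate_mask(), truth, beta)
    order: list[str] = []
    trace: list[float] = []
    # forward selection
    while True:
        if max_steps is not None and len(used) >= max_steps:
            break
        free = [m for m in events.markers if m not in used]
        if not free:
            break
        score, m, d, t = best_candidate(gate_mask(), free)
        if score <= current_score + min_improvement:
            break
        used[m] = (d, t)
        order.append(m)
        current_score = score
        trace.append(score)
    if not used:
        # nothing beats the all-pass gate; return the single best step
        score, m, d, t = best_candidate(np.ones(len(X), dtype=bool), events.markers)
        warnings.warn(
            f"no threshold improves on the trivial all-pass gate for "
            f"{target!r}; returning the single best step"
        )
        used[m] = (d, t)
        order.append(m)
        current_score = score
        trace.append(score)
    # coordinate-wise threshold re-optimization
    improved = True
    while improved:
        improved = False
        for m in order:
            base = gate_mask(exclude=m)
            col = X[:, events.marker_index(m)]
            d0, t0 = used[m]
            best_t, best_s, best_d = t0, current_score, d0
            for t in thresholds[:, events.marker_index(m)]:
                for d, pred in ((GE, col >= t), (LE, col <= t)):
                    s = _fbeta(base & pred, truth, beta)
                    if s > best_s + min_improvement:
                        best_t, best_s, best_d = float(t), s, d
            if (best_t, best_d) != (t0, d0):
                used[m] = (best_d, best_t)
                current_score = best_s
                improved = True

    steps = [GateStep(m, used[m][0], used[m][1]) for m in order]
    gate = GateDefinition(target=target, steps=steps, selection_scores=trace)
    mask, metrics = apply_gate(events, gate, label_col=label_col)
    gate.achieved = metrics
    return gate


def apply_gate(
    events: EventTable,
    gate: GateDefinition,
    label_col: str = "final_label",
) -> tuple[np.ndarray, dict[str, float]]:
    """Conjunction of all gate steps; metrics against labels when present."""
    missing = [s.marker for s in gate.steps if s.marker not in events.markers]
    if missing:
        raise ValueError("events are missing gate markers: " + ", ".join(missing))
    mask = np.ones(events.n_events, dtype=bool)
    for s in gate.steps:
        mask &= s.mask(events)
    metrics: dict[str, float] = {}
    if events.obs is not None and label_col in events.obs.columns:
        truth = events.obs[label_col].to_numpy() == gate.target
        metrics = _confusion_metrics(mask, truth)
    return mask, metrics
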