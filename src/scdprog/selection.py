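"""Rank-ordered sequential forward feature selection.

Candidates are appended in the order given by the ranking ensemble; each
candidate is kept iff it strictly improves the cost-sensitive SVM's F1 score
under inner cross-validation, and selection terminates at the first rejected
candidate (a skip-and-continue mode is available behind ``mode="scan"``).
Hyperparameter tuning (C and cost ratio) is nested inside every candidate
evaluation: the reported F1 is the best over the config's grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .csvm import CsvmConfig, fit_csvm

__all__ = ["f1_score", "SelectionResult", "InnerCVEvaluator", "sequential_forward_select"]

#: Absolute tolerance on "strictly improves".
IMPROVEMENT_TOL = 1e-9


def f1_score(confusion) -> float:
    """F1 = 2 * precision * sensitivity / (precision + sensitivity).

    ``confusion`` is anything exposing integer ``tp``/``fp``/``fn``/``tn``
    attributes, or a (tp, fp, fn, tn) tuple.  Returns 0 by convention when
    precision + sensitivity = 0 (no true positive found).
    """
    if hasattr(confusion, "tp"):
        tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    else:
        tp, fp, fn, tn = confusion
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"confusion cell {name} must be a nonnegative integer")
    if tp + fp + fn + tn == 0:
        raise ValueError("all-zero confusion matrix")
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)


@dataclass
class SelectionResult:
    """Outcome of one sequential forward selection run."""

    selected: list[int]
    selected_names: list[str] | None
    f1_trajectory: list[float]
    stopped_at: int | None  # position in the rank order of the first rejected candidate
    best_config: CsvmConfig

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "selected": self.selected,
            "selected_names": self.selected_names,
            "f1_trajectory": self.f1_trajectory,
            "stopped_at": self.stopped_at,
            "C": self.best_config.C,
            "cost_ratio": self.best_config.cost_ratio,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


class InnerCVEvaluator:
    """Inner cross-validated F1 of a candidate feature set, with tuning.

    ``cv`` is ``"loo"`` for leave-one-out or an integer for stratified
    k-fold (no shuffling; folds are deterministic).  Predictions are pooled
    across folds into one confusion matrix before computing F1.  The
    hyperparameter pair maximizing pooled F1 is reported alongside; grid
    order (C ascending, then ratio ascending) breaks ties.
    """

    def __init__(self, cfg: CsvmConfig | None = None, cv="loo"):
        self.cfg = cfg or CsvmConfig()
        self.cv = cv

    def _splits(self, y: np.ndarray):
        if self.cv == "loo":
            return list(LeaveOneOut().split(np.zeros_like(y), y))
        n_splits = min(int(self.cv), int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
        return list(skf.split(np.zeros_like(y), y))

    def evaluate(self, X: np.ndarray, y: np.ndarray, feature_idx: Sequence[int]):
        """Return (best pooled F1, best CsvmConfig) for the candidate set."""
        import warnings as _warnings

        Xs = np.asarray(X, dtype=float)[:, list(feature_idx)]
        y = np.asarray(y, dtype=int)
        splits = self._splits(y)
        best_f1, best_cfg = -1.0, None
        for C in self.cfg.C_grid:
            for ratio in self.cfg.ratio_grid:
                cand = self.cfg.with_params(C, ratio)
                preds = np.empty_like(y)
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")  # constant folds are expected
                    for tr, te in splits:
                        model = fit_csvm(Xs[tr], y[tr], cand)
                        preds[te] = model.predict(Xs[te])
                tp = int(np.sum((preds == 1) & (y == 1)))
                fp = int(np.sum((preds == 1) & (y == 0)))
                fn = int(np.sum((preds == 0) & (y == 1)))
                tn = int(np.sum((preds == 0) & (y == 0)))
                f1 = f1_score((tp, fp, fn, tn))
                if f1 > best_f1 + IMPROVEMENT_TOL:
                    best_f1, best_cfg = f1, cand
        assert best_cfg is not None
        return best_f1, best_cfg


def sequential_forward_select(
    order: Sequence[int],
    X: np.ndarray,
    y: np.ndarray,
    evaluator: InnerCVEvaluator,
    feature_names: Sequence[str] | None = None,
    max_features: int = 50,
    mode: str = "stop",
    tol: float = IMPROVEMENT_TOL,
) -> SelectionResult:
    """Greedy forward selection along a fixed rank order.

    The top-ranked feature is always kept; each later candidate is kept iff
    the inner-CV F1 strictly improves (absolute tolerance ``tol``).  In the
    default ``mode="stop"`` the first rejection terminates the scan; with
    ``mode="scan"`` rejected candidates are skipped and the scan continues
    down the order.  Deterministic given its inputs.
    """
    order = [int(i) for i in order]
    if not order:
        raise ValueError("empty feature order")
    if mode not in ("stop", "scan"):
        raise ValueError("mode must be 'stop' or 'scan'")
    selected = [order[0]]
    best_f1, best_cfg = evaluator.evaluate(X, y, selected)
    trajectory = [best_f1]
    stopped_at: int | None = None
    for pos, idx in enumerate(order[1:], start=1):
        if len(selected) >= max_features:
            break
        f1, cfg = evaluator.evaluate(X, y, selected + [idx])
        if f1 > best_f1 + tol:
            selected.append(idx)
            best_f1, best_cfg = f1, cfg
            trajectory.append(f1)
        else:
            if stopped_at is None:
                stopped_at = pos
            if mode == "stop":
                break
    names = [feature_names[i] for i in selected] if feature_names is not None else None
    return SelectionResult(
        selected=selected,
        selected_names=names,
        f1_trajectory=trajectory,
        stopped_at=stopped_at,
        best_config=best_cfg,
    )
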