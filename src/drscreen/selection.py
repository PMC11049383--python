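"""Hyperparameter selection by stratified k-fold cross-validation.

The default grid sweeps forest size {100, 200, 300} × attributes per node
{1, 2, 3, 4} × leaf-creation threshold {0.0, 0.1, …, 1.0} — 132
configurations — on identical folds, so per-configuration comparisons are
paired.  Selection maximises mean accuracy with ties broken by sensitivity
and then specificity (the triple whose joint maximum identifies the chosen
configuration).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .forest import FRFParams, classify_evidence, train_forest
from .fuzzy import FuzzyEvidence
from .metrics import accuracy as _acc
from .metrics import confusion, sensitivity, specificity


@dataclass
class HyperGrid:
    trees: list[int] = field(default_factory=lambda: [100, 200, 300])
    attributes_per_node: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    leaf_thresholds: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(11)]
    )

    def configurations(self) -> list[tuple[int, int, float]]:
        """All (n_trees, attributes_per_node, leaf_threshold) combinations,
        in deterministic nested order."""
        return [
            (t, m, tau)
            for t in self.trees
            for m in self.attributes_per_node
            for tau in self.leaf_thresholds
        ]

    def __len__(self) -> int:
        return len(self.configurations())


@dataclass
class CVResult:
    """Cross-validation outcome: long-format fold metrics, per-configuration
    summary, the selected parameters, and the shared fold assignment."""

    folds_table: pd.DataFrame  # (n_trees, m, leaf_threshold, fold, metric, value)
    summary: pd.DataFrame      # per configuration: mean/sd of each metric
    best_config: FRFParams
    fold_assignment: np.ndarray
    fold_hash: str


def kfold_split(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (values 0..k-1), reproducible by seed.

    Fold sizes differ by at most one.  If either class has fewer members than
    k, stratification is impossible; a warning is issued and plain shuffled
    folds are used instead.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError("more folds than records")
    _, counts = np.unique(y, return_counts=True)
    assignment = np.empty(n, dtype=int)
    if counts.min() < k:
        warnings.warn("a class has fewer members than folds; using unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        assignment[test_idx] = f
    return assignment


def fold_assignment_hash(assignment: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(assignment, dtype=np.int64).tobytes()).hexdigest()


def _fold_metrics(pred_pos: np.ndarray, actual_pos: np.ndarray) -> dict[str, float]:
    cm = confusion(pred_pos, actual_pos)
    return {
        "accuracy": _acc(cm),
        "sensitivity": np.nan if sensitivity(cm) is None else sensitivity(cm),
        "specificity": np.nan if specificity(cm) is None else specificity(cm),
    }


def grid_search(
    evidence: FuzzyEvidence,
    grid: HyperGrid | None = None,
    k: int = 10,
    seed: int = 0,
    criterion: str = "accuracy",
    base_params: FRFParams | None = None,
    subsample: float | None = None,
) -> CVResult:
    """Evaluate every grid configuration with k-fold CV on identical folds.

    ``subsample`` (0–1] draws a stratified random fraction of the evidence
    once, before folding, so large sweeps stay tractable; ``base_params``
    carries the non-swept parameters (seed, bootstrap, combination rule).
    """
    if grid is None:
        grid = HyperGrid()
    configs = grid.configurations()
    if not configs:
        raise ValueError("empty hyperparameter grid")
    if base_params is None:
        base_params = FRFParams(seed=seed)

    y = evidence.classes[:, 1].astype(bool)
    if subsample is not None and subsample < 1.0:
        rng = np.random.default_rng(seed)
        keep = np.zeros(len(y), dtype=bool)
        for cls in (False, True):
            idx = np.flatnonzero(y == cls)
            take = max(1, int(round(subsample * len(idx))))
            keep[rng.choice(idx, size=take, replace=False)] = True
        evidence = evidence.subset(np.flatnonzero(keep))
        y = evidence.classes[:, 1].astype(bool)

    assignment = kfold_split(y, k, seed)
    fhash = fold_assignment_hash(assignment)

    rows = []
    for t, m, tau in configs:
        params = replace(base_params, n_trees=t, attributes_per_node=m,
                         leaf_threshold=tau)
        for f in range(k):
            test = assignment == f
            train_ev = evidence.subset(np.flatnonzero(~test))
            test_ev = evidence.subset(np.flatnonzero(test))
            try:
                forest = train_forest(train_ev, params)
            except ValueError as exc:
                raise ValueError(
                    f"training failed for configuration (trees={t}, m={m}, "
                    f"leaf_threshold={tau}), fold {f}: {exc}"
                ) from exc
            votes = classify_evidence(forest, test_ev)
            pred_pos = votes[:, 1] >= votes[:, 0]
            for metric, value in _fold_metrics(pred_pos, y[test]).items():
                rows.append({"n_trees": t, "attributes_per_node": m,
                             "leaf_threshold": tau, "fold": f,
                             "metric": metric, "value": value})
    folds_table = pd.DataFrame(rows)

    keys = ["n_trees", "attributes_per_node", "leaf_threshold"]
    summary = (
        folds_table.pivot_table(index=keys + ["fold"], columns="metric",
                                values="value", observed=True)
        .groupby(level=keys)
        .agg(["mean", "std"])
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()

    order = summary.sort_values(
        by=[f"{criterion}_mean", "sensitivity_mean", "specificity_mean"],
        ascending=False, kind="mergesort",
    )
    top = order.iloc[0]
    best = replace(base_params,
                   n_trees=int(top["n_trees"]),
                   attributes_per_node=int(top["attributes_per_node"]),
                   leaf_threshold=float(top["leaf_threshold"]))
    return CVResult(folds_table, summary, best, assignment, fhash)
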