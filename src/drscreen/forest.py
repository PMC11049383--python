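"""Fuzzy decision-tree induction and the fuzzy random forest classifier.

Trees are grown by the cognitive-uncertainty induction scheme of Yuan and
Shaw: at each node a random subset of the attributes not yet used on the
path is drawn, and the candidate that minimises the mass-weighted
classification ambiguity of its fuzzy partition is selected.  A branch stops
growing when the largest class subsethood reaches the leaf-creation
threshold, when no attributes remain, or when the branch's evidence mass
falls below a support floor.  The forest aggregates tree votes (each a
normalised pair of class supports) by averaging, and reports the winning
vote mass as the prediction's certainty degree.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .cohort import PREDICTORS, CohortTable
from .fuzzy import CLASS_LABELS, FuzzyEvidence, FuzzyPartition, FuzzySet, fuzzify_cohort

MODEL_FORMAT = "drscreen-frf-1"

#: Minimum evidence mass below which a branch is closed as a vacuous leaf.
MIN_BRANCH_MASS = 1e-6


class UndefinedEvidenceError(ValueError):
    """Raised when an operation is asked to evaluate zero evidence mass."""


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or has the wrong format version."""


@dataclass(frozen=True)
class FRFParams:
    """Hyperparameters of the fuzzy random forest.

    ``n_trees``, ``attributes_per_node`` and ``leaf_threshold`` are the three
    quantities swept by the model-selection protocol; the defaults are the
    values that sweep selects (200 trees, 3 attributes per node, a high
    leaf-creation threshold).  ``significance_cut`` is an optional alpha-cut
    zeroing memberships below the cut before path combination; 0 disables it.
    """

    n_trees: int = 200
    attributes_per_node: int = 3
    leaf_threshold: float = 0.9
    significance_cut: float = 0.0
    seed: int = 0
    bootstrap: bool = True
    combine: str = "min"  # path-mass combination: "min" or "prod"
    vote_weighting: str = "equal"  # or "certainty"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.attributes_per_node < 1:
            raise ValueError("attributes_per_node must be positive")
        if not 0.0 <= self.leaf_threshold <= 1.0:
            raise ValueError("leaf_threshold must lie in [0, 1]")
        if self.combine not in ("min", "prod"):
            raise ValueError("combine must be 'min' or 'prod'")
        if self.vote_weighting not in ("equal", "certainty"):
            raise ValueError("vote_weighting must be 'equal' or 'certainty'")


@dataclass
class FuzzyRandomForest:
    """A trained ensemble: tree roots (nested dict nodes), the parameters it
    was grown with, and the frozen training-time fuzzy partitions."""

    trees: list[dict]
    params: FRFParams
    partitions: list[FuzzyPartition]
    class_labels: tuple[str, str] = CLASS_LABELS


@dataclass(frozen=True)
class Prediction:
    """Binary risk call with its certainty degree (the winning vote mass)."""

    label: str
    certainty: float
    votes: tuple[float, float]  # (without_risk, with_risk), sums to 1

    @property
    def certainty_of_dr(self) -> float:
        """Vote mass on the with-risk class regardless of the winning label."""
        return self.votes[1]


def fuzzy_subsethood(evidence_weights, class_memberships) -> float:
    """Degree to which fuzzy evidence E is contained in class C:
    S(E, C) = Σ min(μ_E, μ_C) / Σ μ_E — the truth level of "E implies C"."""
    e = np.asarray(evidence_weights, dtype=float)
    c = np.asarray(class_memberships, dtype=float)
    if e.shape != c.shape:
        raise ValueError("evidence and class membership vectors differ in length")
    tot = e.sum()
    if tot <= 0:
        raise UndefinedEvidenceError("zero evidence mass")
    return float(np.minimum(e, c).sum() / tot)


def possibility_ambiguity(pi) -> float:
    """Nonspecificity g(π) of a normalised possibility distribution:
    sort π descending, append 0, return Σ_i (π*_i − π*_{i+1}) ln i."""
    p = np.sort(np.asarray(pi, dtype=float))[::-1]
    p = np.append(p, 0.0)
    return float(sum((p[i] - p[i + 1]) * math.log(i + 1) for i in range(len(p) - 1)))


def classification_ambiguity(evidence_weights, class_memberships_per_class) -> float:
    """Ambiguity of the class possibility distribution induced by the evidence.

    Per-class subsethoods are normalised by their maximum into a possibility
    distribution, whose nonspecificity g(π) is returned: 0 when one class
    fully dominates, ln 2 when both classes are equally possible.
    """
    subs = np.array(
        [fuzzy_subsethood(evidence_weights, c) for c in class_memberships_per_class]
    )
    top = subs.max()
    if top <= 0:
        raise UndefinedEvidenceError("all class subsethoods are zero")
    return possibility_ambiguity(subs / top)


def _combine(w: np.ndarray, mu: np.ndarray, how: str) -> np.ndarray:
    return np.minimum(w, mu) if how == "min" else w * mu


def _cut(mu: np.ndarray, cut: float) -> np.ndarray:
    if cut <= 0:
        return mu
    return np.where(mu >= cut, mu, 0.0)


def select_attribute(
    candidates,
    evidence: FuzzyEvidence,
    path_weights: np.ndarray,
    combine: str = "min",
    significance_cut: float = 0.0,
) -> str:
    """Pick the candidate attribute minimising weighted partition ambiguity.

    For each candidate, every fuzzy set j of its partition defines a branch
    with evidence w_j = combine(path_weights, μ_j); the score is
    G = Σ_j (|w_j| / Σ|w|) · g(π_j).  Ties go to the lexicographically first
    candidate.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate attributes")
    if path_weights.sum() <= 0:
        raise UndefinedEvidenceError("zero path mass")
    classes = evidence.classes
    best_attr, best_score = None, np.inf
    for attr in sorted(candidates):
        mu = _cut(evidence.attr_memberships[attr], significance_cut)
        branch_masses = []
        branch_amb = []
        for j in range(mu.shape[1]):
            wj = _combine(path_weights, mu[:, j], combine)
            mass = wj.sum()
            if mass <= 0:
                continue
            branch_masses.append(mass)
            branch_amb.append(
                classification_ambiguity(wj, [classes[:, 0], classes[:, 1]])
            )
        if not branch_masses:
            continue
        masses = np.asarray(branch_masses)
        score = float((masses / masses.sum()) @ np.asarray(branch_amb))
        # scores within rounding noise count as ties -> lexicographic winner
        if score < best_score - 1e-12:
            best_attr, best_score = attr, score
    if best_attr is None:
        # every candidate's branches were vacuous; fall back to name order
        best_attr = sorted(candidates)[0]
    return best_attr


def _leaf(cls_idx: int, truth: float) -> dict:
    return {"leaf": True, "class": CLASS_LABELS[cls_idx], "truth": float(truth)}


def _class_subsethoods(w: np.ndarray, classes: np.ndarray) -> np.ndarray:
    tot = w.sum()
    return np.array([np.minimum(w, classes[:, k]).sum() / tot for k in range(2)])


def induce_tree(
    evidence: FuzzyEvidence,
    params: FRFParams,
    rng: np.random.Generator,
) -> dict:
    """Grow one fuzzy decision tree on ``evidence``.

    Nodes are plain dicts: internal nodes carry the split attribute and one
    child per fuzzy set of its partition; leaves carry the class label and
    its subsethood as the leaf truth degree.  Vacuous branches (mass below
    the support floor) become leaves inheriting the parent majority class.
    """
    if evidence.classes is None:
        raise ValueError("evidence has no class memberships")
    n = evidence.n
    if n == 0:
        raise ValueError("empty evidence")
    classes = evidence.classes
    attrs = evidence.attributes

    def grow(idx: np.ndarray, w: np.ndarray, remaining: list[str]) -> dict:
        subs = _class_subsethoods(w, classes[idx])
        # argmax with ties resolved toward with_risk (index 1)
        best = 1 if subs[1] >= subs[0] else 0
        if subs[best] >= params.leaf_threshold or not remaining:
            return _leaf(best, subs[best])
        k = min(params.attributes_per_node, len(remaining))
        pick = rng.choice(len(remaining), size=k, replace=False)
        cands = [remaining[i] for i in sorted(pick)]
        node_view = FuzzyEvidence(
            {a: evidence.attr_memberships[a][idx] for a in cands},
            evidence.partitions, classes[idx],
        )
        attr = select_attribute(
            cands, node_view, w,
            combine=params.combine, significance_cut=params.significance_cut,
        )
        mu = _cut(evidence.attr_memberships[attr], params.significance_cut)
        children = []
        next_remaining = [a for a in remaining if a != attr]
        for j in range(mu.shape[1]):
            wj = _combine(w, mu[idx, j], params.combine)
            keep = wj > 0
            if wj.sum() < MIN_BRANCH_MASS:
                children.append(_leaf(best, subs[best]))
            else:
                children.append(grow(idx[keep], wj[keep], next_remaining))
        return {"leaf": False, "attribute": attr, "children": children}

    idx0 = np.arange(n)
    w0 = np.ones(n)
    return grow(idx0, w0, sorted(attrs))


def tree_depth(node: dict) -> int:
    """Depth of a tree (a lone leaf has depth 0)."""
    if node["leaf"]:
        return 0
    return 1 + max(tree_depth(c) for c in node["children"])


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    # counter-derived substreams: tree i's stream is independent of n_trees
    return np.random.default_rng([seed, tree_index])


def train_forest(evidence: FuzzyEvidence, params: FRFParams) -> FuzzyRandomForest:
    """Train a fuzzy random forest: one tree per bootstrap resample (when
    enabled), each with its own attribute-sampling stream derived from the
    master seed, so retraining with identical inputs is bit-reproducible."""
    if evidence.classes is None:
        raise ValueError("evidence has no class memberships")
    present = evidence.classes.sum(axis=0)
    if present[0] == 0 or present[1] == 0:
        raise ValueError("training evidence must contain both classes")
    n = evidence.n
    trees = []
    for t in range(params.n_trees):
        rng = _tree_rng(params.seed, t)
        if params.bootstrap:
            idx = np.sort(rng.integers(0, n, size=n))
            ev_t = evidence.subset(idx)
        else:
            ev_t = evidence
        trees.append(induce_tree(ev_t, params, rng))
    parts = [evidence.partitions[a] for a in PREDICTORS if a in evidence.partitions]
    if len(parts) != len(evidence.partitions):
        parts = list(evidence.partitions.values())
    return FuzzyRandomForest(trees, params, parts)


def _tree_support(
    node: dict,
    w: np.ndarray,
    memberships: dict[str, np.ndarray],
    support: np.ndarray,
    combine: str,
    significance_cut: float,
) -> None:
    """Propagate record masses down every positive-mass branch, accumulating
    per-class support = Σ over reached leaves of (path mass × truth)."""
    if node["leaf"]:
        support[:, CLASS_LABELS.index(node["class"])] += w * node["truth"]
        return
    mu = _cut(memberships[node["attribute"]], significance_cut)
    for j, child in enumerate(node["children"]):
        wj = _combine(w, mu[:, j], combine)
        if wj.max() > 0:
            _tree_support(child, wj, memberships, support, combine, significance_cut)


def classify_evidence(forest: FuzzyRandomForest, ev: FuzzyEvidence) -> np.ndarray:
    """Forest vote masses, shape (n, 2), for already-fuzzified records."""
    n = ev.n
    p = forest.params
    total = np.zeros((n, 2))
    weight = np.zeros(n) if p.vote_weighting == "certainty" else None
    for tree in forest.trees:
        support = np.zeros((n, 2))
        _tree_support(tree, np.ones(n), ev.attr_memberships, support,
                      p.combine, p.significance_cut)
        tot = support.sum(axis=1)
        vote = np.full((n, 2), 0.5)
        ok = tot > 0
        vote[ok] = support[ok] / tot[ok, None]
        if p.vote_weighting == "certainty":
            cert = vote.max(axis=1)
            total += vote * cert[:, None]
            weight += cert
        else:
            total += vote
    if p.vote_weighting == "certainty":
        votes = total / np.maximum(weight, 1e-300)[:, None]
    else:
        votes = total / len(forest.trees)
    return votes


def classify_cohort(forest: FuzzyRandomForest, cohort: CohortTable) -> list[Prediction]:
    """Classify every record of a complete cohort.

    Each tree votes with its normalised class supports; the forest averages
    tree votes (optionally weighting each tree by its own certainty), labels
    by the larger vote mass, and breaks exact ties toward ``with_risk`` — the
    clinically conservative call.
    """
    ev = fuzzify_cohort(cohort, forest.partitions, require_labels=False)
    votes = classify_evidence(forest, ev)
    n = ev.n
    preds = []
    for i in range(n):
        v = (float(votes[i, 0]), float(votes[i, 1]))
        label_idx = 1 if v[1] >= v[0] else 0
        preds.append(Prediction(CLASS_LABELS[label_idx], v[label_idx], v))
    return preds


def classify(forest: FuzzyRandomForest, record) -> Prediction:
    """Classify one patient record (a mapping or a single-row cohort)."""
    import pandas as pd

    from .cohort import ALL_COLUMNS

    if isinstance(record, CohortTable):
        cohort = record
    else:
        row = dict(record)
        row.setdefault("patient_id", "record")
        df = pd.DataFrame([row])
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        cohort = CohortTable(df[list(ALL_COLUMNS)])
    for colname in PREDICTORS:
        if cohort.records[colname].isna().any():
            raise ValueError(f"record is missing predictor {colname!r}")
    return classify_cohort(forest, cohort)[0]


# ---------------------------------------------------------------------------
# model serialization


def _set_to_dict(s: FuzzySet) -> dict:
    if s.crisp:
        return {"label": s.label, "level": s.level}
    return {"label": s.label, "a": s.a, "b": s.b, "c": s.c, "d": s.d}


def _set_from_dict(d: dict) -> FuzzySet:
    if "level" in d:
        return FuzzySet(d["label"], level=d["level"])
    return FuzzySet(d["label"], d["a"], d["b"], d["c"], d["d"])


def save_model(forest: FuzzyRandomForest, path) -> None:
    """Write a forest to a structured plain-text (JSON) model file with a
    stable key order, so identical forests hash identically."""
    doc = {
        "format": MODEL_FORMAT,
        "params": asdict(forest.params),
        "class_labels": list(forest.class_labels),
        "partitions": [
            {"attribute": p.attribute, "sets": [_set_to_dict(s) for s in p.sets]}
            for p in forest.partitions
        ],
        "trees": forest.trees,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path) -> FuzzyRandomForest:
    """Load a model file written by :func:`save_model`; malformed or
    version-mismatched files raise :class:`ModelFormatError`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"malformed model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(
            f"unsupported model format {doc.get('format') if isinstance(doc, dict) else None!r}"
        )
    try:
        params = FRFParams(**doc["params"])
        partitions = [
            FuzzyPartition(p["attribute"], [_set_from_dict(s) for s in p["sets"]])
            for p in doc["partitions"]
        ]
        trees = doc["trees"]
        labels = tuple(doc["class_labels"])
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"incomplete model file: {exc}") from exc
    if len(trees) != params.n_trees:
        raise ModelFormatError("tree count does not match declared n_trees")
    return FuzzyRandomForest(trees, params, partitions, labels)
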