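"""Fuzzy partitions over clinical attributes and cohort fuzzification.

Continuous predictors are covered by trapezoidal fuzzy sets in Ruspini
configuration (memberships sum to one everywhere in the covered range), with
knots placed at cohort quantiles so each set carries comparable mass.
Categorical and boolean predictors get one crisp singleton set per level, so
fuzzification degenerates to one-hot encoding for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CONTINUOUS_PREDICTORS,
    PREDICTORS,
    SEX_LEVELS,
    TREATMENT_LEVELS,
    CohortTable,
)

CLASS_LABELS = ("without_risk", "with_risk")


@dataclass(frozen=True)
class FuzzySet:
    """A trapezoidal fuzzy set: membership 0 outside [a, d], 1 on [b, c],
    linear on the two flanks.  Crisp categorical levels use ``level`` instead
    of knots."""

    label: str
    a: float = np.nan
    b: float = np.nan
    c: float = np.nan
    d: float = np.nan
    level: str | None = None  # crisp categorical set

    def __post_init__(self):
        if self.level is None and not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"trapezoid knots must be ordered: {self}")

    @property
    def crisp(self) -> bool:
        return self.level is not None


def membership(fset: FuzzySet, value) -> np.ndarray | float:
    """Trapezoidal membership degree of ``value`` in ``fset`` (vectorized)."""
    if fset.crisp:
        out = np.asarray(value) == fset.level
        return out.astype(float) if out.ndim else float(out)
    x = np.asarray(value, dtype=float)
    out = np.zeros_like(x)
    a, b, c, d = fset.a, fset.b, fset.c, fset.d
    out = np.where((x >= b) & (x <= c), 1.0, out)
    if b > a:
        rising = (x > a) & (x < b)
        out = np.where(rising, (x - a) / (b - a), out)
    if d > c:
        falling = (x > c) & (x < d)
        out = np.where(falling, (d - x) / (d - c), out)
    return float(out) if out.ndim == 0 else out


@dataclass
class FuzzyPartition:
    """The ordered fuzzy sets covering one attribute's range."""

    attribute: str
    sets: list[FuzzySet]

    def __post_init__(self):
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate set labels in partition {self.attribute}")

    @property
    def crisp(self) -> bool:
        return all(s.crisp for s in self.sets)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sets]

    def memberships(self, values) -> np.ndarray:
        """(n, n_sets) membership matrix; continuous values are clamped to the
        covered range so out-of-range inputs load the outermost set."""
        if self.crisp:
            return np.column_stack([membership(s, values) for s in self.sets])
        x = np.asarray(values, dtype=float)
        lo = self.sets[0].a
        hi = self.sets[-1].d
        x = np.clip(x, lo, hi)
        return np.column_stack([membership(s, x) for s in self.sets])


@dataclass
class FuzzyEvidence:
    """Per-attribute membership matrices plus crisp class memberships.

    ``attr_memberships[name]`` is an (n, n_sets) matrix; ``classes`` is an
    (n, 2) crisp matrix ordered (without_risk, with_risk).
    """

    attr_memberships: dict[str, np.ndarray]
    partitions: dict[str, FuzzyPartition]
    classes: np.ndarray | None = None
    patient_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        first = next(iter(self.attr_memberships.values()))
        return first.shape[0]

    @property
    def attributes(self) -> list[str]:
        return list(self.attr_memberships)

    def subset(self, idx: np.ndarray) -> "FuzzyEvidence":
        return FuzzyEvidence(
            {k: v[idx] for k, v in self.attr_memberships.items()},
            self.partitions,
            None if self.classes is None else self.classes[idx],
            None if self.patient_ids is None else self.patient_ids[idx],
        )


def _trapezoid_knots(quantiles: np.ndarray, overlap: float) -> list[tuple[float, float, float, float]]:
    """Build Ruspini trapezoids from breakpoints.

    ``quantiles`` holds n_sets+1 breakpoints (min, interior cut points, max).
    Each interior breakpoint becomes a linear crossover zone of half-width
    ``overlap`` times the smaller neighbouring gap; adjacent flanks mirror one
    another so memberships sum to one across the whole range.
    """
    p = quantiles
    k = len(p) - 1  # number of sets
    gaps = np.diff(p)
    half = np.zeros(len(p))
    for j in range(1, k):
        half[j] = overlap * min(gaps[j - 1], gaps[j])
    knots = []
    for j in range(k):
        a = p[j] - half[j]
        b = p[j] + half[j]
        c = p[j + 1] - half[j + 1]
        d = p[j + 1] + half[j + 1]
        knots.append((a, b, max(b, c), max(b, d)))
    return knots


_SET_NAMES = {2: ("low", "high"), 3: ("low", "medium", "high"),
              4: ("low", "medium_low", "medium_high", "high"),
              5: ("very_low", "low", "medium", "high", "very_high")}


def build_default_partitions(
    cohort: CohortTable,
    n_sets: int | dict[str, int] = 3,
    overlap: float = 0.25,
) -> list[FuzzyPartition]:
    """Quantile-based Ruspini partitions for the ten predictors.

    Continuous attributes get ``n_sets`` trapezoids with breakpoints at evenly
    spaced cohort quantiles; categorical and boolean attributes get one crisp
    set per level.  A constant attribute collapses to a single degenerate set
    with a warning.
    """
    if cohort.n == 0:
        raise ValueError("cannot build partitions from an empty cohort")
    df = cohort.records
    partitions = []
    for attr in PREDICTORS:
        if attr in CONTINUOUS_PREDICTORS:
            k = n_sets[attr] if isinstance(n_sets, dict) else n_sets
            if k < 2:
                raise ValueError(f"need at least 2 fuzzy sets for {attr}")
            vals = df[attr].dropna().to_numpy(dtype=float)
            qs = np.quantile(vals, np.linspace(0, 1, k + 1))
            if qs[0] == qs[-1]:
                warnings.warn(f"attribute {attr} is constant; using one degenerate set")
                v = qs[0]
                partitions.append(FuzzyPartition(attr, [FuzzySet("all", v, v, v, v)]))
                continue
            # collapse duplicated quantiles (heavy ties) while keeping order
            uniq = np.unique(qs)
            if len(uniq) < k + 1:
                qs = uniq
                k = len(qs) - 1
            names = _SET_NAMES.get(k, tuple(f"set{i}" for i in range(k)))
            sets = [
                FuzzySet(names[j], *knots)
                for j, knots in enumerate(_trapezoid_knots(qs, overlap))
            ]
            partitions.append(FuzzyPartition(attr, sets))
        elif attr == "sex":
            partitions.append(
                FuzzyPartition(attr, [FuzzySet(lv, level=lv) for lv in SEX_LEVELS])
            )
        elif attr == "dm_treatment":
            levels = [lv for lv in TREATMENT_LEVELS
                      if (df[attr] == lv).any()] or list(TREATMENT_LEVELS)
            partitions.append(
                FuzzyPartition(attr, [FuzzySet(lv, level=lv) for lv in levels])
            )
        else:  # boolean
            partitions.append(
                FuzzyPartition(attr, [FuzzySet("no", level="False"),
                                      FuzzySet("yes", level="True")])
            )
    return partitions


def _attr_values(df: pd.DataFrame, attr: str) -> np.ndarray:
    if attr in CONTINUOUS_PREDICTORS:
        return df[attr].to_numpy(dtype=float)
    if attr in ("sex", "dm_treatment"):
        return df[attr].astype(str).to_numpy()
    # booleans are matched against crisp levels "True"/"False"
    return df[attr].map({True: "True", False: "False"}).astype(str).to_numpy()


def fuzzify_cohort(
    cohort: CohortTable,
    partitions: list[FuzzyPartition],
    require_labels: bool = True,
    outcome: str = "outcome_any_dr",
) -> FuzzyEvidence:
    """Convert a complete cohort into membership matrices over ``partitions``.

    ``outcome`` selects which label column becomes the crisp class membership
    (positive class = ``with_risk``).  With ``require_labels=False`` the class
    matrix is omitted, as for prediction-time cohorts.
    """
    df = cohort.records
    for attr in PREDICTORS:
        if df[attr].isna().any():
            raise ValueError(f"cohort is not complete on predictor {attr!r}")
    attr_m = {}
    part_map = {}
    for part in partitions:
        vals = _attr_values(df, part.attribute)
        attr_m[part.attribute] = part.memberships(vals)
        part_map[part.attribute] = part
    classes = None
    if require_labels:
        lab = df[outcome]
        if lab.isna().any():
            raise ValueError(f"missing outcome label {outcome!r}")
        pos = lab.to_numpy(dtype=bool)
        classes = np.column_stack([~pos, pos]).astype(float)
    return FuzzyEvidence(attr_m, part_map, classes,
                         df["patient_id"].to_numpy())
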