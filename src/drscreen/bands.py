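"""Risk bands and screening-interval recommendations.

The ensemble's certainty of developing retinopathy is mapped onto four bands
— normal, low, moderate, high — and each band onto a recommended number of
months until the next retinal screening (defaults 24/18/12/6).  The default
band cut-offs (0.30, 0.50, 0.70) are package choices, not published values;
boundary certainties fall into the higher-risk band, the clinically
conservative side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import CohortTable
from .forest import FuzzyRandomForest, Prediction, classify_cohort

BANDS = ("normal", "low", "moderate", "high")


@dataclass(frozen=True)
class BandConfig:
    """Three strictly increasing cut-offs on certainty-of-DR partitioning
    [0, 1] into the four bands, plus the band → months interval map."""

    cutoffs: tuple[float, float, float] = (0.30, 0.50, 0.70)
    intervals: dict[str, int] = field(
        default_factory=lambda: {"normal": 24, "low": 18, "moderate": 12, "high": 6}
    )

    def __post_init__(self):
        c = self.cutoffs
        if not (0.0 < c[0] < c[1] < c[2] < 1.0):
            raise ValueError("band cut-offs must be strictly increasing within (0, 1)")
        if set(self.intervals) != set(BANDS):
            raise ValueError(f"interval map must cover exactly the bands {BANDS}")
        if any(v <= 0 for v in self.intervals.values()):
            raise ValueError("screening intervals must be positive")
        for band in ("normal", "low", "moderate"):
            if not 12 <= self.intervals[band] <= 36:
                raise ValueError(
                    f"{band}-band interval must lie in the 12–36 month extension range"
                )


@dataclass(frozen=True)
class ScreeningRecommendation:
    patient_id: str
    band: str
    interval_months: int
    certainty: float  # certainty of developing DR, in [0, 1]
    rationale: str


def band_for(certainty_of_dr: float, config: BandConfig) -> str:
    """Band lookup; a certainty exactly at a cut-off takes the higher band."""
    c = config.cutoffs
    if certainty_of_dr < c[0]:
        return "normal"
    if certainty_of_dr < c[1]:
        return "low"
    if certainty_of_dr < c[2]:
        return "moderate"
    return "high"


def stratify(
    prediction: Prediction,
    config: BandConfig | None = None,
    patient_id: str = "",
) -> ScreeningRecommendation:
    """Turn a forest prediction into a band plus screening interval.

    The banded quantity is the certainty of developing retinopathy: the
    prediction's certainty when the label is ``with_risk``, its complement
    otherwise.
    """
    if config is None:
        config = BandConfig()
    p_dr = prediction.certainty_of_dr
    band = band_for(p_dr, config)
    months = config.intervals[band]
    rationale = (
        f"{100 * (1 - p_dr):.0f}% certainty of not developing retinopathy"
        f" -> {band} risk, next screening in {months} months"
    )
    return ScreeningRecommendation(patient_id, band, months, float(p_dr), rationale)


def batch_recommend(
    forest: FuzzyRandomForest,
    cohort: CohortTable,
    config: BandConfig | None = None,
) -> pd.DataFrame:
    """One recommendation per record, in input order, with columns
    (patient_id, band, interval_months, certainty)."""
    if config is None:
        config = BandConfig()
    if cohort.n == 0:
        return pd.DataFrame(
            columns=["patient_id", "band", "interval_months", "certainty"]
        )
    preds = classify_cohort(forest, cohort)
    ids = cohort.records["patient_id"].tolist()
    recs = [stratify(p, config, pid) for pid, p in zip(ids, preds)]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in recs],
            "band": [r.band for r in recs],
            "interval_months": [r.interval_months for r in recs],
            "certainty": [r.certainty for r in recs],
        }
    )


def band_counts(recommendations: pd.DataFrame) -> pd.Series:
    """Counts per band over a recommendations table, in band order."""
    return recommendations["band"].value_counts().reindex(BANDS, fill_value=0)
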