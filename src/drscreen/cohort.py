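"""Cohort reading, validation, derived clinical variables, and eligibility.

A cohort is a table of type-2-diabetes patients carrying the ten predictors
used by the risk model: current age, sex, body-mass index, diabetes duration,
diabetes treatment category, hypertension-control status, HbA1c, estimated
glomerular filtration rate (eGFR), 24-hour microalbuminuria, and presence of
mild diabetic retinopathy at baseline.  Two derived fields are supported:
eGFR from serum creatinine via the CKD-EPI 2009 creatinine equation, and
hypertension control from raw systolic/diastolic pressures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The ten predictor fields consumed by the risk model, in canonical order.
PREDICTORS: tuple[str, ...] = (
    "age",
    "sex",
    "bmi",
    "dm_duration",
    "dm_treatment",
    "htn_controlled",
    "hba1c",
    "egfr",
    "microalbuminuria",
    "mild_dr",
)

#: Continuous predictors (the rest are categorical or boolean).
CONTINUOUS_PREDICTORS: tuple[str, ...] = (
    "age",
    "bmi",
    "dm_duration",
    "hba1c",
    "egfr",
    "microalbuminuria",
)

SEX_LEVELS = ("male", "female")
TREATMENT_LEVELS = ("diet", "oral", "insulin", "insulin_analogue")
#: Baseline retinopathy grades; only the first two are study-eligible.
DR_GRADES = ("none", "mild", "moderate", "severe", "proliferative", "dme")

NUMERIC_FIELDS = (
    "age",
    "bmi",
    "dm_duration",
    "sbp",
    "dbp",
    "hba1c",
    "creatinine",
    "egfr",
    "microalbuminuria",
)
BOOL_FIELDS = ("htn_controlled", "mild_dr", "outcome_any_dr", "outcome_rdr")

ALL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "dm_duration",
    "dm_treatment",
    "sbp",
    "dbp",
    "htn_controlled",
    "hba1c",
    "creatinine",
    "egfr",
    "microalbuminuria",
    "mild_dr",
    "baseline_dr",
    "outcome_any_dr",
    "outcome_rdr",
)

#: Physiologic plausibility bounds (open intervals) used for validation.
RANGE_CHECKS = {
    "age": (0.0, 120.0),
    "bmi": (10.0, 80.0),
    "hba1c": (3.0, 20.0),
    "dm_duration": (0.0, np.inf),
    "egfr": (0.0, np.inf),
    "microalbuminuria": (0.0, np.inf),
}
# dm_duration / egfr / microalbuminuria may be exactly 0
CLOSED_LOWER = {"dm_duration", "egfr", "microalbuminuria"}


class SchemaError(ValueError):
    """A mapped column is absent or the file cannot be interpreted."""


@dataclass
class ValidationIssue:
    """A row-level problem detected while reading or validating a cohort."""

    row: int
    patient_id: str
    field: str
    message: str


@dataclass
class CohortTable:
    """An ordered collection of patient records with a provenance tag."""

    records: pd.DataFrame
    provenance: str = ""
    issues: list[ValidationIssue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.records["patient_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate patient_id: {dup!r}")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _coerce_bool(series: pd.Series) -> pd.Series:
    """Map common textual encodings of a boolean column to pandas nullable booleans."""
    truthy = {"1", "true", "yes", "y", "t"}
    falsy = {"0", "false", "no", "n", "f"}

    def conv(v):
        if pd.isna(v):
            return pd.NA
        s = str(v).strip().lower()
        if s in truthy:
            return True
        if s in falsy:
            return False
        return None  # sentinel: unparseable

    return series.map(conv)


def read_schema_config(path: str) -> dict[str, str]:
    """Read a ``canonical_field = source_column`` mapping from a plain-text file."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"unparseable schema line: {line!r}")
            key, _, value = line.partition("=")
            mapping[key.strip()] = value.strip()
    return mapping


def read_cohort(
    path,
    schema_config: dict[str, str] | str | None = None,
    sep: str | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read a delimited-text cohort file into a :class:`CohortTable`.

    ``schema_config`` maps canonical field names to source column names (a
    dict, or the path of a plain-text ``key = value`` file).  Unparseable
    cells are flagged in :attr:`CohortTable.issues` — rows are reported, not
    dropped, so that eligibility filtering stays an explicit, auditable step.
    """
    if isinstance(schema_config, str):
        schema_config = read_schema_config(schema_config)
    if sep is None:
        # comma default, tab accepted
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if ("\t" in header and "," not in header) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.mask(raw == "")

    if schema_config:
        missing = [src for src in schema_config.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"mapped column(s) not in file: {missing}")
        raw = raw.rename(columns={v: k for k, v in schema_config.items()})

    if "patient_id" not in raw.columns:
        raise SchemaError("mapped column(s) not in file: ['patient_id']")

    df = pd.DataFrame(index=raw.index)
    issues: list[ValidationIssue] = []
    df["patient_id"] = raw["patient_id"].astype(str)

    for col in NUMERIC_FIELDS:
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad = vals.isna() & raw[col].notna()
            for i in np.flatnonzero(bad.to_numpy()):
                issues.append(
                    ValidationIssue(int(i), df["patient_id"].iat[i], col,
                                    f"unparseable numeric value {raw[col].iat[i]!r}")
                )
            df[col] = vals.astype(float)
        else:
            df[col] = np.nan

    for col in BOOL_FIELDS:
        if col in raw.columns:
            vals = _coerce_bool(raw[col])
            bad = vals.map(lambda v: v is None)
            for i in np.flatnonzero(bad.to_numpy()):
                issues.append(
                    ValidationIssue(int(i), df["patient_id"].iat[i], col,
                                    f"unparseable boolean value {raw[col].iat[i]!r}")
                )
            df[col] = vals.map(lambda v: pd.NA if v is None else v).astype("boolean")
        else:
            df[col] = pd.array([pd.NA] * len(raw), dtype="boolean")

    for col, levels in (("sex", SEX_LEVELS), ("dm_treatment", TREATMENT_LEVELS),
                        ("baseline_dr", DR_GRADES)):
        if col in raw.columns:
            vals = raw[col].astype("string").str.strip().str.lower()
            bad = vals.notna() & ~vals.isin(levels)
            for i in np.flatnonzero(bad.to_numpy()):
                issues.append(
                    ValidationIssue(int(i), df["patient_id"].iat[i], col,
                                    f"unknown {col} level {raw[col].iat[i]!r}")
                )
            df[col] = vals.where(~bad)
        else:
            df[col] = pd.array([pd.NA] * len(raw), dtype="string")

    table = CohortTable(df[list(ALL_COLUMNS)],
                        provenance=provenance or str(path), issues=issues)
    issues.extend(_range_issues(table.records))
    return table


def _range_issues(df: pd.DataFrame) -> list[ValidationIssue]:
    issues = []
    for col, (lo, hi) in RANGE_CHECKS.items():
        vals = df[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < lo) | (vals > hi) if col in CLOSED_LOWER else (
                (vals <= lo) | (vals >= hi)
            )
        for i in np.flatnonzero(bad & ~np.isnan(vals)):
            issues.append(
                ValidationIssue(int(i), df["patient_id"].iat[i], col,
                                f"value {vals[i]} outside plausible range")
            )
    return issues


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort back to delimited text in the canonical column order."""
    out = cohort.records.copy()
    for col in BOOL_FIELDS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else ("1" if v else "0"))
    out.to_csv(path, sep=sep, index=False)


def compute_egfr_ckdepi(creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m²) from serum creatinine, CKD-EPI 2009.

    Uses the creatinine-only equation without the race coefficient:

        eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female]

    with κ = 0.7, α = −0.329 for women and κ = 0.9, α = −0.411 for men.
    Accepts scalars or arrays; ``sex`` is ``"male"``/``"female"``.
    """
    scr = np.asarray(creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    sex_a = np.asarray(sex)
    if np.any(scr <= 0) or np.any(age_a <= 0):
        raise ValueError("creatinine and age must be positive")
    female = sex_a == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age_a
        * np.where(female, 1.018, 1.0)
    )
    return float(egfr) if egfr.ndim == 0 else egfr


def derive_hypertension_control(sbp, dbp):
    """Blood pressure controlled: systolic < 140 mmHg AND diastolic < 90 mmHg."""
    sbp_a = np.asarray(sbp, dtype=float)
    dbp_a = np.asarray(dbp, dtype=float)
    if np.any(np.isnan(sbp_a)) or np.any(np.isnan(dbp_a)):
        raise ValueError("missing blood pressure and no hypertension-control flag")
    if np.any(sbp_a <= 0) or np.any(dbp_a <= 0):
        raise ValueError("blood pressures must be positive")
    out = (sbp_a < 140) & (dbp_a < 90)
    return bool(out) if out.ndim == 0 else out


def derive_fields(cohort: CohortTable) -> CohortTable:
    """Fill derivable predictors in place of missing ones.

    eGFR is computed from creatinine where absent; hypertension control from
    SBP/DBP where absent; ``mild_dr`` from an explicit baseline grade when
    one is given.  Records that lack both a value and its raw inputs are left
    missing and will fall out at the eligibility step.
    """
    df = cohort.records.copy()
    need = df["egfr"].isna() & df["creatinine"].notna() & df["age"].notna() & df["sex"].notna()
    if need.any():
        sub = df.loc[need]
        ok = (sub["creatinine"] > 0) & (sub["age"] > 0)
        idx = sub.index[ok]
        df.loc[idx, "egfr"] = compute_egfr_ckdepi(
            df.loc[idx, "creatinine"].to_numpy(),
            df.loc[idx, "age"].to_numpy(),
            df.loc[idx, "sex"].to_numpy(),
        )
    need = df["htn_controlled"].isna() & df["sbp"].notna() & df["dbp"].notna()
    if need.any():
        idx = df.index[need]
        df.loc[idx, "htn_controlled"] = derive_hypertension_control(
            df.loc[idx, "sbp"].to_numpy(), df.loc[idx, "dbp"].to_numpy()
        )
    need = df["mild_dr"].isna() & df["baseline_dr"].notna()
    if need.any():
        idx = df.index[need]
        df.loc[idx, "mild_dr"] = (df.loc[idx, "baseline_dr"] == "mild")
    return CohortTable(df, provenance=cohort.provenance, issues=list(cohort.issues))


def apply_eligibility(cohort: CohortTable) -> tuple[CohortTable, pd.DataFrame]:
    """Partition a cohort into the study-eligible subset and an exclusion report.

    Eligible records have all ten predictors present, plausible values, and a
    baseline retinopathy status of none or mild.  Returns the eligible cohort
    and a report with columns ``(patient_id, reason)``; every input record
    lands in exactly one of the two outputs.
    """
    df = cohort.records
    reasons = pd.Series([None] * len(df), index=df.index, dtype=object)

    beyond_mild = df["baseline_dr"].notna() & ~df["baseline_dr"].isin(["none", "mild"])
    reasons[beyond_mild] = "DR more serious than mild"

    incomplete = pd.Series(False, index=df.index)
    for col in PREDICTORS:
        incomplete |= df[col].isna()
    reasons[incomplete & reasons.isna()] = "incomplete"

    bad_rows = {iss.row for iss in cohort.issues if iss.field in RANGE_CHECKS}
    if bad_rows:
        pos = df.index[sorted(bad_rows)]
        mask = pd.Series(False, index=df.index)
        mask.loc[pos] = True
        reasons[mask & reasons.isna()] = "implausible value"

    excluded = reasons.notna()
    report = pd.DataFrame(
        {"patient_id": df.loc[excluded, "patient_id"].to_numpy(),
         "reason": reasons[excluded].to_numpy()}
    )
    eligible = CohortTable(
        df.loc[~excluded].reset_index(drop=True),
        provenance=cohort.provenance,
    )
    return eligible, report


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive summary: mean ± SD for continuous variables, counts and
    percentages for categorical ones (sample SD, ddof=1)."""
    if cohort.n < 2:
        raise ValueError("need at least 2 records to compute a standard deviation")
    df = cohort.records
    rows = []
    for col in CONTINUOUS_PREDICTORS:
        vals = df[col].dropna().to_numpy(dtype=float)
        rows.append({"variable": col, "level": "", "mean": vals.mean(),
                     "sd": vals.std(ddof=1), "count": np.nan, "percent": np.nan})
    for col in ("sex", "dm_treatment"):
        counts = df[col].value_counts(dropna=True)
        total = counts.sum()
        for level, cnt in counts.items():
            rows.append({"variable": col, "level": str(level), "mean": np.nan,
                         "sd": np.nan, "count": int(cnt),
                         "percent": 100.0 * cnt / total})
    for col in ("htn_controlled", "mild_dr", "outcome_any_dr", "outcome_rdr"):
        vals = df[col].dropna()
        if len(vals) == 0:
            continue
        cnt = int(vals.sum())
        rows.append({"variable": col, "level": "yes", "mean": np.nan, "sd": np.nan,
                     "count": cnt, "percent": 100.0 * cnt / len(vals)})
    return pd.DataFrame(rows)


def render_summary(summary: pd.DataFrame) -> str:
    """Human-readable one-variable-per-line rendering of a cohort summary."""
    buf = io.StringIO()
    for _, r in summary.iterrows():
        name = r["variable"] + (f" [{r['level']}]" if r["level"] else "")
        if np.isnan(r["count"]) if not pd.isna(r["count"]) else False:
            pass
        if pd.isna(r["count"]):
            buf.write(f"{name:<32s} {r['mean']:8.2f} ± {r['sd']:.2f}\n")
        else:
            buf.write(f"{name:<32s} {int(r['count']):8d} ({r['percent']:.1f}%)\n")
    return buf.getvalue()
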