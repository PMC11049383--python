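"""Synthetic type-2-diabetes cohorts for testing the screening pipeline.

Real primary-care EHR extracts of this kind are not publicly deposited, so
the generator emulates the published marginal structure of such a cohort:
continuous predictors are drawn from moment-matched truncated normals (age
68.01 ± 10.41 y, diabetes duration 9.11 ± 5.48 y, BMI 27.86 ± 5.17 kg/m²,
HbA1c 7.75 ± 1.59 %, eGFR 75.08 ± 16.55 mL/min/1.73 m²), 24-h
microalbuminuria (25.44 ± 125.92 mg — SD far above the mean) from a
moment-matched normal-range/log-normal-tail mixture, and the categorical
predictors at their published proportions (57% male; treatment 9.8% diet /
76.7% oral / 13.5% insulin; 30.9% uncontrolled hypertension; 7.64% baseline
mild retinopathy).  Age and eGFR are negatively coupled through a Gaussian
copula, since filtration rate declines mechanically with age.

Outcomes follow a logistic model on standardised covariates whose intercept
is calibrated by bisection to hit a target prevalence (15.5% any
retinopathy; 4.77% referable retinopathy, generated as a subset of the
any-retinopathy positives).  The effect sizes are package defaults chosen
for testability, not published quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from .cohort import ALL_COLUMNS, CohortTable

#: Default log-odds effects on the outcome linear predictor (per SD for
#: continuous covariates, per indicator for mild_dr and insulin use).  These
#: are package choices, sized so the true risk score discriminates at an AUC
#: near 0.9 — the level the emulated screening system reports on its real
#: cohort — leaving prediction error to the classifier rather than the data.
DEFAULT_COEFFICIENTS = {
    "hba1c": 1.5,
    "dm_duration": 1.0,
    "mild_dr": 3.0,
    "insulin": 0.75,
    "egfr": -0.5,
}


@dataclass(frozen=True)
class ContinuousMarginal:
    """Target mean/SD of one continuous predictor with truncation bounds."""

    mean: float
    sd: float
    lo: float
    hi: float


DEFAULT_MARGINALS = {
    "age": ContinuousMarginal(68.01, 10.41, 18.0, 110.0),
    "dm_duration": ContinuousMarginal(9.11, 5.48, 0.0, 60.0),
    "bmi": ContinuousMarginal(27.86, 5.17, 12.0, 70.0),
    "hba1c": ContinuousMarginal(7.75, 1.59, 3.5, 19.0),
    "egfr": ContinuousMarginal(75.08, 16.55, 1.0, 160.0),
}

#: Microalbuminuria mixture: normal-range uniform component plus a
#: log-normal tail carrying the heavy dispersion.
MICROALBUMINURIA = {"mean": 25.44, "sd": 125.92, "tail_frac": 0.15,
                    "normal_lo": 0.0, "normal_hi": 30.0}


@dataclass
class CohortSpec:
    """Everything needed to draw a reproducible synthetic cohort."""

    n: int = 10_000
    seed: int = 0
    marginals: dict[str, ContinuousMarginal] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    male_frac: float = 0.57
    treatment_probs: dict[str, float] = field(
        default_factory=lambda: {"diet": 0.098, "oral": 0.767, "insulin": 0.135}
    )
    htn_uncontrolled_frac: float = 0.309
    mild_dr_frac: float = 0.0764
    age_egfr_corr: float = -0.4
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    any_dr_intercept: float | None = None  # None -> calibrate to target
    rdr_intercept: float | None = None
    any_dr_target: float = 0.155
    rdr_target: float = 0.0477

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        tot = sum(self.treatment_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("treatment proportions must sum to 1")
        for attr, m in self.marginals.items():
            if m.sd <= 0:
                raise ValueError(f"{attr}: SD must be positive")
            if not (m.lo < m.hi):
                raise ValueError(f"{attr}: empty truncation interval")
            if m.lo > m.mean + 6 * m.sd or m.hi < m.mean - 6 * m.sd:
                raise ValueError(f"{attr}: truncation bounds exclude mean ± 6 SD")


@dataclass
class GeneratedCohort:
    """A synthetic cohort plus the true outcome linear predictors (with
    intercept), kept for oracle checks of downstream classifiers."""

    cohort: CohortTable
    true_linear_predictors: np.ndarray
    spec: CohortSpec
    any_dr_intercept: float
    rdr_intercept: float


def _truncnorm_params(target: ContinuousMarginal) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal has the target
    mean and SD (so truncation does not bias the marginal)."""
    def eqs(p):
        mu, sig = p
        sig = abs(sig)
        a, b = (target.lo - mu) / sig, (target.hi - mu) / sig
        m, v = truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - target.mean, np.sqrt(v) - target.sd]

    sol = root(eqs, [target.mean, target.sd])
    mu, sig = sol.x[0], abs(sol.x[1])
    return mu, sig


def _draw_truncnorm(rng, target: ContinuousMarginal, n: int,
                    z: np.ndarray | None = None) -> np.ndarray:
    mu, sig = _truncnorm_params(target)
    a, b = (target.lo - mu) / sig, (target.hi - mu) / sig
    if z is None:
        u = rng.uniform(size=n)
    else:
        u = norm.cdf(z)  # Gaussian-copula transform
    return truncnorm.ppf(u, a, b, loc=mu, scale=sig)


def _microalbuminuria_tail() -> tuple[float, float]:
    """Moment-matched log-normal (mu, sigma) for the heavy tail of the
    microalbuminuria mixture."""
    cfg = MICROALBUMINURIA
    p = cfg["tail_frac"]
    lo, hi = cfg["normal_lo"], cfg["normal_hi"]
    m_norm = 0.5 * (lo + hi)
    m2_norm = (hi - lo) ** 2 / 12 + m_norm**2
    m_tail = (cfg["mean"] - (1 - p) * m_norm) / p
    m2_total = cfg["sd"] ** 2 + cfg["mean"] ** 2
    m2_tail = (m2_total - (1 - p) * m2_norm) / p
    cv2 = m2_tail / m_tail**2 - 1.0
    sigma2 = np.log1p(cv2)
    mu = np.log(m_tail) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _bisect_intercept(lp: np.ndarray, u: np.ndarray, target: float,
                      tol: float = 0.002) -> float:
    """Intercept b0 such that the realised fraction of u < expit(b0 + lp)
    is within ``tol`` of target (the fraction is monotone in b0)."""
    lo, hi = -20.0, 20.0
    frac = lambda b0: float(np.mean(u < expit(b0 + lp)))
    while frac(lo) > target and lo > -60:
        lo -= 20
    while frac(hi) < target and hi < 60:
        hi += 20
    if frac(lo) > target or frac(hi) < target:
        raise ValueError("could not bracket the target prevalence")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if abs(frac(mid) - target) <= tol:
            return mid
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    rho = spec.age_egfr_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    df = pd.DataFrame({"patient_id": [f"S{i:07d}" for i in range(n)]})
    df["age"] = _draw_truncnorm(rng, spec.marginals["age"], n, z=z[:, 0])
    df["egfr"] = _draw_truncnorm(rng, spec.marginals["egfr"], n, z=z[:, 1])
    for attr in ("dm_duration", "bmi", "hba1c"):
        df[attr] = _draw_truncnorm(rng, spec.marginals[attr], n)

    cfg = MICROALBUMINURIA
    mu_t, sig_t = _microalbuminuria_tail()
    tail = rng.uniform(size=n) < cfg["tail_frac"]
    micro = rng.uniform(cfg["normal_lo"], cfg["normal_hi"], size=n)
    micro[tail] = rng.lognormal(mu_t, sig_t, size=int(tail.sum()))
    df["microalbuminuria"] = micro

    df["sex"] = np.where(rng.uniform(size=n) < spec.male_frac, "male", "female")
    levels = list(spec.treatment_probs)
    probs = np.array([spec.treatment_probs[lv] for lv in levels])
    df["dm_treatment"] = rng.choice(levels, size=n, p=probs)
    df["htn_controlled"] = rng.uniform(size=n) >= spec.htn_uncontrolled_frac
    df["mild_dr"] = rng.uniform(size=n) < spec.mild_dr_frac
    return df


def _linear_predictor(df: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    lp = np.zeros(len(df))
    for attr, coef in spec.coefficients.items():
        if attr == "mild_dr":
            lp += coef * df["mild_dr"].to_numpy(dtype=float)
        elif attr == "insulin":
            ins = df["dm_treatment"].isin(["insulin", "insulin_analogue"])
            lp += coef * ins.to_numpy(dtype=float)
        elif attr == "htn_uncontrolled":
            lp += coef * (~df["htn_controlled"].to_numpy(dtype=bool)).astype(float)
        else:
            m = spec.marginals[attr]
            lp += coef * (df[attr].to_numpy(dtype=float) - m.mean) / m.sd
    return lp


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw a reproducible synthetic cohort under ``spec``.

    Outcome labels: any retinopathy from a logistic model on the standardised
    covariates; referable retinopathy from a second logistic model evaluated
    only among the any-retinopathy positives, so the label hierarchy holds by
    construction.  Intercepts left as ``None`` are calibrated against the
    drawn cohort so realised prevalences sit on their targets.
    """
    rng = np.random.default_rng(spec.seed)
    df = _draw_covariates(spec, rng)
    lp = _linear_predictor(df, spec)

    u_any = rng.uniform(size=spec.n)
    if spec.any_dr_intercept is None:
        b0 = _bisect_intercept(lp, u_any, spec.any_dr_target)
    else:
        b0 = spec.any_dr_intercept
    any_dr = u_any < expit(b0 + lp)

    u_rdr = rng.uniform(size=spec.n)
    pos = np.flatnonzero(any_dr)
    if spec.rdr_intercept is None:
        prev_any = max(any_dr.mean(), 1e-12)
        cond_target = min(spec.rdr_target / prev_any, 0.999)
        if len(pos) > 0:
            b0r = _bisect_intercept(lp[pos], u_rdr[pos], cond_target,
                                    tol=max(0.002, 1.0 / max(len(pos), 1)))
        else:
            b0r = 0.0
    else:
        b0r = spec.rdr_intercept
    rdr = np.zeros(spec.n, dtype=bool)
    rdr[pos] = u_rdr[pos] < expit(b0r + lp[pos])

    df["outcome_any_dr"] = any_dr
    df["outcome_rdr"] = rdr
    df["baseline_dr"] = np.where(df["mild_dr"], "mild", "none")
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("htn_controlled", "mild_dr", "outcome_any_dr", "outcome_rdr"):
        df[col] = df[col].astype("boolean")
    table = CohortTable(df[list(ALL_COLUMNS)].copy(),
                        provenance=f"synthetic(seed={spec.seed}, n={spec.n})")
    return GeneratedCohort(table, b0 + lp, spec, b0, b0r)


def calibrate_intercept(
    spec: CohortSpec,
    target_prevalence: float,
    which: str = "any_dr",
    n_sim: int = 200_000,
) -> tuple[float, float]:
    """Bisect the logistic intercept so simulated prevalence hits the target.

    Returns ``(intercept, achieved_prevalence)``; the achieved value is the
    realised label fraction on a fixed large simulation (seeded from the
    spec), within 0.2 percentage points of the target.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    if which not in ("any_dr", "rdr"):
        raise ValueError("which must be 'any_dr' or 'rdr'")
    big = replace(spec, n=n_sim)
    rng = np.random.default_rng(spec.seed)
    df = _draw_covariates(big, rng)
    lp = _linear_predictor(df, big)
    u = rng.uniform(size=n_sim)
    if which == "rdr":
        # conditional layer: calibrate among simulated any-DR positives
        u_any = u
        b0_any = (spec.any_dr_intercept
                  if spec.any_dr_intercept is not None
                  else _bisect_intercept(lp, u_any, spec.any_dr_target))
        pos = np.flatnonzero(u_any < expit(b0_any + lp))
        prev_any = len(pos) / n_sim
        cond_target = min(target_prevalence / prev_any, 0.999)
        u2 = rng.uniform(size=n_sim)
        b0 = _bisect_intercept(lp[pos], u2[pos], cond_target)
        achieved = float(np.mean(u2[pos] < expit(b0 + lp[pos]))) * prev_any
    else:
        b0 = _bisect_intercept(lp, u, target_prevalence)
        achieved = float(np.mean(u < expit(b0 + lp)))
    if abs(achieved - target_prevalence) > 0.002:
        raise ValueError("calibration did not reach the target prevalence")
    return float(b0), achieved


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures


def _fixture_frame(values: dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame(values)
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("htn_controlled", "mild_dr", "outcome_any_dr", "outcome_rdr"):
        df[col] = df[col].astype("boolean")
    return df[list(ALL_COLUMNS)].copy()


#: Hand-solvable 12-record crisp cohort: outcome = mild_dr OR (uncontrolled
#: hypertension AND insulin).  Continuous predictors are held constant so
#: only the three crisp attributes carry signal.
TINY_CRISP_ROWS = {
    "patient_id": [f"T{i:02d}" for i in range(12)],
    "age": [65.0] * 12,
    "sex": ["male", "female"] * 6,
    "bmi": [28.0] * 12,
    "dm_duration": [9.0] * 12,
    "dm_treatment": ["oral", "oral", "insulin", "insulin"] * 3,
    "htn_controlled": [True, False] * 6,
    "hba1c": [7.5] * 12,
    "egfr": [75.0] * 12,
    "microalbuminuria": [20.0] * 12,
    "mild_dr": [False] * 8 + [True] * 4,
}


def make_fixture(name: str, n: int | None = None, seed: int = 0) -> GeneratedCohort:
    """Small deterministic cohorts for unit tests.

    ``tiny_crisp``: 12 records with purely categorical signal, hand-checkable
    against brute-force tree induction.  ``overlap_midpoints``: continuous
    values on a uniform grid so quantile-partition crossover points are
    predictable.  ``separable``: outcome a step function of HbA1c with a
    margin, so any sensible classifier reaches AUC 1.  ``null_signal``:
    default covariates with an independent coin-flip outcome (AUC ≈ 0.5).
    """
    if name == "tiny_crisp":
        rows = dict(TINY_CRISP_ROWS)
        uncontrolled_insulin = [
            (not h) and (t == "insulin")
            for h, t in zip(rows["htn_controlled"], rows["dm_treatment"])
        ]
        any_dr = [m or ui for m, ui in zip(rows["mild_dr"], uncontrolled_insulin)]
        rows["outcome_any_dr"] = any_dr
        rows["outcome_rdr"] = [a and m for a, m in zip(any_dr, rows["mild_dr"])]
        df = _fixture_frame(rows)
        table = CohortTable(df, provenance="fixture:tiny_crisp")
        lp = np.array([2.0 if y else -2.0 for y in any_dr])
        return GeneratedCohort(table, lp, CohortSpec(n=12, seed=seed), 0.0, 0.0)

    if name == "overlap_midpoints":
        m = n or 9
        grid = np.linspace(5.0, 11.0, m)
        rows = {
            "patient_id": [f"G{i:02d}" for i in range(m)],
            "age": np.linspace(50, 80, m),
            "sex": ["male"] * m,
            "bmi": np.linspace(22, 34, m),
            "dm_duration": np.linspace(1, 20, m),
            "dm_treatment": ["oral"] * m,
            "htn_controlled": [True] * m,
            "hba1c": grid,
            "egfr": np.linspace(50, 100, m),
            "microalbuminuria": np.linspace(5, 50, m),
            "mild_dr": [False] * m,
            "outcome_any_dr": [False] * (m // 2) + [True] * (m - m // 2),
        }
        rows["outcome_rdr"] = [False] * m
        table = CohortTable(_fixture_frame(rows), provenance="fixture:overlap_midpoints")
        return GeneratedCohort(table, grid - grid.mean(),
                               CohortSpec(n=m, seed=seed), 0.0, 0.0)

    if name in ("separable", "null_signal"):
        m = n or (200 if name == "separable" else 2000)
        spec = CohortSpec(n=m, seed=seed, coefficients={},
                          any_dr_intercept=logit(0.5 if name == "separable" else 0.155),
                          rdr_intercept=-2.0)
        gen = generate_cohort(spec)
        df = gen.cohort.records.copy()
        if name == "separable":
            # wide HbA1c margin: negatives at 5–7, positives at 9–11
            rng = np.random.default_rng(seed)
            pos = np.arange(m) % 2 == 0
            hba1c = np.where(pos, rng.uniform(9.0, 11.0, m), rng.uniform(5.0, 7.0, m))
            df["hba1c"] = hba1c
            df["outcome_any_dr"] = pd.array(pos, dtype="boolean")
            df["outcome_rdr"] = pd.array(pos & (np.arange(m) % 4 == 0),
                                         dtype="boolean")
            lp = np.where(pos, 4.0, -4.0)
        else:
            lp = np.zeros(m)  # outcome independent of covariates
        table = CohortTable(df, provenance=f"fixture:{name}")
        return GeneratedCohort(table, lp, spec, 0.0, 0.0)

    raise ValueError(f"unknown fixture {name!r}")
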