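"""Stage 1: ex-vivo gamma dose-response and subject radiosensitivities.

Fits the mixed Poisson dose-response model to the pre-flight samples
(random intercept + random dose slope per crew-mission), derives each
subject's average dose-response slope B_i (CAR per Gy, chord of the fitted
log-linear curve from zero to the subject's top dose), the repeat-flier
mission-effect model grouped by astronaut, and age correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from . import glmm
from .cohort import CohortTable, DEFAULT_DOSE_CAP

logger = logging.getLogger(__name__)

PRE_FIXED = ["const", "dose_Gy", "a50", "female"]
PRE_RANDOM = ["const", "dose_Gy"]


@dataclass
class PreflightFit:
    """Mixed Poisson fit of the ex-vivo dose response plus EB effects."""

    fit: glmm.MixedPoissonFit
    eb: glmm.RandomEffectPrediction
    include_baseline: bool
    n_rows_used: int
    subjects: pd.DataFrame  # subject_id, age_years, female, max pre dose

    @property
    def beta0(self) -> float:
        return self.fit.coef("const")

    @property
    def beta1(self) -> float:
        return self.fit.coef("dose_Gy")

    def subject_effects(self) -> pd.DataFrame:
        """Per-subject table: w0i, w1i posterior means and SDs."""
        df = self.eb.frame().rename(
            columns={
                "group": "subject_id",
                "w_const": "w0",
                "w_dose_Gy": "w1",
                "sd_const": "sd_w0",
                "sd_dose_Gy": "sd_w1",
            }
        )
        return df.merge(self.subjects, on="subject_id")


@dataclass
class SlopeEstimate:
    """Average slope of the fitted dose response for one subject, the chord
    B_i = (lambda_hat(x_max) - lambda_hat(0)) / x_max, in CAR/Gy."""

    subject_id: str
    B: float
    x_max: float
    x_min: float = 0.0


def _pre_frame(cohort: CohortTable, include_baseline: bool, dose_cap: float):
    df = cohort.df
    m = (df["phase"] == "pre") & (df["dose_Gy"] <= dose_cap)
    if not include_baseline:
        m &= df["timepoint"] != "baseline"
    out = df.loc[m].copy()
    out["a50"] = out["age_years"] - 50.0
    return out


def fit_preflight(
    cohort: CohortTable,
    include_baseline: bool = True,
    dose_cap: float = DEFAULT_DOSE_CAP,
    quad_order: int = 7,
) -> PreflightFit:
    """Fit the ex-vivo dose-response model on pre-flight rows.

    With ``include_baseline=False`` the unirradiated (dose 0) rows are held
    out — the variant whose EB effects feed the post-flight model, which
    reuses those baseline rows itself.
    """
    df = _pre_frame(cohort, include_baseline, dose_cap)
    if df.empty:
        raise ValueError("no pre-flight rows under the dose cap")
    ndose = df.groupby("subject_id")["dose_Gy"].nunique()
    if (ndose < 2).any():
        warnings.warn(
            f"{int((ndose < 2).sum())} subject(s) with <2 distinct doses; "
            "their EB effects are prior-dominated",
            stacklevel=2,
        )
    spec, counts = glmm.ModelSpec.from_frame(df, PRE_FIXED, PRE_RANDOM)
    fit = glmm.fit(spec, counts, quad_order=quad_order)
    eb = glmm.empirical_bayes(fit)
    subjects = (
        df.groupby("subject_id")
        .agg(
            age_years=("age_years", "first"),
            female=("female", "first"),
            max_dose_Gy=("dose_Gy", "max"),
        )
        .reset_index()
    )
    return PreflightFit(
        fit=fit,
        eb=eb,
        include_baseline=include_baseline,
        n_rows_used=len(df),
        subjects=subjects,
    )


def average_slope(
    pf: PreflightFit, subject_id: str, use_covariates: bool = True
) -> SlopeEstimate:
    """Average slope B_i of subject i's fitted dose response, CAR per Gy.

    Evaluates the fitted curve at dose 0 and at the subject's own maximum
    pre-flight dose with the subject's EB effects (and, by default, age and
    gender covariates) plugged in.
    """
    row = pf.subjects.loc[pf.subjects["subject_id"] == subject_id]
    if row.empty:
        raise KeyError(f"subject {subject_id!r} not in the pre-flight fit")
    row = row.iloc[0]
    labels = list(pf.eb.group_labels)
    w0, w1 = pf.eb.mean[labels.index(subject_id)]
    x_max = float(row["max_dose_Gy"])
    eta0 = pf.beta0 + w0
    if use_covariates:
        eta0 += pf.fit.coef("a50", 0.0) * (row["age_years"] - 50.0)
        eta0 += pf.fit.coef("female", 0.0) * row["female"]
    slope = pf.beta1 + w1
    lam0 = np.exp(eta0)
    lam_top = np.exp(eta0 + slope * x_max)
    return SlopeEstimate(subject_id, float((lam_top - lam0) / x_max), x_max)


def average_slopes(pf: PreflightFit, use_covariates: bool = True) -> pd.DataFrame:
    rows = [
        average_slope(pf, s, use_covariates)
        for s in pf.subjects["subject_id"]
    ]
    return pd.DataFrame(
        {"subject_id": [r.subject_id for r in rows],
         "B_per_Gy": [r.B for r in rows],
         "x_max_Gy": [r.x_max for r in rows]}
    )


@dataclass
class RepeatFlierResult:
    fit: glmm.MixedPoissonFit
    intercept_pct_change: float
    intercept_ci_pct: tuple
    intercept_p: float
    slope_term: Optional[float]
    slope_term_se: Optional[float]


def fit_repeat_flier(
    cohort: CohortTable,
    dose_cap: float = DEFAULT_DOSE_CAP,
    include_slope_term: bool = True,
    quad_order: int = 7,
) -> RepeatFlierResult:
    """Mission-number effect model grouped by astronaut (not crew-mission).

    Adds a second-mission indicator on the intercept (and, by default, on the
    dose slope) to the pre-flight model, with random effects per distinct
    astronaut so a repeat flier's two dose series share their person-level
    baseline and sensitivity.  The intercept effect is reported as a
    multiplicative % change in baseline CAR with a Wald 95% CI.
    """
    df = _pre_frame(cohort, include_baseline=True, dose_cap=dose_cap)
    nmiss = df.groupby("astronaut_id")["subject_id"].nunique()
    if (nmiss < 2).all():
        raise ValueError("no astronaut with two missions in the cohort")
    df["mission2"] = (df["mission_number"] == 2).astype(float)
    fixed = list(PRE_FIXED)
    if df["mission2"].any():
        fixed = fixed + ["mission2"]
        if include_slope_term:
            df["mission2_dose"] = df["mission2"] * df["dose_Gy"]
            fixed = fixed + ["mission2_dose"]
    else:
        logger.info("no mission-2 rows: reducing to the astronaut-grouped "
                    "pre-flight model")
    spec, counts = glmm.ModelSpec.from_frame(
        df, fixed, PRE_RANDOM, group="astronaut_id"
    )
    fit = glmm.fit(spec, counts, quad_order=quad_order)
    if "mission2" in fixed:
        est = fit.coef("mission2")
        se = fit.coef_se("mission2")
        lo, hi = est - 1.96 * se, est + 1.96 * se
        p = 2.0 * norm.sf(abs(est / se)) if se > 0 else np.nan
        pct = (np.exp(est) - 1.0) * 100.0
        ci = ((np.exp(lo) - 1.0) * 100.0, (np.exp(hi) - 1.0) * 100.0)
    else:
        pct, ci, p = 0.0, (0.0, 0.0), np.nan
    return RepeatFlierResult(
        fit=fit,
        intercept_pct_change=float(pct),
        intercept_ci_pct=ci,
        intercept_p=float(p),
        slope_term=fit.coef("mission2_dose") if "mission2_dose" in fixed else None,
        slope_term_se=(
            fit.coef_se("mission2_dose") if "mission2_dose" in fixed else None
        ),
    )


def correlate_with_age(
    values: Sequence[float], ages: Sequence[float], level: float = 0.95
):
    """Pearson r between a per-subject statistic and age, with Fisher-z CI."""
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if len(values) != len(ages) or len(values) < 4:
        raise ValueError("need >=4 paired observations")
    if np.ptp(values) == 0 or np.ptp(ages) == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(pearsonr(values, ages).statistic)
    n = len(values)
    zc = norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = zc / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))
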