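"""Stage 2: post-flight CAR prediction with plugged-in stage-1 effects.

The post-flight model pools each subject's post-mission samples (at the
mission BFO dose) with that subject's pre-flight *baseline* sample (dose 0,
held out of the stage-1 refit so no observation is used twice).  The stage-1
empirical-Bayes effects enter as known covariates: w0i on the intercept and
w1i scaled by dose, so pre-flight radiosensitivity can modify the in-vivo
dose slope.  A random intercept per crew-mission absorbs what the plug-ins
do not explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_rel

from . import glmm
from .cohort import CohortTable

POST_FIXED = ["const", "x", "a50", "female", "w0", "w1x"]
POST_RANDOM = ["const"]

#: coefficient labels in model order, for reading fits and injecting
#: published values: beta0=const, beta1=x (dose), beta2=a50, beta3=female,
#: beta4=w0, beta5=w1x.


@dataclass
class PredictorCombination:
    """One point on the prediction surface: dose/age/gender plus plug-ins."""

    label: str
    dose_Gy: float
    age: float
    female: int = 0
    w0: float = 0.0
    w1: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_Gy < 0:
            raise ValueError("dose must be nonnegative")


@dataclass
class PostflightDesign:
    df: pd.DataFrame
    spec: glmm.ModelSpec
    counts: np.ndarray
    n_post: int
    n_baseline: int


@dataclass
class PostflightFit:
    fit: glmm.MixedPoissonFit
    design: Optional[PostflightDesign] = None

    def coef(self, name: str) -> float:
        return self.fit.coef(name)

    @classmethod
    def from_coefficients(cls, beta, vcov=None) -> "PostflightFit":
        """Build from published coefficients, ordered as
        (const, dose, a50, female, w0, w1x) or given as a name->value map."""
        if isinstance(beta, dict):
            est = [beta[n] for n in POST_FIXED]
        else:
            est = list(beta)
        return cls(
            glmm.MixedPoissonFit.from_coefficients(
                POST_FIXED, est, vcov=vcov, z_names=POST_RANDOM
            )
        )


def assemble_postflight_design(
    cohort: CohortTable, stage1, extra_x: Optional[pd.Series] = None
) -> PostflightDesign:
    """Rows = all post-flight samples + pre-flight baseline samples.

    ``stage1`` must be a no-baseline pre-flight fit (its EB effects were
    estimated without the baseline rows reused here; anything else double
    counts data and raises).  ``extra_x`` optionally overrides the dose
    column (used by the dose-rate variant), indexed like the cohort frame.
    """
    if stage1.include_baseline:
        raise ValueError(
            "stage-1 fit must exclude baseline rows (they are reused here); "
            "refit with include_baseline=False"
        )
    df = cohort.df
    m = (df["phase"] == "post") | (
        (df["phase"] == "pre") & (df["timepoint"] == "baseline")
    )
    out = df.loc[m].copy()
    n_post = int((out["phase"] == "post").sum())
    n_base = len(out) - n_post

    eb = stage1.subject_effects().set_index("subject_id")
    missing = set(out["subject_id"]) - set(eb.index)
    if missing:
        raise ValueError(
            f"no stage-1 EB effects for subject(s): {sorted(missing)[:5]}"
        )
    out["w0"] = eb["w0"].reindex(out["subject_id"]).to_numpy()
    out["w1"] = eb["w1"].reindex(out["subject_id"]).to_numpy()
    if extra_x is not None:
        out["x"] = extra_x.reindex(out.index).to_numpy()
    else:
        out["x"] = np.where(out["phase"] == "post", out["dose_Gy"], 0.0)
    out.loc[out["phase"] == "pre", "x"] = 0.0
    out["w1x"] = out["w1"] * out["x"]
    out["a50"] = out["age_years"] - 50.0

    spec, counts = glmm.ModelSpec.from_frame(out, POST_FIXED, POST_RANDOM)
    return PostflightDesign(out, spec, counts, n_post, n_base)


def fit_postflight(design: PostflightDesign, quad_order: int = 7) -> PostflightFit:
    """Random-intercept Poisson fit of the post-flight prediction model."""
    fit = glmm.fit(design.spec, design.counts, quad_order=quad_order)
    return PostflightFit(fit, design)


def predict_combinations(
    pf: PostflightFit, combos: Sequence[PredictorCombination], level: float = 0.95
) -> pd.DataFrame:
    """Predicted CAR (%) with CIs for a list of predictor combinations.

    The plug-in effects w0/w1 are treated as known constants; the CI uses
    only the fixed-effect covariance.
    """
    fit = pf.fit
    V = np.asarray(fit.vcov_beta, float)
    zc = norm.ppf(0.5 + level / 2.0)
    rows = []
    for c in combos:
        vals = {
            "const": 1.0, "x": c.dose_Gy, "a50": c.age - 50.0,
            "female": float(c.female), "w0": c.w0, "w1x": c.w1 * c.dose_Gy,
        }
        vec = np.array([vals[n] for n in fit.x_names])
        eta = float(vec @ fit.beta)
        if np.all(np.isfinite(V)):
            se = float(np.sqrt(max(vec @ V @ vec, 0.0)))
            lo, hi = 100 * np.exp(eta - zc * se), 100 * np.exp(eta + zc * se)
        else:
            lo = hi = np.nan
        rows.append(
            {
                "label": c.label,
                "dose_Gy": c.dose_Gy,
                "age": c.age,
                "female": c.female,
                "w0": c.w0,
                "w1": c.w1,
                "car_pct": 100 * np.exp(eta),
                "lo_pct": lo,
                "hi_pct": hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DoseRateComparison:
    rate_fit: PostflightFit
    dose_fit: PostflightFit
    dose_rates_cGy_day: pd.Series  # per subject with post rows

    @property
    def aic_rate(self) -> float:
        return self.rate_fit.fit.aic

    @property
    def aic_dose(self) -> float:
        return self.dose_fit.fit.aic


def fit_dose_rate_variant(
    cohort: CohortTable, stage1, quad_order: int = 7
) -> DoseRateComparison:
    """Refit the post-flight model with BFO dose rate as the exposure.

    The dose rate is 100 * BFO dose / mission duration, i.e. cGy/day — the
    unit keeps the design column on a numerically comfortable scale and is
    the one used for reporting; the w1-by-exposure interaction is rebuilt on
    the same scale.  Fits the plain-dose model on the identical rows for an
    AIC/log-likelihood comparison.
    """
    df = cohort.df
    post = df["phase"] == "post"
    if df.loc[post, "mission_duration_days"].isna().any():
        raise ValueError("mission_duration_days missing for post-flight rows")
    x_rate = pd.Series(0.0, index=df.index)
    x_rate.loc[post] = (
        100.0 * df.loc[post, "dose_Gy"] / df.loc[post, "mission_duration_days"]
    )
    design_rate = assemble_postflight_design(cohort, stage1, extra_x=x_rate)
    design_dose = assemble_postflight_design(cohort, stage1)
    rate_fit = fit_postflight(design_rate, quad_order=quad_order)
    dose_fit = fit_postflight(design_dose, quad_order=quad_order)
    per_subject = (
        df.loc[post]
        .groupby("subject_id")
        .apply(
            lambda g: 100.0 * g["dose_Gy"].iloc[0] / g["mission_duration_days"].iloc[0],
            include_groups=False,
        )
        .rename("dose_rate_cGy_day")
    )
    return DoseRateComparison(rate_fit, dose_fit, per_subject)


@dataclass
class RecoveryResult:
    mean_early: float
    mean_late: float
    t: float
    p: float
    n_pairs: int


def recovery_test(cohort: CohortTable) -> RecoveryResult:
    """Paired t-test of observed CAR early vs late after landing.

    Uses subjects with both post-flight time points; rates are observed
    aberrations per scored cell (no model adjustment).
    """
    post = cohort.post_rows().copy()
    post["car"] = post["aberrations"] / post["cells_scored"]
    wide = post.pivot_table(
        index="subject_id", columns="timepoint", values="car", aggfunc="mean"
    )
    if "post_early" not in wide or "post_late" not in wide:
        raise ValueError("need both post-flight time points")
    wide = wide.dropna(subset=["post_early", "post_late"])
    if len(wide) < 2:
        raise ValueError("fewer than 2 subjects with both post time points")
    early = wide["post_early"].to_numpy()
    late = wide["post_late"].to_numpy()
    if np.allclose(early, late):
        t, p = 0.0, 1.0
    else:
        res = ttest_rel(early, late)
        t, p = float(res.statistic), float(res.pvalue)
    return RecoveryResult(
        float(early.mean()), float(late.mean()), t, p, int(len(wide))
    )
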