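"""Joint pre+post model and relative biological effectiveness (RBE).

All samples enter one mixed Poisson fit with separate slopes for the
ex-vivo gamma dose (pre-flight rows) and the in-vivo BFO dose (post-flight
rows), sharing intercept and covariates.  The RBE is the gamma dose needed
to produce the same expected aberration yield as one unit of space-radiation
dose: the ratio of the in-vivo to the ex-vivo log-linear slope.  A random
slope on the gamma dose gives subject-specific denominators and hence
subject-specific RBEs; no subject-level perturbation of the in-vivo slope is
modeled (the narrow BFO dose range cannot support one), so the per-subject
spread is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import glmm
from .cohort import CohortTable, DEFAULT_DOSE_CAP

RBE_FIXED = ["const", "x_pre", "x_post", "a50", "female"]
RBE_RANDOM = ["const", "x_pre"]


@dataclass
class RBEFit:
    fit: glmm.MixedPoissonFit
    eb: glmm.RandomEffectPrediction  # posterior means of (U0i, U1i)

    @property
    def beta1_pre(self) -> float:
        return self.fit.coef("x_pre")

    @property
    def beta1_post(self) -> float:
        return self.fit.coef("x_post")

    def slope_vcov(self) -> np.ndarray:
        """2x2 covariance of (beta1_pre, beta1_post)."""
        idx = [self.fit.x_names.index("x_pre"), self.fit.x_names.index("x_post")]
        return np.asarray(self.fit.vcov_beta)[np.ix_(idx, idx)]


@dataclass
class RBEResult:
    rbe: float
    se: float
    ci: tuple
    per_subject: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: the per-subject spread omits in-vivo slope perturbations and is
    #: therefore likely an underestimate of the true between-subject range
    range_is_conservative: bool = True


def fit_rbe_model(
    cohort: CohortTable,
    dose_cap: float = DEFAULT_DOSE_CAP,
    quad_order: int = 7,
) -> RBEFit:
    """Fit the joint model on all pre-flight (dose-capped) and post rows."""
    df = cohort.df
    m = (df["phase"] == "post") | (
        (df["phase"] == "pre") & (df["dose_Gy"] <= dose_cap)
    )
    out = df.loc[m].copy()
    if not (out["phase"] == "post").any():
        raise ValueError("no post-flight rows: the in-vivo slope is inestimable")
    if not (out["phase"] == "pre").any():
        raise ValueError("no pre-flight rows: the ex-vivo slope is inestimable")
    out["x_pre"] = np.where(out["phase"] == "pre", out["dose_Gy"], 0.0)
    out["x_post"] = np.where(out["phase"] == "post", out["dose_Gy"], 0.0)
    out["a50"] = out["age_years"] - 50.0
    spec, counts = glmm.ModelSpec.from_frame(out, RBE_FIXED, RBE_RANDOM)
    fit = glmm.fit(spec, counts, quad_order=quad_order)
    eb = glmm.empirical_bayes(fit)
    return RBEFit(fit, eb)


def average_rbe(rfit: RBEFit, use_covariance: bool = True) -> RBEResult:
    """Average RBE = beta1_post / beta1_pre with a delta-method SE.

    The SE uses the full joint covariance of the two slopes by default; with
    ``use_covariance=False`` the cross term is dropped (independent-SE
    variant, for comparison).
    """
    bp, bq = rfit.beta1_post, rfit.beta1_pre
    if bq <= 0:
        raise ValueError("ex-vivo slope estimate <= 0: RBE undefined")
    ratio = bp / bq
    V = rfit.slope_vcov()  # order (pre, post)
    grad = np.array([-bp / bq**2, 1.0 / bq])
    if not use_covariance:
        V = np.diag(np.diag(V))
    var = float(grad @ V @ grad)
    se = float(np.sqrt(max(var, 0.0))) if np.all(np.isfinite(V)) else np.nan
    ci = (ratio - 1.96 * se, ratio + 1.96 * se)
    return RBEResult(float(ratio), se, ci, per_subject=subject_rbe(rfit))


def subject_rbe(rfit: RBEFit) -> pd.DataFrame:
    """Per-subject RBE_i = beta1_post / (beta1_pre + u1i_hat).

    Subjects whose EB-adjusted ex-vivo slope is nonpositive get RBE NaN and
    a flag instead of an error.
    """
    labels = list(rfit.eb.group_labels)
    u1 = rfit.eb.mean[:, rfit.eb.names.index("x_pre")]
    denom = rfit.beta1_pre + u1
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, rfit.beta1_post / denom, np.nan)
    return pd.DataFrame(
        {
            "subject_id": labels,
            "u1": u1,
            "rbe": vals,
            "nonpositive_slope": denom <= 0,
        }
    )
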