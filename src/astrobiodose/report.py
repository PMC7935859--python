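"""Exp-scale effect translations of fitted coefficients.

Turns log-scale Poisson coefficients into the multiplicative statements a
radiation biologist reads: baseline CAR for a reference subject, the factor
per 0.1 Gy of gamma dose (and its 1-SD subject band), the factor per year of
age, and the post-flight factor per 0.01 Gy of BFO dose with and without the
radiosensitivity modifier.  Each translation carries its formula and inputs
so the number can be recomputed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass
class EffectTranslation:
    description: str
    formula: str          # e.g. "exp(beta0 + sigma_w0)"
    params: dict
    value: float
    provenance: str = ""

    def recompute(self) -> float:
        """Re-evaluate the stored formula on the stored inputs."""
        return float(eval(self.formula, {"exp": math.exp, "__builtins__": {}},
                          dict(self.params)))


def _mk(desc, formula, params, provenance):
    val = float(eval(formula, {"exp": math.exp, "__builtins__": {}}, dict(params)))
    return EffectTranslation(desc, formula, params, val, provenance)


def _pre_params(fit_or_params) -> tuple[dict, str]:
    if isinstance(fit_or_params, dict):
        return dict(fit_or_params), "supplied coefficients"
    pf = fit_or_params
    f = pf.fit
    sig = {n: s for n, s in zip(f.spec.z_names, f.sigmas)}
    return (
        {
            "beta0": pf.beta0,
            "beta1": pf.beta1,
            "beta2": f.coef("a50", 0.0),
            "beta3": f.coef("female", 0.0),
            "sigma_w0": sig.get("const", 0.0),
            "sigma_w1": sig.get("dose_Gy", 0.0),
        },
        "pre-flight mixed Poisson fit",
    )


def translate_preflight(fit_or_params) -> list[EffectTranslation]:
    """Human-readable effects of the ex-vivo dose-response model.

    ``fit_or_params`` is a PreflightFit or a dict with keys beta0, beta1,
    beta2, beta3, sigma_w0, sigma_w1 (log-CAR scale, dose in Gy).
    """
    p, prov = _pre_params(fit_or_params)
    out = [
        _mk("baseline CAR, male age 50", "exp(beta0)", {"beta0": p["beta0"]}, prov),
        _mk(
            "baseline CAR, +1 SD subject",
            "exp(beta0 + sigma_w0)",
            {"beta0": p["beta0"], "sigma_w0": p["sigma_w0"]},
            prov,
        ),
        _mk(
            "baseline CAR, -1 SD subject",
            "exp(beta0 - sigma_w0)",
            {"beta0": p["beta0"], "sigma_w0": p["sigma_w0"]},
            prov,
        ),
        _mk(
            "CAR factor per 0.1 Gy gamma",
            "exp(beta1 / 10)",
            {"beta1": p["beta1"]},
            prov,
        ),
        _mk(
            "CAR factor per 0.1 Gy, +1 SD subject",
            "exp((beta1 + sigma_w1) / 10)",
            {"beta1": p["beta1"], "sigma_w1": p["sigma_w1"]},
            prov,
        ),
        _mk(
            "CAR factor per 0.1 Gy, -1 SD subject",
            "exp((beta1 - sigma_w1) / 10)",
            {"beta1": p["beta1"], "sigma_w1": p["sigma_w1"]},
            prov,
        ),
        _mk("baseline CAR factor per year of age", "exp(beta2)",
            {"beta2": p["beta2"]}, prov),
        _mk(
            "baseline CAR, female age 50",
            "exp(beta0 + beta3)",
            {"beta0": p["beta0"], "beta3": p["beta3"]},
            prov,
        ),
    ]
    return out


def _post_params(fit_or_params) -> tuple[dict, str]:
    if isinstance(fit_or_params, dict):
        return dict(fit_or_params), "supplied coefficients"
    pf = fit_or_params
    return (
        {"beta1": pf.coef("x"), "beta5": pf.coef("w1x")},
        "post-flight mixed Poisson fit",
    )


def translate_postflight(
    fit_or_params, w1: Optional[float] = None
) -> list[EffectTranslation]:
    """Post-flight factors per 0.01 Gy of BFO dose.

    With ``w1`` supplied, also the modified factor for a subject whose
    pre-flight radiosensitivity perturbation is w1.
    """
    p, prov = _post_params(fit_or_params)
    out = [
        _mk(
            "post-flight CAR factor per 0.01 Gy BFO",
            "exp(beta1 / 100)",
            {"beta1": p["beta1"]},
            prov,
        )
    ]
    if w1 is not None:
        out.append(
            _mk(
                f"post-flight CAR factor per 0.01 Gy BFO, w1={w1:g} subject",
                "exp((beta1 + beta5 * w1) / 100)",
                {"beta1": p["beta1"], "beta5": p["beta5"], "w1": float(w1)},
                prov,
            )
        )
    return out
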