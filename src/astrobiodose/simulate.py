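"""Synthetic crew cohorts with known generating truth.

Emulates the study design behind the astronaut biodosimetry tables: each
crew-mission contributes a pre-flight ex-vivo gamma dose series (baseline
plus a graded dose grid) and one or two post-flight samples at the mission's
BFO dose.  Counts follow the hierarchical Poisson model with bivariate-normal
subject effects on the baseline log-rate and the ex-vivo dose slope; a
handful of repeat fliers share their person-level effects across two
crew-missions.  The realized random effects and per-sample rates are kept in
a :class:`SimTruth` for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable, COLUMNS


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Fixed effects default to the published pre-flight estimates (log CAR
    scale): intercept ``beta0``, ex-vivo gamma slope ``beta1_pre`` (per Gy),
    age ``beta2`` (per year, centered at 50), gender ``beta3``; the in-vivo
    slope ``beta1_post`` (per Gy BFO dose) defaults to the joint-model
    estimate.  Random effect SDs/correlation are on the same log scale.
    """

    n_subjects: int = 43
    n_repeat_astronauts: int = 5
    female_count: int = 10
    age_range: tuple = (37.0, 57.0)

    beta0: float = -5.717
    beta1_pre: float = 4.151
    beta2: float = 0.029
    beta3: float = 0.168
    beta1_post: float = 12.475

    sigma_w0: float = 0.46
    sigma_w1: float = 0.88
    rho_w: float = 0.4

    dose_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4)
    cells_baseline: int = 8000
    cells_irradiated: int = 1500

    bfo_range: tuple = (0.01, 0.04)
    dose_rate_range_cGy_day: tuple = (0.012, 0.024)
    duration_range: tuple = (67.0, 215.0)
    cells_post: int = 8000
    frac_post_early: float = 39.0 / 43.0
    frac_post_late: float = 31.0 / 43.0

    #: in-vivo slope of subject i is beta1_post * exp(post_coupling * W1i);
    #: 0 decouples post-flight response from pre-flight radiosensitivity
    post_coupling: float = 0.5
    #: multiplier on the true rate of the late post-flight sample (1 = no
    #: recovery, matching the published comparison)
    late_rate_mult: float = 1.0

    mission2_intercept_mult: float = 1.5
    mission2_slope_mult: float = 1.23

    endpoint: str = "total_exchanges"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w0 < 0 or self.sigma_w1 < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not abs(self.rho_w) < 1:
            raise ValueError("|rho_w| must be < 1")
        if 0.0 not in self.dose_grid:
            raise ValueError("dose grid must include 0 (baseline)")
        if min(self.cells_baseline, self.cells_irradiated, self.cells_post) <= 0:
            raise ValueError("cell counts must be positive")
        if not 0 <= self.n_repeat_astronauts <= self.n_subjects // 2:
            raise ValueError("n_repeat_astronauts out of range")
        if not 0 <= self.female_count <= self.n_subjects - self.n_repeat_astronauts:
            raise ValueError("female_count exceeds the number of astronauts")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def scaled(cls, n_subjects: int, seed: int = 0, **overrides) -> "SimConfig":
        """A config for a different cohort size, keeping the default
        proportions of repeat fliers and female astronauts."""
        base = cls()
        frac_rep = base.n_repeat_astronauts / base.n_subjects
        frac_fem = base.female_count / (base.n_subjects - base.n_repeat_astronauts)
        n_rep = overrides.pop(
            "n_repeat_astronauts", int(round(frac_rep * n_subjects))
        )
        fem = overrides.pop(
            "female_count", int(round(frac_fem * (n_subjects - n_rep)))
        )
        return cls(
            n_subjects=n_subjects, n_repeat_astronauts=n_rep,
            female_count=fem, seed=seed, **overrides,
        )


@dataclass
class SimTruth:
    """Generating truth of one synthetic cohort, for recovery testing."""

    config: SimConfig
    subjects: pd.DataFrame  # per crew-mission: effects, covariates, BFO dose
    rates: np.ndarray       # realized per-sample rate, row-aligned with table

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "subjects": self.subjects.to_dict(orient="list"),
            "rates": np.asarray(self.rates).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_counts(rate: float, n_cells: int, rng: np.random.Generator):
    """Poisson aberration count for one sample: k ~ Poisson(n * rate)."""
    rate = np.asarray(rate, float)
    if np.any(rate < 0) or np.any(rate >= 1):
        raise ValueError("rate must lie in [0, 1) for the Poisson approximation")
    return rng.poisson(np.asarray(n_cells) * rate)


def simulate_cohort(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> tuple[CohortTable, SimTruth]:
    """Draw one synthetic cohort; deterministic given the seed.

    Raises if any realized rate reaches 1 (outside the Poisson-approximation
    regime); lower the fixed effects or random-effect SDs in that case.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    n = cfg.n_subjects
    n_ast = n - cfg.n_repeat_astronauts

    # person-level random effects, shared by a repeat flier's two missions
    cov = np.array(
        [
            [cfg.sigma_w0**2, cfg.rho_w * cfg.sigma_w0 * cfg.sigma_w1],
            [cfg.rho_w * cfg.sigma_w0 * cfg.sigma_w1, cfg.sigma_w1**2],
        ]
    )
    W = rng.multivariate_normal(np.zeros(2), cov, size=n_ast)

    female = np.zeros(n_ast, int)
    female[rng.choice(n_ast, size=cfg.female_count, replace=False)] = 1
    age1 = rng.uniform(*cfg.age_range, size=n_ast)

    # crew-missions: the first n_repeat astronauts fly twice
    rows = []
    for a in range(n_ast):
        rows.append((a, 1, age1[a]))
    for a in range(cfg.n_repeat_astronauts):
        gap = rng.uniform(3.0, 9.0)
        rows.append((a, 2, min(age1[a] + gap, cfg.age_range[1])))
    ast_idx = np.array([r[0] for r in rows])
    mission = np.array([r[1] for r in rows])
    age = np.array([r[2] for r in rows])

    # mission BFO dose, dose rate and duration, mutually consistent
    bfo = rng.uniform(*cfg.bfo_range, size=n)
    rate_cgy = rng.uniform(*cfg.dose_rate_range_cGy_day, size=n)
    duration = np.clip(100.0 * bfo / rate_cgy, *cfg.duration_range)

    # post-flight sampling pattern (early subset, late subset of early)
    n_early = int(round(cfg.frac_post_early * n))
    n_late = min(int(round(cfg.frac_post_late * n)), n_early)
    order = rng.permutation(n)
    has_early = np.zeros(n, bool)
    has_early[order[:n_early]] = True
    has_late = np.zeros(n, bool)
    has_late[order[:n_late]] = True

    w0 = W[ast_idx, 0]
    w1 = W[ast_idx, 1]
    m2 = (mission == 2).astype(float)
    d0 = np.log(cfg.mission2_intercept_mult) * m2
    d1 = cfg.beta1_pre * (cfg.mission2_slope_mult - 1.0) * m2

    a50 = age - 50.0
    fem = female[ast_idx]
    base_lp = cfg.beta0 + w0 + d0 + cfg.beta2 * a50 + cfg.beta3 * fem
    slope_pre = cfg.beta1_pre + w1 + d1
    slope_post = cfg.beta1_post * np.exp(cfg.post_coupling * w1)

    recs, lam_list = [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        aid = f"A{ast_idx[i] + 1:03d}"
        common = dict(
            subject_id=sid,
            astronaut_id=aid,
            mission_number=int(mission[i]),
            age_years=round(float(age[i]), 1),
            female=int(fem[i]),
            mission_duration_days=round(float(duration[i]), 1),
            endpoint=cfg.endpoint,
        )
        for x in cfg.dose_grid:
            lam = float(np.exp(base_lp[i] + slope_pre[i] * x))
            cells = cfg.cells_baseline if x == 0 else cfg.cells_irradiated
            recs.append(
                dict(
                    common,
                    phase="pre",
                    timepoint="baseline" if x == 0 else "irradiated",
                    dose_Gy=float(x),
                    cells_scored=cells,
                    aberrations=0,
                )
            )
            lam_list.append(lam)
        lam_post = float(np.exp(base_lp[i] + slope_post[i] * bfo[i]))
        for tp, present, mult in (
            ("post_early", has_early[i], 1.0),
            ("post_late", has_late[i], cfg.late_rate_mult),
        ):
            if not present:
                continue
            recs.append(
                dict(
                    common,
                    phase="post",
                    timepoint=tp,
                    dose_Gy=float(round(bfo[i], 5)),
                    cells_scored=cfg.cells_post,
                    aberrations=0,
                )
            )
            lam_list.append(lam_post * mult)

    rates = np.array(lam_list)
    if np.any(rates >= 1.0):
        raise ValueError(
            "a realized rate reached 1; the Poisson-approximation regime is "
            "violated — reduce the fixed effects or random-effect SDs"
        )
    df = pd.DataFrame(recs)
    df["aberrations"] = simulate_counts(rates, df["cells_scored"].to_numpy(), rng)
    table = CohortTable(
        df[COLUMNS].copy(),
        endpoint=cfg.endpoint,
        provenance=f"simulated (seed={cfg.seed if seed is None else seed})",
    )

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "astronaut_id": [f"A{ast_idx[i] + 1:03d}" for i in range(n)],
            "mission_number": mission,
            "age_years": age,
            "female": fem,
            "W0": w0,
            "W1": w1,
            "bfo_Gy": bfo,
            "duration_days": duration,
            "has_early": has_early,
            "has_late": has_late,
        }
    )
    return table, SimTruth(config=cfg, subjects=subjects, rates=rates)
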