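"""End-to-end analysis pipeline: simulate (or load) a cohort, fit the
stage-1/stage-2 and joint RBE models, and write all numeric artifacts.

Artifacts are JSON/CSV with full precision; each JSON carries the config
hash so outputs of different runs cannot be silently mixed.  Figures are
optional and headless-safe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import postflight, preflight, rbe, report
from .cohort import CohortTable, DEFAULT_DOSE_CAP, read_cohort, write_cohort
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "astrobiodose_run"
    cohort_path: Optional[str] = None  # if unset, simulate
    endpoint: str = "total_exchanges"
    dose_cap: float = DEFAULT_DOSE_CAP
    quad_order: int = 7
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    make_figures: bool = False

    # -- (de)serialization, bit-stable round trip --------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in {".yml", ".yaml"}
            else json.loads(text)
        )
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)
        if self.quad_order < 1:
            raise ValueError("quad_order must be >= 1")
        if self.dose_cap <= 0:
            raise ValueError("dose_cap must be positive")


def _dump(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = dict(obj)
    obj["config_hash"] = cfg_hash
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> Path:
    """simulate/load -> stage 1 (no baseline) -> stage 2 -> RBE -> reports.

    Returns the artifact directory.  Re-running with the same config and
    seed reproduces the numeric outputs byte-identically.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("astrobiodose")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out, h)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path, h: str) -> Path:
    import astrobiodose

    logger.info("astrobiodose %s, config hash %s, seed %d",
                astrobiodose.__version__, h, config.seed)
    config.to_json(out / "config.json")

    stage = "simulate/load"
    try:
        if config.cohort_path:
            cohort = read_cohort(
                config.cohort_path, endpoint=config.endpoint,
                dose_cap=config.dose_cap,
            )
            truth = None
        else:
            sim = SimConfig(
                **{"seed": config.seed, "endpoint": config.endpoint, **config.sim}
            )
            cohort, truth = simulate_cohort(sim)
            write_cohort(cohort, out / "cohort.csv")
            truth.to_json(out / "truth.json")

        stage = "fit-preflight"
        pre_full = preflight.fit_preflight(
            cohort, include_baseline=True, dose_cap=config.dose_cap,
            quad_order=config.quad_order,
        )
        pre_nb = preflight.fit_preflight(
            cohort, include_baseline=False, dose_cap=config.dose_cap,
            quad_order=config.quad_order,
        )
        _dump(pre_full.fit.to_dict(), out / "preflight_full.json", h)
        _dump(pre_nb.fit.to_dict(), out / "preflight_nobaseline.json", h)
        eff = pre_nb.subject_effects()
        slopes = preflight.average_slopes(pre_full)
        eff.merge(slopes, on="subject_id").to_csv(
            out / "subject_effects.csv", index=False
        )

        stage = "fit-postflight"
        design = postflight.assemble_postflight_design(cohort, pre_nb)
        post = postflight.fit_postflight(design, quad_order=config.quad_order)
        _dump(post.fit.to_dict(), out / "postflight.json", h)
        try:
            rec = postflight.recovery_test(cohort)
            _dump(dataclasses.asdict(rec), out / "recovery.json", h)
        except ValueError as e:
            logger.info("recovery test skipped: %s", e)
            rec = None

        stage = "fit-rbe"
        rfit = rbe.fit_rbe_model(
            cohort, dose_cap=config.dose_cap, quad_order=config.quad_order
        )
        res = rbe.average_rbe(rfit)
        _dump(
            {
                "fit": rfit.fit.to_dict(),
                "rbe": res.rbe,
                "se": res.se,
                "ci": list(res.ci),
                "range_is_conservative": res.range_is_conservative,
            },
            out / "rbe.json",
            h,
        )
        res.per_subject.to_csv(out / "rbe_per_subject.csv", index=False)

        stage = "report"
        trans = report.translate_preflight(pre_full) + report.translate_postflight(
            post, w1=1.5
        )
        _dump(
            {
                "translations": [
                    {
                        "description": t.description,
                        "formula": t.formula,
                        "params": t.params,
                        "value": t.value,
                        "provenance": t.provenance,
                    }
                    for t in trans
                ]
            },
            out / "translations.json",
            h,
        )
        summary = {
            "seed": config.seed,
            "n_subjects": cohort.n_subjects,
            "preflight_beta1": pre_full.beta1,
            "postflight_beta5": post.coef("w1x"),
            "average_rbe": res.rbe,
            "recovery_p": rec.p if rec else None,
        }
        _dump(summary, out / "summary.json", h)

        if config.make_figures:
            stage = "figures"
            _figures(out, cohort, pre_full, post, res)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    return out


def _figures(out: Path, cohort: CohortTable, pre_full, post, rbe_res) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # per-subject fitted dose-response curves over observed CARs
    fig, ax = plt.subplots(figsize=(6, 4))
    eff = pre_full.subject_effects()
    x = np.linspace(0, eff["max_dose_Gy"].max(), 50)
    for _, r in eff.head(6).iterrows():
        eta = (
            pre_full.beta0
            + r["w0"]
            + (pre_full.beta1 + r["w1"]) * x
            + pre_full.fit.coef("a50", 0.0) * (r["age_years"] - 50.0)
            + pre_full.fit.coef("female", 0.0) * r["female"]
        )
        ax.plot(x, np.exp(eta), lw=1)
    pre = cohort.pre_rows()
    ax.plot(pre["dose_Gy"], pre["aberrations"] / pre["cells_scored"], "r.", ms=3)
    ax.set_xlabel("gamma dose (Gy)")
    ax.set_ylabel("CAR")
    fig.savefig(out / "fig_dose_response.png", dpi=100)
    plt.close(fig)

    # observed vs predicted post-flight CAR
    d = post.design.df
    eta = post.design.spec.X @ post.fit.beta
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    obs = d["aberrations"] / d["cells_scored"]
    ax.plot(np.exp(eta), obs, "o", ms=4)
    lim = max(obs.max(), np.exp(eta).max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("predicted CAR")
    ax.set_ylabel("observed CAR")
    fig.savefig(out / "fig_obs_vs_pred.png", dpi=100)
    plt.close(fig)

    # per-subject RBE
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ps = rbe_res.per_subject.dropna(subset=["rbe"]).reset_index()
    ax.plot(ps.index, ps["rbe"], "o", ms=4)
    ax.axhline(rbe_res.rbe, color="k")
    for b in rbe_res.ci:
        ax.axhline(b, color="k", ls="--", lw=0.8)
    ax.set_xlabel("subject")
    ax.set_ylabel("RBE")
    fig.savefig(out / "fig_rbe.png", dpi=100)
    plt.close(fig)
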