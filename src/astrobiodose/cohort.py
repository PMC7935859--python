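"""Cohort data model for crew-mission chromosome-aberration samples.

One row per scored blood sample: a pre-flight sample irradiated ex vivo with
a graded gamma dose (or the unirradiated baseline), or a post-flight sample
carrying the mission's blood-forming-organ (BFO) dose.  Counts are aberrations
(total exchanges or stable translocations) in ``cells_scored`` lymphocytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASES = ("pre", "post")
TIMEPOINTS = ("baseline", "irradiated", "post_early", "post_late")
ENDPOINTS = ("total_exchanges", "stable_translocations")

#: canonical column order of the on-disk table
COLUMNS = [
    "subject_id",
    "astronaut_id",
    "mission_number",
    "phase",
    "timepoint",
    "dose_Gy",
    "cells_scored",
    "aberrations",
    "age_years",
    "female",
    "mission_duration_days",
    "endpoint",
]

#: default cap on ex-vivo gamma doses retained for the low-dose analysis (Gy)
DEFAULT_DOSE_CAP = 0.5


class SchemaError(ValueError):
    """The table header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a cohort invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """A single scored blood sample."""

    subject_id: str
    astronaut_id: str
    mission_number: int
    phase: str
    timepoint: str
    dose_Gy: float
    cells_scored: int
    aberrations: int
    age_years: float
    female: int
    mission_duration_days: float = float("nan")
    endpoint: str = "total_exchanges"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.cells_scored <= 0:
            raise ValidationError("cells_scored must be positive")
        if self.aberrations < 0 or self.aberrations > self.cells_scored:
            raise ValidationError(
                f"aberrations ({self.aberrations}) must lie in "
                f"[0, cells_scored={self.cells_scored}]"
            )
        if self.dose_Gy < 0:
            raise ValidationError("dose_Gy must be nonnegative")


def observed_car(record) -> float:
    """Observed chromosome aberration rate: aberrations per scored cell.

    Accepts a :class:`SampleRecord` or any object/row with ``aberrations``
    and ``cells_scored`` attributes/keys.
    """
    try:
        k, n = record.aberrations, record.cells_scored
    except AttributeError:
        k, n = record["aberrations"], record["cells_scored"]
    if n <= 0:
        raise ValidationError("cells_scored must be positive to form a rate")
    return float(k) / float(n)


@dataclass
class CohortTable:
    """Validated long-format cohort table.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rows whose
    pre-flight gamma dose exceeds ``dose_cap`` are *flagged* (boolean column
    ``high_dose``) rather than dropped, mirroring how high-dose calibration
    points are retained on disk but excluded from the low-dose analysis.
    """

    df: pd.DataFrame
    endpoint: str = "total_exchanges"
    provenance: str = ""
    dose_cap: float = DEFAULT_DOSE_CAP

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()
        self.df["high_dose"] = (self.df["phase"] == "pre") & (
            self.df["dose_Gy"] > self.dose_cap
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: list[SampleRecord], **kw) -> "CohortTable":
        df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
        return cls(df, **kw)

    def records(self) -> Iterator[SampleRecord]:
        names = {f.name for f in fields(SampleRecord)}
        for row in self.df.itertuples(index=False):
            d = {k: v for k, v in row._asdict().items() if k in names}
            yield SampleRecord(**d)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")

        bad_phase = ~df["phase"].isin(PHASES)
        if bad_phase.any():
            i = int(df.index[bad_phase][0])
            raise ValidationError(f"row {i}: unknown phase {df.loc[i, 'phase']!r}")
        bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            i = int(df.index[bad_tp][0])
            raise ValidationError(
                f"row {i}: unknown timepoint {df.loc[i, 'timepoint']!r}"
            )

        bad_k = df["aberrations"] > df["cells_scored"]
        if bad_k.any():
            i = int(df.index[bad_k][0])
            raise ValidationError(
                f"row {i}: aberrations ({df.loc[i, 'aberrations']}) exceed "
                f"cells scored ({df.loc[i, 'cells_scored']})"
            )
        if (df["cells_scored"] <= 0).any():
            i = int(df.index[df["cells_scored"] <= 0][0])
            raise ValidationError(f"row {i}: cells_scored must be positive")
        if (df["dose_Gy"] < 0).any():
            i = int(df.index[df["dose_Gy"] < 0][0])
            raise ValidationError(f"row {i}: negative dose")

        pre = df["phase"] == "pre"
        ok_pre_tp = df.loc[pre, "timepoint"].isin(["baseline", "irradiated"])
        if not ok_pre_tp.all():
            i = int(ok_pre_tp.index[~ok_pre_tp][0])
            raise ValidationError(f"row {i}: pre-flight row with post timepoint")
        base = pre & (df["timepoint"] == "baseline")
        if (df.loc[base, "dose_Gy"] != 0).any():
            raise ValidationError("baseline rows must have dose_Gy = 0")
        irr = pre & (df["timepoint"] == "irradiated")
        if (df.loc[irr, "dose_Gy"] == 0).any():
            raise ValidationError("irradiated pre-flight rows must have dose_Gy > 0")

        post = df["phase"] == "post"
        ok_post_tp = df.loc[post, "timepoint"].isin(["post_early", "post_late"])
        if not ok_post_tp.all():
            i = int(ok_post_tp.index[~ok_post_tp][0])
            raise ValidationError(f"row {i}: post-flight row with pre timepoint")
        # one BFO dose per subject across its post rows
        ndose = df.loc[post].groupby("subject_id")["dose_Gy"].nunique()
        if (ndose > 1).any():
            sid = ndose.index[ndose > 1][0]
            raise ValidationError(
                f"subject {sid}: post-flight rows carry more than one BFO dose"
            )
        # subject-level covariates constant within subject
        for col in ("age_years", "female", "mission_number", "astronaut_id"):
            nun = df.groupby("subject_id")[col].nunique(dropna=False)
            if (nun > 1).any():
                sid = nun.index[nun > 1][0]
                raise ValidationError(f"subject {sid}: {col} varies across rows")

    # -- views -------------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return int(self.df["subject_id"].nunique())

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            self.df.loc[mask, COLUMNS].copy(),
            endpoint=self.endpoint,
            provenance=self.provenance,
            dose_cap=self.dose_cap,
        )

    def pre_rows(self, include_baseline: bool = True, apply_cap: bool = True):
        df = self.df
        m = df["phase"] == "pre"
        if apply_cap:
            m &= ~df["high_dose"]
        if not include_baseline:
            m &= df["timepoint"] != "baseline"
        return df.loc[m]

    def post_rows(self):
        return self.df.loc[self.df["phase"] == "post"]


# -- I/O -------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort(
    path, endpoint: str = "total_exchanges", dose_cap: float = DEFAULT_DOSE_CAP
) -> CohortTable:
    """Read a cohort CSV/TSV (delimiter from the extension) and validate it.

    Rows above ``dose_cap`` are flagged, not dropped; rows whose ``endpoint``
    differs from the requested one are excluded from the returned table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {c.lower(): c for c in COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s): {', '.join(missing)}"
        )
    df = df[df["endpoint"] == endpoint]
    df["subject_id"] = df["subject_id"].astype(str)
    df["astronaut_id"] = df["astronaut_id"].astype(str)
    table = CohortTable(
        df[COLUMNS].copy(), endpoint=endpoint,
        provenance=f"read from {path}", dose_cap=dose_cap,
    )
    n_hi = int(table.df["high_dose"].sum())
    if n_hi:
        logger.info("%s: flagged %d row(s) above dose cap %.3g Gy",
                    path.name, n_hi, dose_cap)
    return table


def write_cohort(cohort: CohortTable, path) -> Path:
    """Write the canonical columns to CSV/TSV (delimiter from the extension)."""
    path = Path(path)
    cohort.df[COLUMNS].to_csv(path, sep=_sep_for(path), index=False)
    return path


def filter_low_dose(cohort: CohortTable, cap: float = DEFAULT_DOSE_CAP) -> CohortTable:
    """Drop pre-flight rows with gamma dose above ``cap`` (post rows kept).

    Idempotent; the number of removed rows is logged.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    df = cohort.df
    keep = (df["phase"] == "post") | (df["dose_Gy"] <= cap)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_dose: removed %d row(s) above %.3g Gy",
                    n_removed, cap)
    return cohort.subset(keep)
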