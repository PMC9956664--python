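"""Cohort ingest and derivation of analysis quantities.

Raw cohort tables carry, per eye: axial length AL (mm), central corneal
thickness CCT (µm), external anterior chamber depth ACD (mm, corneal
front apex to lens front apex), lens thickness LT (mm), flat and steep
corneal front radii R1/R2 (mm), the implanted IOL power PIOL (dpt) and
the postoperative refraction (sphere/cylinder, dpt).  From these we
derive

* ``SEQ``   — spherical equivalent refraction, sphere + cylinder/2;
* ``Rmean`` — arithmetic mean corneal radius, (R1 + R2)/2;
* ``Rpow``  — the radius reconverted from the mean corneal power,
  2·R1·R2/(R1 + R2): for any keratometer index its thin-lens power is
  the mean of the two meridional powers (harmonic-mean radius).

The SEQ reduction makes the analysis invariant to the cylinder sign
dialect: transposing a plus-cylinder refraction to minus-cylinder form
leaves sphere + cylinder/2 unchanged, so both dialects are accepted
as-is and never converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError

logger = logging.getLogger(__name__)

#: Canonical cohort column names.
CANONICAL_COLUMNS = (
    "AL",
    "CCT",
    "ACD",
    "LT",
    "R1",
    "R2",
    "PIOL",
    "sphere",
    "cylinder",
    "VA",
)

_REQUIRED = ("AL", "CCT", "ACD", "LT", "R1", "R2", "PIOL", "sphere", "cylinder")


@dataclass(frozen=True)
class BiometryRecord:
    """One eye's measured inputs and observed refractive outcome.

    Units: AL, ACD, LT, R1, R2 in mm; CCT in µm; PIOL, sphere, cylinder
    in dpt; VA as decimal visual acuity.  Plausibility bounds reject
    transcription errors (e.g. radii entered as dioptres).
    """

    AL: float
    CCT: float
    ACD: float
    LT: float
    R1: float
    R2: float
    PIOL: float
    sphere: float
    cylinder: float
    VA: float | None = None
    eye: str | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if not 15.0 < self.AL < 40.0:
            raise ValueError(f"AL {self.AL} mm outside (15, 40)")
        if not 350.0 < self.CCT < 750.0:
            raise ValueError(f"CCT {self.CCT} µm outside (350, 750)")
        for name in ("R1", "R2"):
            r = getattr(self, name)
            if not 5.5 < r < 10.5:
                raise ValueError(f"{name} {r} mm outside (5.5, 10.5)")
        if not np.isfinite(self.PIOL):
            raise ValueError("PIOL must be finite")


def compute_seq(sphere, cylinder):
    """Spherical equivalent refraction: sphere + cylinder/2, dpt."""
    sphere = np.asarray(sphere, dtype=float)
    cylinder = np.asarray(cylinder, dtype=float)
    if not (np.all(np.isfinite(sphere)) and np.all(np.isfinite(cylinder))):
        raise CohortError("sphere and cylinder must be finite")
    out = sphere + 0.5 * cylinder
    return float(out) if out.ndim == 0 else out


def mean_radius(r1_mm, r2_mm):
    """Arithmetic mean of the two meridional corneal radii, mm."""
    r1 = np.asarray(r1_mm, dtype=float)
    r2 = np.asarray(r2_mm, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("corneal radii must be positive")
    out = 0.5 * (r1 + r2)
    return float(out) if out.ndim == 0 else out


def power_mean_radius(r1_mm, r2_mm):
    """Radius reconverted from the mean corneal power, mm.

    Returns the harmonic mean 2·R1·R2/(R1 + R2), the radius whose
    thin-lens power (nK − 1)/R equals the mean of the two meridional
    powers for any keratometer index nK.  It never exceeds the
    arithmetic mean radius, with equality only for R1 = R2.
    """
    r1 = np.asarray(r1_mm, dtype=float)
    r2 = np.asarray(r2_mm, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("corneal radii must be positive")
    out = 2.0 * r1 * r2 / (r1 + r2)
    return float(out) if out.ndim == 0 else out


def filter_va(
    cohort: pd.DataFrame, threshold: float = 0.8, keep_missing: bool = False
) -> pd.DataFrame:
    """Keep eyes with decimal visual acuity at or above ``threshold``.

    Postoperative refraction is only trusted when the eye resolves well
    (default 0.8 decimal, 20/25); the comparison is inclusive.  Records
    without a VA entry are dropped unless ``keep_missing`` is set.
    """
    if not 0 < threshold <= 2:
        raise ValueError("threshold must be in (0, 2]")
    if "VA" not in cohort.columns:
        if keep_missing:
            return cohort.copy()
        raise CohortError("cohort has no VA column; pass keep_missing=True to retain")
    va = pd.to_numeric(cohort["VA"], errors="coerce")
    keep = va >= threshold
    if keep_missing:
        keep |= va.isna()
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_va: removed %d of %d eyes below VA %.2f",
                    removed, len(cohort), threshold)
    return cohort.loc[keep].copy()


def derive(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the derived columns SEQ, Rmean and Rpow to a cohort table.

    Rows with non-finite sphere/cylinder are dropped with a log entry
    rather than failing the whole cohort.
    """
    missing = [c for c in _REQUIRED if c not in cohort.columns]
    if missing:
        raise CohortError(f"cohort is missing required columns: {missing}")
    out = cohort.copy()
    finite = (
        np.isfinite(pd.to_numeric(out["sphere"], errors="coerce"))
        & np.isfinite(pd.to_numeric(out["cylinder"], errors="coerce"))
    )
    if not finite.all():
        logger.warning("derive: dropped %d eyes with non-finite refraction",
                       int((~finite).sum()))
        out = out.loc[finite].copy()
    out["SEQ"] = compute_seq(out["sphere"].to_numpy(), out["cylinder"].to_numpy())
    out["Rmean"] = mean_radius(out["R1"].to_numpy(), out["R2"].to_numpy())
    out["Rpow"] = power_mean_radius(out["R1"].to_numpy(), out["R2"].to_numpy())
    return out


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a cohort table from .csv or .xlsx.

    ``column_map`` maps file column names to the canonical names in
    :data:`CANONICAL_COLUMNS`; columns already canonically named need no
    entry.  Unknown columns are preserved untouched as metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        table = pd.read_excel(path, sheet_name=sheet)
    else:
        table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise CohortError(
            f"{path.name}: missing required columns {missing}; "
            "declare a column_map for non-canonical headers"
        )
    for col in _REQUIRED:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def records_to_frame(records: Sequence[BiometryRecord]) -> pd.DataFrame:
    """Assemble typed per-eye records into a cohort table."""
    return pd.DataFrame([vars(r) for r in records])
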