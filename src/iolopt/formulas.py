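"""Four IOL power formulas solved for the predicted refraction.

Each formula is split into two parts:

* an **ELP prediction part** — the empirical regression/expression that
  predicts the effective lens position from preoperative biometry.
  This part always uses the formula's published keratometer index and
  is never touched when the refractive index is varied; and
* a **main (vergence) part** — the paraxial vergence transformation
  from retina to spectacle plane through the IOL and the cornea, where
  the keratometer index nK (thin-lens cornea: Hoffer Q, Holladay 1,
  Haigis) or the stromal index nC (thick-lens cornea: Castrop) enters
  and may be varied.

All formulas are solved for the spherical-equivalent refraction SEQ at
the spectacle plane as a function of biometry, constants and the
implanted IOL power, so the prediction error PE = SEQ_achieved −
SEQ_predicted is directly computable per eye.

Published ELP parts
-------------------
Hoffer Q     ELP = pACD + 0.3·(AL − 23.5) + tan²(K) − 0.99166
                   + 0.1·M·(23.5 − AL)²·tan(0.1·(G − AL)²),
             angles in degrees, AL clamped to [18.5, 31] mm,
             M = +1, G = 28 for AL ≤ 23 and M = −1, G = 23.5 above;
             K is the mean corneal power at the Javal index 1.3375.
             The vergence part places the image plane 0.05 mm behind
             the nominal ELP (Hoffer's retinal offset), treated here as
             main-part geometry.
Holladay 1   anatomical ACD from the corneal-height formula
             0.56 + Rag − sqrt(Rag² − AG²/4) with the radius floored at
             Rag = max(R, 7) mm and the corneal width regression
             AG = min(12.5·AL/23.45, 13.5) mm, plus the surgeon factor
             SF; the vergence part uses the modified axial length
             AL + 0.2 mm (retinal thickness).
Haigis       ELP = a0 + a1·ACD + a2·AL (no truncations).
Castrop      ELP = ACD + C·LT + H; the vergence part runs through a
             thick-lens cornea (back radius 0.834·Rmean) over the
             Cooke sum-of-segments modified axial length, and the
             constant R is an additive offset on the predicted SEQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .cornea import AQUEOUS_INDEX, keratometric_power
from .errors import DegenerateVergenceError

_DEGENERATE_TOL = 1e-12

#: Spectacle vertex distance, mm (convention of the Haigis literature).
DEFAULT_VERTEX_MM = 12.0

#: Hoffer Q retinal offset added to the ELP inside the vergence part, mm.
_HOFFERQ_RETINA_MM = 0.05

#: Holladay 1 retinal-thickness addend to the axial length, mm.
_HOLLADAY_RT_MM = 0.2

#: Cooke sum-of-segments modified axial length coefficients (mm).
_CMAL_INTERCEPT = 1.23853
_CMAL_AL = 0.95855
_CMAL_LT = -0.05467

#: Castrop back/front corneal radius ratio for normal corneas.
CASTROP_BACK_RADIUS_RATIO = 0.834

FORMULAS = ("hofferq", "holladay1", "haigis", "castrop")

_PUBLISHED_INDEX = {
    "hofferq": 1.3375,  # Javal
    "holladay1": 4.0 / 3.0,
    "haigis": 1.3315,
    "castrop": 1.376,  # stromal index of the thick-lens cornea
}


def published_index(formula: str) -> float:
    """The keratometer/corneal refractive index published for a formula."""
    try:
        return _PUBLISHED_INDEX[formula]
    except KeyError:
        raise ValueError(f"unknown formula {formula!r}; expected one of {FORMULAS}")


# --------------------------------------------------------------------------
# constants


@dataclass(frozen=True)
class HofferQConstants:
    """Personalised anterior chamber depth constant, mm."""

    pacd: float


@dataclass(frozen=True)
class Holladay1Constants:
    """Surgeon factor, mm."""

    sf: float


@dataclass(frozen=True)
class HaigisConstants:
    """ELP regression triplet: ELP = a0 + a1·ACD + a2·AL (mm)."""

    a0: float
    a1: float
    a2: float


@dataclass(frozen=True)
class CastropConstants:
    """ELP regression C/H (ELP = ACD + C·LT + H) and refraction offset R."""

    c: float
    h: float
    r_offset: float


FormulaConstants = Union[
    HofferQConstants, Holladay1Constants, HaigisConstants, CastropConstants
]


def nominal_constants(formula: str) -> FormulaConstants:
    """Typical starting constants for an average monofocal IOL."""
    return {
        "hofferq": HofferQConstants(pacd=5.64),
        "holladay1": Holladay1Constants(sf=1.84),
        "haigis": HaigisConstants(a0=0.4, a1=0.1, a2=0.1),
        "castrop": CastropConstants(c=0.325, h=0.0, r_offset=0.0),
    }[formula]


@dataclass(frozen=True)
class FormulaSpec:
    """Which formula to evaluate and with which indices/geometry.

    ``n_main`` is the index used in the vergence (main) part; ``None``
    means the published default.  The ELP part always uses the
    published index regardless of ``n_main``.
    """

    formula: str
    n_main: float | None = None
    n_aqueous: float = AQUEOUS_INDEX
    vertex_mm: float = DEFAULT_VERTEX_MM
    back_radius_ratio: float = CASTROP_BACK_RADIUS_RATIO

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise ValueError(f"unknown formula {self.formula!r}")
        if self.vertex_mm <= 0:
            raise ValueError("vertex distance must be positive")

    @property
    def n_elp(self) -> float:
        """Keratometer index of the (frozen) ELP part."""
        return published_index(self.formula)

    @property
    def main_index(self) -> float:
        return published_index(self.formula) if self.n_main is None else self.n_main


@dataclass(frozen=True)
class Prediction:
    """Per-eye formula output: ELP, corneal power, predicted SEQ, PE."""

    elp_mm: float
    d_cornea: float
    seq_pred: float
    pe: float | None = None


# --------------------------------------------------------------------------
# vergence chains


def _finalise(seq, degenerate, on_degenerate):
    seq = np.where(degenerate, np.nan, seq)
    if on_degenerate == "raise" and np.any(degenerate):
        raise DegenerateVergenceError("vergence chain hit a degenerate denominator")
    return float(seq) if seq.ndim == 0 else seq


def seq_thin_chain(
    al_mm,
    elp_mm,
    d_cornea,
    p_iol,
    n_aqueous: float = AQUEOUS_INDEX,
    vertex_mm: float = DEFAULT_VERTEX_MM,
    on_degenerate: str = "raise",
):
    """Predicted SEQ of a thin-cornea pseudophakic eye, dpt.

    Backward vergence transformation retina → thin IOL → thin cornea →
    spectacle plane, with the aqueous/vitreous index ``n_aqueous`` on
    both sides of the IOL.  With lengths in metres:

        z  = n/(AL − ELP)            vergence leaving the IOL
        V  = z − PIOL                vergence entering the IOL
        Vc = n/(ELP + n/V) − Dc      vergence in air before the cornea
        SEQ = Vc/(1 + VD·Vc)         at the spectacle plane

    ``on_degenerate`` is ``"raise"`` (typed error) or ``"nan"``
    (degenerate eyes yield NaN; used by the optimiser to apply an
    explicit penalty).
    """
    al = np.asarray(al_mm, dtype=float) * 1e-3
    elp = np.asarray(elp_mm, dtype=float) * 1e-3
    dc = np.asarray(d_cornea, dtype=float)
    piol = np.asarray(p_iol, dtype=float)
    vd = vertex_mm * 1e-3

    with np.errstate(all="ignore"):
        d1 = al - elp
        z = n_aqueous / d1
        v = z - piol
        # n/V -> inf for V = 0 (image at infinity); the chain's limit is
        # finite and correct, so only true zero denominators are flagged.
        d2 = elp + n_aqueous / v
        vc = n_aqueous / d2 - dc
        d3 = 1.0 + vd * vc
        seq = vc / d3
    degenerate = (
        (np.abs(d1) < _DEGENERATE_TOL)
        | (np.abs(d2) < _DEGENERATE_TOL)
        | (np.abs(d3) < _DEGENERATE_TOL)
        | ~np.isfinite(seq)
    )
    return _finalise(seq, degenerate, on_degenerate)


def seq_thick_chain(
    al_eff_mm,
    elp_mm,
    p_front,
    p_back,
    cct_um,
    n_cornea,
    p_iol,
    n_aqueous: float = AQUEOUS_INDEX,
    vertex_mm: float = DEFAULT_VERTEX_MM,
    on_degenerate: str = "raise",
):
    """Predicted SEQ with a two-surface (thick-lens) cornea, dpt.

    Backward chain retina → IOL → (ELP − CCT in aqueous) → corneal back
    surface → (CCT in stroma) → corneal front surface → (vertex distance
    in air).  ``p_front``/``p_back`` are the corneal surface powers in
    dpt; ELP is measured from the corneal front apex, so it must exceed
    the corneal thickness.
    """
    al = np.asarray(al_eff_mm, dtype=float) * 1e-3
    elp = np.asarray(elp_mm, dtype=float) * 1e-3
    cct = np.asarray(cct_um, dtype=float) * 1e-6
    p1 = np.asarray(p_front, dtype=float)
    p2 = np.asarray(p_back, dtype=float)
    piol = np.asarray(p_iol, dtype=float)
    vd = vertex_mm * 1e-3

    with np.errstate(all="ignore"):
        d1 = al - elp
        v5 = n_aqueous / d1 - piol
        d2 = 1.0 + ((elp - cct) / n_aqueous) * v5
        v4 = v5 / d2
        v3 = v4 - p2
        d3 = 1.0 + (cct / n_cornea) * v3
        v2 = v3 / d3
        v1 = v2 - p1
        d4 = 1.0 + vd * v1
        seq = v1 / d4
    degenerate = (
        (np.abs(d1) < _DEGENERATE_TOL)
        | (np.abs(d2) < _DEGENERATE_TOL)
        | (np.abs(d3) < _DEGENERATE_TOL)
        | (np.abs(d4) < _DEGENERATE_TOL)
        | ~np.isfinite(seq)
    )
    return _finalise(seq, degenerate, on_degenerate)


# --------------------------------------------------------------------------
# ELP parts (frozen published indices; never see a varied n_main)


def elp_hofferq(al_mm, k_dpt, pacd):
    """Hoffer Q effective lens position, mm (tangents in degrees)."""
    al = np.asarray(al_mm, dtype=float)
    k = np.asarray(k_dpt, dtype=float)
    al_c = np.clip(al, 18.5, 31.0)
    m = np.where(al_c <= 23.0, 1.0, -1.0)
    g = np.where(al_c <= 23.0, 28.0, 23.5)
    tan_deg = lambda x: np.tan(np.radians(x))
    elp = (
        pacd
        + 0.3 * (al_c - 23.5)
        + tan_deg(k) ** 2
        + 0.1 * m * (23.5 - al_c) ** 2 * tan_deg(0.1 * (g - al_c) ** 2)
        - 0.99166
    )
    return float(elp) if elp.ndim == 0 else elp


def elp_holladay1(al_mm, r_mm, sf):
    """Holladay 1 ELP: corneal-height anatomical ACD plus surgeon factor, mm."""
    al = np.asarray(al_mm, dtype=float)
    rag = np.maximum(np.asarray(r_mm, dtype=float), 7.0)
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    acd = 0.56 + rag - np.sqrt(rag**2 - ag**2 / 4.0)
    elp = acd + sf
    return float(elp) if elp.ndim == 0 else elp


def elp_haigis(acd_mm, al_mm, constants: HaigisConstants):
    """Haigis ELP regression a0 + a1·ACD + a2·AL, mm."""
    elp = (
        constants.a0
        + constants.a1 * np.asarray(acd_mm, dtype=float)
        + constants.a2 * np.asarray(al_mm, dtype=float)
    )
    return float(elp) if np.ndim(elp) == 0 else elp


def elp_castrop(acd_mm, lt_mm, c, h):
    """Castrop ELP regression ACD + C·LT + H, mm."""
    elp = np.asarray(acd_mm, dtype=float) + c * np.asarray(lt_mm, dtype=float) + h
    return float(elp) if np.ndim(elp) == 0 else elp


def cmal(al_mm, lt_mm):
    """Cooke sum-of-segments modified axial length, mm."""
    out = (
        _CMAL_INTERCEPT
        + _CMAL_AL * np.asarray(al_mm, dtype=float)
        + _CMAL_LT * np.asarray(lt_mm, dtype=float)
    )
    return float(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------------------
# full predictions


def prediction_error(seq_achieved, seq_pred):
    """PE = achieved SEQ − formula-predicted SEQ, dpt."""
    out = np.asarray(seq_achieved, dtype=float) - np.asarray(seq_pred, dtype=float)
    return float(out) if out.ndim == 0 else out


def _cohort_arrays(cohort: pd.DataFrame):
    need = {"AL", "CCT", "ACD", "LT", "Rmean", "Rpow", "PIOL"}
    missing = need - set(cohort.columns)
    if missing:
        raise KeyError(
            f"cohort lacks columns {sorted(missing)}; run preprocess.derive() first"
        )
    g = lambda c: cohort[c].to_numpy(dtype=float)
    return g("AL"), g("CCT"), g("ACD"), g("LT"), g("Rmean"), g("Rpow"), g("PIOL")


def predict_cohort(
    spec: FormulaSpec,
    cohort: pd.DataFrame,
    constants: FormulaConstants,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Vectorised formula evaluation over a derived cohort table.

    Returns a DataFrame (same index as ``cohort``) with columns
    ``ELP``, ``Dcornea``, ``SEQ_pred`` and, when the cohort has an
    achieved ``SEQ`` column, ``PE``.  ``Dcornea`` is the thin-lens
    corneal power of the main part (for Castrop: the front-surface
    power of the thick-lens cornea).
    """
    al, cct, acd, lt, rmean, rpow, piol = _cohort_arrays(cohort)
    n_main = spec.main_index

    if spec.formula == "hofferq":
        k_elp = keratometric_power(rpow, spec.n_elp)
        elp = elp_hofferq(al, k_elp, constants.pacd)
        dc = keratometric_power(rpow, n_main)
        seq = seq_thin_chain(
            al, elp + _HOFFERQ_RETINA_MM, dc, piol,
            spec.n_aqueous, spec.vertex_mm, on_degenerate,
        )
    elif spec.formula == "holladay1":
        elp = elp_holladay1(al, rmean, constants.sf)
        dc = keratometric_power(rmean, n_main)
        seq = seq_thin_chain(
            al + _HOLLADAY_RT_MM, elp, dc, piol,
            spec.n_aqueous, spec.vertex_mm, on_degenerate,
        )
    elif spec.formula == "haigis":
        elp = elp_haigis(acd, al, constants)
        dc = keratometric_power(rmean, n_main)
        seq = seq_thin_chain(
            al, elp, dc, piol, spec.n_aqueous, spec.vertex_mm, on_degenerate
        )
    else:  # castrop
        elp = elp_castrop(acd, lt, constants.c, constants.h)
        r_back = spec.back_radius_ratio * rmean
        p1 = (n_main - 1.0) / (rmean * 1e-3)
        p2 = (spec.n_aqueous - n_main) / (r_back * 1e-3)
        seq = seq_thick_chain(
            cmal(al, lt), elp, p1, p2, cct, n_main, piol,
            spec.n_aqueous, spec.vertex_mm, on_degenerate,
        )
        seq = seq + constants.r_offset
        dc = p1

    out = pd.DataFrame(
        {
            "ELP": np.broadcast_to(np.asarray(elp, dtype=float), al.shape).copy(),
            "Dcornea": np.broadcast_to(np.asarray(dc, dtype=float), al.shape).copy(),
            "SEQ_pred": np.asarray(seq, dtype=float),
        },
        index=cohort.index,
    )
    if "SEQ" in cohort.columns:
        out["PE"] = prediction_error(cohort["SEQ"].to_numpy(dtype=float),
                                     out["SEQ_pred"].to_numpy())
    return out


def predict(
    spec: FormulaSpec,
    record,
    constants: FormulaConstants,
) -> Prediction:
    """Evaluate one formula for a single eye.

    ``record`` is a :class:`~iolopt.preprocess.BiometryRecord`, a mapping
    or a pandas Series with the raw cohort fields.  Degenerate vergences
    raise :class:`~iolopt.errors.DegenerateVergenceError`.
    """
    from .preprocess import compute_seq, mean_radius, power_mean_radius

    row = vars(record) if hasattr(record, "__dataclass_fields__") else dict(record)
    frame = pd.DataFrame([{k: v for k, v in row.items() if v is not None}])
    frame["Rmean"] = mean_radius(frame["R1"], frame["R2"])
    frame["Rpow"] = power_mean_radius(frame["R1"], frame["R2"])
    if "SEQ" not in frame.columns and {"sphere", "cylinder"} <= set(frame.columns):
        frame["SEQ"] = compute_seq(frame["sphere"], frame["cylinder"])
    res = predict_cohort(spec, frame, constants, on_degenerate="raise").iloc[0]
    return Prediction(
        elp_mm=float(res["ELP"]),
        d_cornea=float(res["Dcornea"]),
        seq_pred=float(res["SEQ_pred"]),
        pe=float(res["PE"]) if "PE" in res else None,
    )


def constants_to_array(constants: FormulaConstants) -> np.ndarray:
    """Pack a constants dataclass into a flat parameter vector."""
    return np.array(
        [getattr(constants, f) for f in constants.__dataclass_fields__], dtype=float
    )


def constants_from_array(formula: str, params) -> FormulaConstants:
    """Unpack a flat parameter vector into the formula's constants."""
    cls = {
        "hofferq": HofferQConstants,
        "holladay1": Holladay1Constants,
        "haigis": HaigisConstants,
        "castrop": CastropConstants,
    }[formula]
    return cls(*[float(p) for p in np.asarray(params, dtype=float)])
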