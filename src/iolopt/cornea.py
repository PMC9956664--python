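"""Paraxial corneal optics: thin-lens keratometry and thick-lens powers.

The cornea is either reduced to a single refracting surface via a
fictitious keratometer index nK (thin-lens model, classical formulas) or
treated as a meniscus lens with two refracting surfaces, a central
thickness and a physical stromal index nC (thick-lens model).  The
thick-lens cornea has three conventional powers — equivalent power
(referenced to the principal planes), back-vertex power and front-vertex
power — which differ by a propagation factor and agree only in the
thin-lens limit.

All radii are taken in millimetres and thicknesses in micrometres at the
API boundary; powers are returned in dioptres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .errors import DegenerateVergenceError, NoSolutionError

#: Refractive index of the aqueous humour (Gullstrand schematic eye).
AQUEOUS_INDEX = 1.336

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class CorneaThickLens:
    """Two-surface meniscus cornea.

    Parameters
    ----------
    r_front_mm : float
        Front (anterior) surface radius of curvature, mm.
    r_back_mm : float
        Back (posterior) surface radius of curvature, mm.  ``np.inf``
        describes a flat back surface.
    cct_um : float
        Central corneal thickness, µm.
    n_cornea : float
        Refractive index of the corneal stroma (classically 1.376).
    n_aqueous : float
        Index of the aqueous humour behind the cornea, default 1.336.
    """

    r_front_mm: float
    r_back_mm: float
    cct_um: float
    n_cornea: float
    n_aqueous: float = AQUEOUS_INDEX

    def __post_init__(self) -> None:
        if not self.r_front_mm > 0 or not self.r_back_mm > 0:
            raise ValueError("corneal radii must be positive")
        if not 1.25 < self.n_cornea < 1.45:
            raise ValueError(f"corneal index {self.n_cornea} outside (1.25, 1.45)")
        if not 0 <= self.cct_um < 900:
            raise ValueError(f"corneal thickness {self.cct_um} µm outside [0, 900)")


@dataclass(frozen=True)
class PowerSet:
    """The three conventional powers of a thick lens, dpt.

    ``equivalent`` is referenced to the principal planes,
    ``back_vertex`` to the back surface vertex (emergent vergence for
    parallel incident light), and ``front_vertex`` to the front vertex
    (emergent vergence of the reversed system).
    """

    p_front: float
    p_back: float
    equivalent: float
    back_vertex: float
    front_vertex: float


def keratometric_power(r_mm, n_k):
    """Thin-lens corneal power (nK − 1)/R from a front radius.

    Parameters
    ----------
    r_mm : float or array
        Corneal front radius, mm.
    n_k : float
        Keratometer index (Javal: 1.3375).
    """
    r_mm = np.asarray(r_mm, dtype=float)
    if np.any(r_mm <= 0):
        raise ValueError("corneal radius must be positive")
    out = (n_k - 1.0) / (r_mm * 1e-3)
    return float(out) if out.ndim == 0 else out


def thick_lens_powers(cornea: CorneaThickLens) -> PowerSet:
    """Surface, equivalent and vertex powers of a thick-lens cornea."""
    p1 = (cornea.n_cornea - 1.0) / (cornea.r_front_mm * 1e-3)
    p2 = (
        0.0
        if np.isinf(cornea.r_back_mm)
        else (cornea.n_aqueous - cornea.n_cornea) / (cornea.r_back_mm * 1e-3)
    )
    t = cornea.cct_um * 1e-6 / cornea.n_cornea  # reduced thickness, m
    p_eq = p1 + p2 - t * p1 * p2
    den_back = 1.0 - t * p1
    den_front = 1.0 - t * p2
    if abs(den_back) < _DEGENERATE_TOL or abs(den_front) < _DEGENERATE_TOL:
        raise DegenerateVergenceError("vertex-power denominator vanishes")
    return PowerSet(
        p_front=p1,
        p_back=p2,
        equivalent=p_eq,
        back_vertex=p_eq / den_back,
        front_vertex=p_eq / den_front,
    )


_WHICH = ("equivalent", "back_vertex", "front_vertex")


def solve_index_for_power(
    target_dpt: float,
    which: str,
    r_front_mm: float,
    r_back_mm: float,
    cct_um: float,
    n_aqueous: float = AQUEOUS_INDEX,
    bracket: tuple[float, float] = (1.30, 1.42),
    xtol: float = 1e-12,
) -> float:
    """Corneal index nC at which a thick-lens power equals a target.

    Finds the stromal index for which the selected member of
    :class:`PowerSet` (``which`` in ``{"equivalent", "back_vertex",
    "front_vertex"}``) equals ``target_dpt``, by bisection on the
    bracket.  The selected power is continuous and monotone in nC over
    physiological brackets, so bisection is robust.

    Raises
    ------
    NoSolutionError
        If the target power is not attained inside the bracket.
    """
    if which not in _WHICH:
        raise ValueError(f"which must be one of {_WHICH}, got {which!r}")

    def _gap(n_c: float) -> float:
        powers = thick_lens_powers(
            CorneaThickLens(r_front_mm, r_back_mm, cct_um, n_c, n_aqueous)
        )
        return getattr(powers, which) - target_dpt

    lo, hi = bracket
    if _gap(lo) * _gap(hi) > 0:
        raise NoSolutionError(
            f"{which} power {target_dpt} dpt not attained for nC in {bracket}"
        )
    return float(bisect(_gap, lo, hi, xtol=xtol))
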