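"""Independent paraxial oracles used by the tests.

The raytracer here is deliberately coded against a different formalism
than the library's vergence chains: 2×2 ABCD matrices acting on rays
(y, nu) with reduced angles nu = n·u.  A refraction of power P is
[[1, 0], [−P, 1]] and a translation t in medium n is [[1, t/n], [0, 1]].
A ray from an axial point with vergence V at the entry plane crosses it
at height y with reduced angle nu = −V·y, so for a system matrix M from
the spectacle plane to the retina the point images on the retina iff
A·y + B·nu = (A − B·V)·y = 0: the predicted refraction is V = A/B.
"""

from __future__ import annotations

import numpy as np


def _t(t_m: float, n: float) -> np.ndarray:
    return np.array([[1.0, t_m / n], [0.0, 1.0]])


def _r(power: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [-power, 1.0]])


def matrix_seq_thin(al_mm, elp_mm, d_cornea, p_iol, n_aq=1.336, vd_mm=12.0):
    """Predicted SEQ of the thin-cornea pseudophakic eye via matrices."""
    m = (
        _t((al_mm - elp_mm) * 1e-3, n_aq)
        @ _r(p_iol)
        @ _t(elp_mm * 1e-3, n_aq)
        @ _r(d_cornea)
        @ _t(vd_mm * 1e-3, 1.0)
    )
    a, b = m[0]
    return a / b


def matrix_seq_thick(
    al_eff_mm, elp_mm, p_front, p_back, cct_um, n_c, p_iol, n_aq=1.336, vd_mm=12.0
):
    """Predicted SEQ with a two-surface cornea via matrices."""
    cct_mm = cct_um * 1e-3
    m = (
        _t((al_eff_mm - elp_mm) * 1e-3, n_aq)
        @ _r(p_iol)
        @ _t((elp_mm - cct_mm) * 1e-3, n_aq)
        @ _r(p_back)
        @ _t(cct_mm * 1e-3, n_c)
        @ _r(p_front)
        @ _t(vd_mm * 1e-3, 1.0)
    )
    a, b = m[0]
    return a / b


def matrix_equivalent_power(p_front, p_back, cct_um, n_c):
    """Equivalent power of a thick lens from its system matrix."""
    m = _r(p_back) @ _t(cct_um * 1e-6, n_c) @ _r(p_front)
    return -m[1, 0]


def bisect_index(gap, lo=1.30, hi=1.42, tol=1e-12):
    """Plain hand-rolled bisection, independent of scipy."""
    f_lo = gap(lo)
    if f_lo * gap(hi) > 0:
        raise ValueError("no sign change")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f_lo * gap(mid) <= 0:
            hi = mid
        else:
            lo = mid
            f_lo = gap(lo)
    return 0.5 * (lo + hi)
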