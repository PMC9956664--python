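"""Formula-constant and refractive-index optimisation.

Four optimisation situations are supported, mirroring how IOL formula
constants are customised in practice:

* **A** — constants only, with the formula's published keratometer or
  corneal refractive index; minimises the sum of squared prediction
  errors PE.
* **B** — constants plus the main-part index nK/nC as an extra free
  parameter (the ELP prediction part keeps the published index).
* **C** — as B, with the least-squares slope of PE over corneal radius
  (Rpow for Hoffer Q, Rmean otherwise) added to the merit as a single
  strongly weighted residual, so the radius trend error is driven to
  zero alongside the PE minimisation.
* **D** — constants only (as A) but with a main-part index transferred
  from another cohort's situation-B fit (cross-validation).

The minimiser is a damped (Levenberg–Marquardt) least-squares iteration
with a finite-difference Jacobian, parameter rescaling, and three
stopping criteria: at most 1000 iterations, a merit-improvement
threshold of 1e−16 and a step-size threshold of 1e−14.  Writing the
iteration out (rather than delegating to a canned solver) keeps the
merit sequence, iteration/evaluation counts and stop reason available
as diagnostics, and guarantees the accepted-step merit sequence is
monotone.  Eyes whose vergence chain is degenerate at the current
parameters contribute a large finite penalty residual (100 dpt) so the
merit stays finite over invalid parameter regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortError
from .formulas import (
    FormulaConstants,
    FormulaSpec,
    constants_from_array,
    constants_to_array,
    nominal_constants,
    predict_cohort,
    published_index,
)
from .metrics import TrendFit, trend_regression

logger = logging.getLogger(__name__)

#: Penalty residual (dpt) for an eye with a degenerate vergence chain.
PENALTY_RESIDUAL = 100.0

#: Characteristic scale of the index parameter around its default.
_INDEX_SCALE = 0.01

SITUATIONS = ("A", "B", "C", "D")


def trend_covariate(formula: str) -> str:
    """Radius covariate of the trend regression: Rpow for Hoffer Q."""
    return "Rpow" if formula == "hofferq" else "Rmean"


def default_slope_weight(n: int) -> float:
    """Default trend-nulling weight λ = 100·√n.

    Together with the √n factor inside the slope residual this makes
    the single trend term dominate the merit once the PE residuals have
    plateaued, so the optimum carries an essentially exactly nulled
    slope.
    """
    return 100.0 * np.sqrt(n)


@dataclass
class OptimisationProblem:
    """One formula/situation fit on one derived cohort.

    ``cohort`` must carry the derived columns (``SEQ``, ``Rmean``,
    ``Rpow``); ``n_main_fixed`` supplies the transferred index for
    situation D.  ``x0_constants``/``x0_index`` override the staged
    initialisation.
    """

    cohort: pd.DataFrame
    formula: str
    situation: str
    n_main_fixed: float | None = None
    slope_weight: float | None = None
    x0_constants: FormulaConstants | None = None
    x0_index: float | None = None
    vertex_mm: float = 12.0
    max_iter: int = 1000
    merit_tol: float = 1e-16
    step_tol: float = 1e-14

    def __post_init__(self) -> None:
        if self.situation not in SITUATIONS:
            raise ValueError(f"situation must be one of {SITUATIONS}")
        if self.situation == "D" and self.n_main_fixed is None:
            raise ValueError("situation D needs a transferred index (n_main_fixed)")
        if self.slope_weight is not None and self.slope_weight <= 0:
            raise ValueError("slope weight must be positive")
        for col in ("SEQ", "Rmean", "Rpow"):
            if col not in self.cohort.columns:
                raise CohortError(
                    f"cohort lacks derived column {col!r}; run preprocess.derive()"
                )

    @property
    def frees_index(self) -> bool:
        return self.situation in ("B", "C")


@dataclass(frozen=True)
class OptimisationResult:
    """Fitted constants/index plus convergence diagnostics."""

    formula: str
    situation: str
    constants: FormulaConstants
    n_main: float
    iterations: int
    n_fev: int
    rms_pe: float
    trend: TrendFit
    converged: bool
    stop_reason: str
    merit_history: tuple[float, ...] = field(repr=False, default=())


# --------------------------------------------------------------------------
# residual vectors


def _pe_vector(problem: OptimisationProblem, constants, n_main) -> np.ndarray:
    spec = FormulaSpec(
        formula=problem.formula, n_main=n_main, vertex_mm=problem.vertex_mm
    )
    pred = predict_cohort(spec, problem.cohort, constants, on_degenerate="nan")
    pe = problem.cohort["SEQ"].to_numpy(dtype=float) - pred["SEQ_pred"].to_numpy()
    return pe


def _penalised(pe: np.ndarray) -> np.ndarray:
    return np.where(np.isfinite(pe), pe, PENALTY_RESIDUAL)


def residuals_A(params, problem: OptimisationProblem) -> np.ndarray:
    """PE residuals at the given constants, published (or fixed) index."""
    n_main = (
        problem.n_main_fixed
        if problem.n_main_fixed is not None
        else published_index(problem.formula)
    )
    constants = constants_from_array(problem.formula, params)
    return _penalised(_pe_vector(problem, constants, n_main))


def residuals_B(params, problem: OptimisationProblem) -> np.ndarray:
    """PE residuals with the main-part index as the last free parameter."""
    constants = constants_from_array(problem.formula, params[:-1])
    return _penalised(_pe_vector(problem, constants, float(params[-1])))


def residuals_C(params, problem: OptimisationProblem) -> np.ndarray:
    """Situation-B residuals plus one weighted radius-trend element.

    The extra element is λ·√N·slope(PE, radius) with slope in dpt/mm;
    eyes with degenerate vergences are excluded from the slope and
    penalised in the PE part.
    """
    constants = constants_from_array(problem.formula, params[:-1])
    pe = _pe_vector(problem, constants, float(params[-1]))
    cov = trend_covariate(problem.formula)
    radius = problem.cohort[cov].to_numpy(dtype=float)
    valid = np.isfinite(pe)
    n = pe.size
    lam = (
        problem.slope_weight
        if problem.slope_weight is not None
        else default_slope_weight(n)
    )
    if valid.sum() >= 2:
        slope = trend_regression(pe[valid], radius[valid], cov).slope
    else:
        slope = PENALTY_RESIDUAL
    return np.append(_penalised(pe), lam * np.sqrt(n) * slope)


# --------------------------------------------------------------------------
# damped least squares


def _fd_jacobian(fun, x, r0, nfev_counter):
    n = x.size
    jac = np.empty((r0.size, n))
    for j in range(n):
        h = np.sqrt(np.finfo(float).eps) * max(1.0, abs(x[j]))
        xh = x.copy()
        xh[j] += h
        jac[:, j] = (fun(xh) - r0) / h
        nfev_counter[0] += 1
    return jac


def _levenberg_marquardt(fun, x0, max_iter, merit_tol, step_tol):
    """Marquardt-damped Gauss-Newton on a scaled parameter vector.

    Returns (x, merits, iterations, nfev, stop_reason).  ``merits`` is
    the sequence of accepted merit values and is non-increasing by
    construction.
    """
    x = np.asarray(x0, dtype=float).copy()
    nfev = [0]
    r = fun(x)
    nfev[0] += 1
    merit = float(r @ r)
    merits = [merit]
    lam = 1e-3
    stop_reason = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        jac = _fd_jacobian(fun, x, r, nfev)
        g = jac.T @ r
        a = jac.T @ jac
        diag = np.diag(a).copy()
        diag[diag <= 0] = np.max(diag) if np.max(diag) > 0 else 1.0
        accepted = False
        while lam < 1e14:
            try:
                step = np.linalg.solve(a + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_new = fun(x + step)
            nfev[0] += 1
            merit_new = float(r_new @ r_new)
            if merit_new <= merit:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            stop_reason = "stalled"
            break
        improvement = merit - merit_new
        step_norm = float(np.linalg.norm(step))
        x = x + step
        r, merit = r_new, merit_new
        merits.append(merit)
        lam = max(lam / 10.0, 1e-12)
        if improvement < merit_tol:
            stop_reason = "merit_tol"
            break
        if step_norm < step_tol:
            stop_reason = "step_tol"
            break
    return x, merits, it, nfev[0], stop_reason


# --------------------------------------------------------------------------
# public entry points


def _coarse_offset_scan(problem, constants0, n_main, half_width=4.0, step=0.5):
    """1-D grid pre-search over the additive position constant.

    Shifting pACD/SF/a0/H moves the whole PE distribution; a coarse
    scan avoids starting the damped iteration in a far-off basin.
    """
    offset_field = {
        "hofferq": "pacd", "holladay1": "sf", "haigis": "a0", "castrop": "h",
    }[problem.formula]
    best, best_merit = constants0, np.inf
    for delta in np.arange(-half_width, half_width + step / 2, step):
        cand = replace(
            constants0, **{offset_field: getattr(constants0, offset_field) + delta}
        )
        r = _penalised(_pe_vector(problem, cand, n_main))
        merit = float(r @ r)
        if merit < best_merit:
            best, best_merit = cand, merit
    return best


def optimise(problem: OptimisationProblem) -> OptimisationResult:
    """Run one optimisation situation on one cohort.

    Initialisation: situations A and D start from the supplied (or
    nominal) constants refined by a coarse scan of the additive position
    constant; situations B and C start from the situation-A optimum
    with the published index.  Free parameters are rescaled to
    comparable magnitude (constants ~1, index ~0.01) before damping.
    """
    n_params = constants_to_array(nominal_constants(problem.formula)).size + (
        1 if problem.frees_index else 0
    )
    usable = int(np.isfinite(problem.cohort["SEQ"]).sum())
    if usable < max(10, n_params + 1):
        raise CohortError(
            f"need at least {max(10, n_params + 1)} usable eyes, have {usable}"
        )

    if problem.frees_index:
        residual_fun = residuals_C if problem.situation == "C" else residuals_B
        base = problem.x0_constants
        if base is None:
            sit_a = optimise(
                replace(problem, situation="A", n_main_fixed=None, x0_index=None)
            )
            base = sit_a.constants
        n0 = (
            problem.x0_index
            if problem.x0_index is not None
            else published_index(problem.formula)
        )
        x0 = np.append(constants_to_array(base), n0)
        scales = np.append(np.ones(x0.size - 1), _INDEX_SCALE)
    else:
        residual_fun = residuals_A
        n_fixed = (
            problem.n_main_fixed
            if problem.n_main_fixed is not None
            else published_index(problem.formula)
        )
        base = problem.x0_constants or nominal_constants(problem.formula)
        base = _coarse_offset_scan(problem, base, n_fixed)
        x0 = constants_to_array(base)
        scales = np.ones(x0.size)

    fun = lambda xs: residual_fun(xs * scales, problem)
    xs, merits, iterations, nfev, stop_reason = _levenberg_marquardt(
        fun, x0 / scales, problem.max_iter, problem.merit_tol, problem.step_tol
    )
    x = xs * scales

    if problem.frees_index:
        constants = constants_from_array(problem.formula, x[:-1])
        n_main = float(x[-1])
    else:
        constants = constants_from_array(problem.formula, x)
        n_main = (
            problem.n_main_fixed
            if problem.n_main_fixed is not None
            else published_index(problem.formula)
        )

    pe = _pe_vector(problem, constants, n_main)
    valid = np.isfinite(pe)
    cov = trend_covariate(problem.formula)
    trend = trend_regression(
        pe[valid], problem.cohort[cov].to_numpy(dtype=float)[valid], cov
    )
    converged = stop_reason in ("merit_tol", "step_tol")
    if not converged:
        logger.warning(
            "%s situation %s did not converge (%s after %d iterations)",
            problem.formula, problem.situation, stop_reason, iterations,
        )
    return OptimisationResult(
        formula=problem.formula,
        situation=problem.situation,
        constants=constants,
        n_main=float(n_main),
        iterations=iterations,
        n_fev=nfev,
        rms_pe=float(np.sqrt(np.mean(pe[valid] ** 2))),
        trend=trend,
        converged=converged,
        stop_reason=stop_reason,
        merit_history=tuple(merits),
    )


def optimise_situation(
    cohort: pd.DataFrame,
    formula: str,
    situation: str,
    n_main_fixed: float | None = None,
    slope_weight: float | None = None,
    **kwargs,
) -> OptimisationResult:
    """Convenience wrapper building the :class:`OptimisationProblem`."""
    return optimise(
        OptimisationProblem(
            cohort=cohort,
            formula=formula,
            situation=situation,
            n_main_fixed=n_main_fixed,
            slope_weight=slope_weight,
            **kwargs,
        )
    )


@dataclass(frozen=True)
class CrossValidation:
    """Situation-B fits of two cohorts and the index-swapped D fits."""

    b_first: OptimisationResult
    b_second: OptimisationResult
    d_first: OptimisationResult  # first cohort, index from second's B
    d_second: OptimisationResult  # second cohort, index from first's B


def cross_validate(
    cohort1: pd.DataFrame, cohort2: pd.DataFrame, formula: str, **kwargs
) -> CrossValidation:
    """Transfer each cohort's fitted index to the other cohort.

    Runs situation B on both cohorts, then a constants-only refit
    (situation D) on each cohort using the index fitted on the other —
    the cross-validation of the optimised keratometer/corneal index.
    """
    b1 = optimise_situation(cohort1, formula, "B", **kwargs)
    b2 = optimise_situation(cohort2, formula, "B", **kwargs)
    d1 = optimise_situation(
        cohort1, formula, "D", n_main_fixed=b2.n_main,
        x0_constants=b1.constants, **kwargs,
    )
    d2 = optimise_situation(
        cohort2, formula, "D", n_main_fixed=b1.n_main,
        x0_constants=b2.constants, **kwargs,
    )
    return CrossValidation(b_first=b1, b_second=b2, d_first=d1, d_second=d2)
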