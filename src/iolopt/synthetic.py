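"""Synthetic pseudophakic cohorts with a known ground-truth optical model.

Clinical constant-optimisation datasets are rarely shareable, so this
module generates cohorts whose biometry reproduces the marginal
distributions of a typical European cataract population (means/SDs and
95% spans of AL, CCT, ACD, LT, R1, R2) together with a plausible
correlation structure, and whose refractive outcomes are produced by a
*known* forward model: a chosen formula with chosen constants and
index selects the implanted IOL power from a discrete grid against a
target refraction, and the achieved refraction is the model prediction
plus measurement noise, rounded to the refraction increment.

Because the generating constants and index are known, every
optimisation situation can be validated end-to-end by parameter
recovery, which real clinical data never allows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CohortError
from .formulas import (
    FormulaConstants,
    FormulaSpec,
    HaigisConstants,
    predict_cohort,
)
from .preprocess import derive

logger = logging.getLogger(__name__)

_VARS = ("AL", "CCT", "ACD", "LT", "R1", "R2")

#: Marginal means of the biometry variables (mm except CCT in µm).
DEFAULT_MEANS = {
    "AL": 24.0980, "CCT": 559.0, "ACD": 3.1864,
    "LT": 4.6176, "R1": 7.8598, "R2": 7.6732,
}

#: Marginal standard deviations.
DEFAULT_SDS = {
    "AL": 1.4072, "CCT": 36.0, "ACD": 0.4081,
    "LT": 0.4568, "R1": 0.2828, "R2": 0.2745,
}

#: 2.5%/97.5% marginal quantiles used to truncate the sampler.
DEFAULT_SPANS = {
    "AL": (22.0997, 26.7788), "CCT": (499.0, 618.0), "ACD": (2.5139, 3.8299),
    "LT": (3.8630, 5.3548), "R1": (7.3955, 8.3355), "R2": (7.2234, 8.1504),
}

#: Physiologically plausible cross-correlations (positive-definite).
DEFAULT_CORRELATIONS = {
    ("AL", "ACD"): 0.45,
    ("AL", "LT"): -0.30,
    ("ACD", "LT"): -0.35,
    ("R1", "R2"): 0.95,
    ("AL", "R1"): 0.30,
    ("AL", "R2"): 0.30,
}

#: Default ground truth: a Haigis eye model with a realistic triplet.
DEFAULT_TRUTH_CONSTANTS = HaigisConstants(a0=-0.6853, a1=0.3417, a2=0.2029)


def correlation_matrix(
    correlations: Mapping[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Assemble (and PD-check) the 6×6 biometry correlation matrix."""
    corr = np.eye(len(_VARS))
    idx = {v: i for i, v in enumerate(_VARS)}
    for (a, b), rho in (correlations or DEFAULT_CORRELATIONS).items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise CohortError("correlation matrix is not positive definite")
    return corr


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults describe a cataract population implanted with an
    aspheric monofocal IOL: ~0.3 dpt refraction noise, refraction
    recorded in 1/8-dpt steps, lens powers available from 6 to 30 dpt
    in half-dioptre increments, and surgeons targeting −0.3 dpt.
    Truncation bounds are the marginal 95% spans widened by 20% so the
    tails are soft but impossible eyes are excluded.
    """

    n: int = 888
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS)
    )
    truth_formula: str = "haigis"
    truth_constants: FormulaConstants = DEFAULT_TRUTH_CONSTANTS
    truth_n_main: float | None = None  # None -> the formula's published index
    target_refraction: float = -0.3
    iol_grid: tuple[float, float, float] = (6.0, 30.0, 0.5)
    noise_sd: float = 0.3
    rounding: float = 0.125
    widen: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CohortError("cohort size must be positive")
        if self.noise_sd < 0 or self.rounding < 0:
            raise CohortError("noise SD and rounding step must be non-negative")
        if self.iol_grid[2] <= 0:
            raise CohortError("IOL grid step must be positive")

    def bounds(self) -> dict[str, tuple[float, float]]:
        """Rejection bounds: each 95% quantile moved outward by
        ``widen`` times the 95% span (soft tails, no impossible eyes)."""
        out = {}
        for v in _VARS:
            lo, hi = DEFAULT_SPANS[v]
            margin = self.widen * (hi - lo)
            out[v] = (lo - margin, hi + margin)
        return out


def sample_biometry(
    cfg: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw biometry from a truncated correlated Gaussian.

    Rejection sampling against the per-variable bounds; deterministic
    under a seeded generator.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    corr = correlation_matrix(cfg.correlations)
    chol = np.linalg.cholesky(corr)
    mean = np.array([cfg.means[v] for v in _VARS])
    sd = np.array([cfg.sds[v] for v in _VARS])
    bounds = cfg.bounds()
    lo = np.array([bounds[v][0] for v in _VARS])
    hi = np.array([bounds[v][1] for v in _VARS])

    rows = []
    needed = cfg.n
    for _ in range(200):
        z = rng.standard_normal((max(2 * needed, 64), len(_VARS)))
        x = mean + (z @ chol.T) * sd
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        rows.append(x[ok])
        needed = cfg.n - sum(len(r) for r in rows)
        if needed <= 0:
            break
    else:
        raise CohortError("rejection sampling failed; check bounds vs marginals")
    table = np.concatenate(rows)[: cfg.n]
    return pd.DataFrame(table, columns=list(_VARS))


def implant_and_refract(
    eyes: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Select IOL powers and simulate postoperative refractions.

    For each eye the ground-truth formula is evaluated over the IOL
    power grid and the power whose predicted SEQ is closest to the
    target refraction is implanted (ties resolved towards the lower
    power).  The achieved SEQ is the truth prediction plus Gaussian
    noise, rounded to the refraction step, and recorded as sphere with
    zero cylinder.  Eyes with no valid grid power are dropped with a
    log entry.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spec = FormulaSpec(formula=cfg.truth_formula, n_main=cfg.truth_n_main)
    lo, hi, step = cfg.iol_grid
    powers = np.arange(lo, hi + step / 2, step)

    work = eyes.copy().reset_index(drop=True)
    work["PIOL"] = 0.0
    work["sphere"] = 0.0
    work["cylinder"] = 0.0
    base = derive(work.assign(VA=1.0))

    seq_grid = np.empty((len(base), powers.size))
    for j, p in enumerate(powers):
        seq_grid[:, j] = predict_cohort(
            spec, base.assign(PIOL=p), cfg.truth_constants, on_degenerate="nan"
        )["SEQ_pred"].to_numpy()

    gap = np.abs(seq_grid - cfg.target_refraction)
    gap = np.where(np.isfinite(gap), gap, np.inf)
    choice = np.argmin(gap, axis=1)  # first minimum -> lower power on ties
    valid = np.isfinite(gap[np.arange(len(base)), choice])
    if not valid.all():
        logger.warning(
            "implant_and_refract: dropped %d eyes with no valid IOL power",
            int((~valid).sum()),
        )

    out = base.loc[valid].copy()
    sel = choice[valid]
    out["PIOL"] = powers[sel]
    seq_true = seq_grid[np.arange(len(base)), choice][valid]
    out["SEQ_true"] = seq_true
    achieved = seq_true + (
        rng.normal(0.0, cfg.noise_sd, size=seq_true.size) if cfg.noise_sd > 0 else 0.0
    )
    if cfg.rounding > 0:
        achieved = np.round(achieved / cfg.rounding) * cfg.rounding
    out["sphere"] = achieved
    out["cylinder"] = 0.0
    out["SEQ"] = achieved
    out["VA"] = 1.0
    return out.reset_index(drop=True)


def generate_cohort(
    cfg: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample biometry, implant IOLs and refract: one complete cohort."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return implant_and_refract(sample_biometry(cfg, rng), cfg, rng)
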