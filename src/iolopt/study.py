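"""End-to-end study execution: preprocess → optimise → metrics → tables.

``run_study`` ties the modules together into a reproducible run: it
loads (or simulates) cohorts, applies the visual-acuity inclusion
filter, fits every requested formula × situation, and writes constants
tables, prediction-error statistics, trend/CDF/boxplot data and a
machine-readable manifest to an output directory.  Partial failures are
isolated per formula/situation and recorded instead of aborting the
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formulas import FORMULAS, FormulaSpec, predict_cohort
from .metrics import abs_pe_box, cdf_curve, pe_stats, trend_regression
from .optimize import (
    OptimisationResult,
    cross_validate,
    optimise_situation,
    trend_covariate,
)
from .preprocess import derive, filter_va, read_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one study run."""

    inputs: list[str] = field(default_factory=list)  # cohort files (1 or 2)
    column_map: dict = field(default_factory=dict)
    formulas: list[str] = field(default_factory=lambda: list(FORMULAS))
    situations: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    slope_weight: float | None = None
    vertex_mm: float = 12.0
    va_threshold: float = 0.8
    keep_missing_va: bool = True
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        bad = set(self.situations) - set("ABCD")
        if bad:
            raise ValueError(f"unknown situations {sorted(bad)}")
        if "D" in self.situations and len(self.inputs) != 2:
            raise ValueError("situation D requires two cohorts (cross-validation)")


def _result_row(res: OptimisationResult) -> dict:
    row = {
        "formula": res.formula,
        "situation": res.situation,
        "n_main": res.n_main,
        "rms_pe": res.rms_pe,
        "trend_slope": res.trend.slope,
        "trend_intercept": res.trend.intercept,
        "iterations": res.iterations,
        "n_fev": res.n_fev,
        "converged": res.converged,
        "stop_reason": res.stop_reason,
    }
    row.update(asdict(res.constants))
    return row


def _stats_rows(res: OptimisationResult, cohort: pd.DataFrame) -> list[dict]:
    spec = FormulaSpec(formula=res.formula, n_main=res.n_main)
    pe = predict_cohort(spec, cohort, res.constants)["PE"].to_numpy()
    s = pe_stats(pe)
    return [
        {
            "formula": res.formula,
            "situation": res.situation,
            "statistic": name,
            "value": value,
        }
        for name, value in (
            ("mean", s.mean), ("SD", s.sd), ("median", s.median),
            ("q2.5", s.q025), ("q97.5", s.q975), ("IQR", s.iqr),
        )
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(cfg: RunConfig, cohorts: list[pd.DataFrame] | None = None) -> dict:
    """Execute a full constant-optimisation study.

    ``cohorts`` may inject in-memory tables (e.g. synthetic ones);
    otherwise ``cfg.inputs`` are read from disk.  Returns a bundle with
    the fitted results, the output tables and the manifest, and writes
    everything under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cohorts is None:
        cohorts = [read_cohort(p, cfg.column_map or None) for p in cfg.inputs]
    prepared = [
        derive(filter_va(c, cfg.va_threshold, keep_missing=cfg.keep_missing_va))
        for c in cohorts
    ]

    results: list[OptimisationResult] = []
    failures: list[dict] = []
    stats_rows: list[dict] = []
    per_eye_frames: list[pd.DataFrame] = []

    for ci, cohort in enumerate(prepared, start=1):
        for formula in cfg.formulas:
            for situation in [s for s in cfg.situations if s != "D"]:
                try:
                    res = optimise_situation(
                        cohort, formula, situation,
                        slope_weight=cfg.slope_weight if situation == "C" else None,
                        vertex_mm=cfg.vertex_mm,
                    )
                except Exception as exc:  # isolate per formula/situation
                    logger.exception("%s/%s failed on cohort %d", formula, situation, ci)
                    failures.append(
                        {"cohort": ci, "formula": formula,
                         "situation": situation, "error": str(exc)}
                    )
                    continue
                results.append(res)
                stats_rows.extend(_stats_rows(res, cohort))
                spec = FormulaSpec(formula=formula, n_main=res.n_main)
                per_eye = predict_cohort(spec, cohort, res.constants)
                per_eye.insert(0, "cohort", ci)
                per_eye.insert(1, "formula", formula)
                per_eye.insert(2, "situation", situation)
                per_eye[trend_covariate(formula)] = cohort[trend_covariate(formula)]
                per_eye_frames.append(per_eye)

    if "D" in cfg.situations and len(prepared) == 2:
        for formula in cfg.formulas:
            try:
                cv = cross_validate(prepared[0], prepared[1], formula,
                                    vertex_mm=cfg.vertex_mm)
            except Exception as exc:
                logger.exception("%s cross-validation failed", formula)
                failures.append(
                    {"cohort": "1+2", "formula": formula,
                     "situation": "D", "error": str(exc)}
                )
                continue
            for ci, res in ((1, cv.d_first), (2, cv.d_second)):
                results.append(res)
                stats_rows.extend(_stats_rows(res, prepared[ci - 1]))

    constants_long = pd.DataFrame([_result_row(r) for r in results])
    stats_long = pd.DataFrame(stats_rows)
    constants_long.to_csv(out_dir / "constants_long.csv", index=False)
    stats_long.to_csv(out_dir / "pe_stats_long.csv", index=False)
    if not stats_long.empty:
        stats_wide = stats_long.pivot_table(
            index=["formula", "statistic"], columns="situation",
            values="value", sort=False,
        )
        stats_wide.to_csv(out_dir / "pe_stats_wide.csv")
    if per_eye_frames:
        per_eye_all = pd.concat(per_eye_frames, ignore_index=True)
        per_eye_all.to_csv(out_dir / "per_eye_pe.csv", index=False)
        _write_figure_data(per_eye_all, out_dir)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "settings": {
            k: v for k, v in asdict(cfg).items() if k not in ("inputs",)
        },
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in cfg.inputs
        ],
        "n_results": len(results),
        "failures": failures,
        "iteration_counts": [r.iterations for r in results],
        "function_evaluations": [r.n_fev for r in results],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "results": results,
        "constants": constants_long,
        "pe_stats": stats_long,
        "failures": failures,
        "manifest": manifest,
    }


def _write_figure_data(per_eye: pd.DataFrame, out_dir: Path) -> None:
    """CDF, |PE| boxplot and trend-regression data per formula/situation."""
    cdf_rows, box_rows, trend_rows = [], [], []
    for (cohort, formula, situation), grp in per_eye.groupby(
        ["cohort", "formula", "situation"], sort=False
    ):
        pe = grp["PE"].to_numpy(dtype=float)
        curve = cdf_curve(pe)
        curve.insert(0, "cohort", cohort)
        curve.insert(1, "formula", formula)
        curve.insert(2, "situation", situation)
        cdf_rows.append(curve)
        b = abs_pe_box(pe)
        box_rows.append(
            {"cohort": cohort, "formula": formula, "situation": situation,
             **asdict(b)}
        )
        cov = trend_covariate(formula)
        t = trend_regression(pe, grp[cov].to_numpy(dtype=float), cov)
        trend_rows.append(
            {"cohort": cohort, "formula": formula, "situation": situation,
             **asdict(t)}
        )
    pd.concat(cdf_rows, ignore_index=True).to_csv(out_dir / "cdf_data.csv", index=False)
    pd.DataFrame(box_rows).to_csv(out_dir / "box_data.csv", index=False)
    pd.DataFrame(trend_rows).to_csv(out_dir / "trend_data.csv", index=False)
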