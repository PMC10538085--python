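"""Empirical critical-pressure model.

The central relation of the package is the power law

    Pc = c * E * (a/g)**n

with Pc the critical (escape) pressure in Pa, E the cell's Young modulus in
Pa, a the cell diameter and g the trap gap (both in um, only their ratio
matters).  The calibrated values are c = 0.027 and n = 2: critical pressure
grows quadratically with the diameter-to-gap ratio and linearly with cell
stiffness.

This module provides

* :func:`predict_critical_pressure` -- evaluate the relation,
* :func:`fit_power_law` -- estimate (c, n) from sweep data by least squares,
* :func:`compare_model_orders` -- rank fixed exponents {1, 2, 3} by fit,
* :func:`validate_against` -- R^2 / Pearson r of the model against measured
  (gap, Pc) observations,
* CSV/JSON helpers for the sweep-record dataset and fit reports.

Regression is done on log-transformed pressures by default (the power law
becomes linear, and relative errors are weighted equally across decades); an
untransformed nonlinear least-squares objective is available for sensitivity
checks.  R^2 is always reported on the untransformed pressure scale, because
models of different exponent are compared on pressure values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
    UnidentifiableModelError,
)
from .types import CellSpec, FitResult, PowerLawModel, SweepRecord, TrapGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "predict_critical_pressure",
    "fit_power_law",
    "compare_model_orders",
    "validate_against",
    "read_sweep_csv",
    "write_sweep_csv",
    "write_fit_report",
]

#: Search range for the free exponent in the nonlinear objective; brackets
#: the linear-to-cubic model comparison with margin.
EXPONENT_RANGE = (0.5, 4.0)


def predict_critical_pressure(
    model: PowerLawModel, cell: CellSpec, geometry: TrapGeometry
) -> float:
    """Critical pressure (Pa) for ``cell`` at ``geometry`` under ``model``.

    Strictly increasing in E and in a/g; exactly linear in E; depends on
    the lengths only through the ratio a/g.
    """
    ratio = cell.diameter / geometry.gap
    return model.coefficient * cell.youngs_modulus * ratio**model.exponent


def _usable(records: Sequence[SweepRecord]) -> list[SweepRecord]:
    """Records that can enter a log-space fit: converged and Pc > 0."""
    kept = [r for r in records if r.converged and r.critical_pressure > 0]
    dropped = len(records) - len(kept)
    if dropped:
        logger.warning(
            "excluding %d record(s) with Pc = 0 or failed runs from the fit",
            dropped,
        )
    return kept


def _diagnostics(
    records: Sequence[SweepRecord],
    model: PowerLawModel,
    n_params: int,
    exponent_mode: str,
) -> FitResult:
    pc = np.array([r.critical_pressure for r in records])
    pred = np.array(
        [predict_critical_pressure(model, r.cell, r.geometry) for r in records]
    )
    resid = pc - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((pc - pc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    dof = max(len(records) - n_params, 1)
    se = np.sqrt(ss_res / dof)
    log_resid = np.log(pc) - np.log(pred)
    se_log = float(np.sqrt(np.sum(log_resid**2) / dof))
    return FitResult(
        model=model,
        r_squared=float(r2),
        standard_error=float(se),
        log_standard_error=se_log,
        n_points=len(records),
        residuals=tuple(resid),
        exponent_mode=exponent_mode,
    )


def fit_power_law(
    records: Sequence[SweepRecord],
    exponent: float | None = None,
    objective: str = "log",
) -> FitResult:
    """Least-squares fit of Pc = c * E * (a/g)**n to sweep records.

    Parameters
    ----------
    records
        Sweep observations; records with Pc = 0 (free passage) or failed
        runs are excluded with a logged warning.
    exponent
        If ``None`` (default) the exponent n is a free parameter; otherwise
        it is held fixed at the given value and only c is estimated.  The
        relation is linear in E by construction, so E needs no exponent.
    objective
        ``"log"`` (default): ordinary least squares on log Pc, which
        linearizes the power law.  ``"nls"``: nonlinear least squares on
        the pressure scale, multi-started across the exponent range.

    Raises
    ------
    InsufficientDataError
        Fewer usable records than free parameters + 1.
    UnidentifiableModelError
        Free exponent requested but all records share one a/g ratio.
    """
    records = _usable(list(records))
    free = exponent is None
    n_params = 2 if free else 1
    if len(records) < max(n_params + 1, 3):
        raise InsufficientDataError(
            f"need at least {max(n_params + 1, 3)} usable records, "
            f"got {len(records)}"
        )
    if not free and exponent <= 0:
        raise InvalidInputError(f"fixed exponent must be > 0, got {exponent}")

    ratio = np.array([r.size_ratio for r in records])
    e_mod = np.array([r.cell.youngs_modulus for r in records])
    pc = np.array([r.critical_pressure for r in records])
    x = np.log(ratio)
    y = np.log(pc) - np.log(e_mod)  # log(Pc/E) = log c + n log(a/g)

    if free and np.ptp(x) < 1e-12:
        raise UnidentifiableModelError(
            "all records share a single a/g ratio; the exponent is not "
            "identifiable — fix it or vary the geometry"
        )

    if objective == "log":
        if free:
            n_hat, logc_hat = np.polyfit(x, y, 1)
        else:
            n_hat = float(exponent)
            logc_hat = float(np.mean(y - n_hat * x))
        model = PowerLawModel(coefficient=float(np.exp(logc_hat)), exponent=float(n_hat))
    elif objective == "nls":

        def resid(theta):
            c, n = theta
            return c * e_mod * ratio**n - pc

        starts = (
            [np.array([np.exp(np.mean(y - n0 * x)), n0]) for n0 in (1.0, 2.0, 3.0)]
            if free
            else [np.array([np.exp(np.mean(y - exponent * x)), float(exponent)])]
        )
        best = None
        for th0 in starts:
            if free:
                res = optimize.least_squares(
                    resid,
                    th0,
                    bounds=([1e-12, EXPONENT_RANGE[0]], [np.inf, EXPONENT_RANGE[1]]),
                )
            else:
                res = optimize.least_squares(
                    lambda th: resid([th[0], exponent]),
                    th0[:1],
                    bounds=([1e-12], [np.inf]),
                )
            if best is None or res.cost < best.cost:
                best = res
        c_hat = float(best.x[0])
        n_hat = float(best.x[1]) if free else float(exponent)
        model = PowerLawModel(coefficient=c_hat, exponent=n_hat)
    else:
        raise InvalidInputError(f"unknown objective {objective!r}")

    return _diagnostics(records, model, n_params, "free" if free else "fixed")


def compare_model_orders(
    records: Sequence[SweepRecord], exponents: Iterable[float] = (1, 2, 3)
) -> list[FitResult]:
    """Fit fixed-exponent power laws and rank them.

    Returns the fits sorted by R^2 (pressure scale) descending; on ties the
    lower exponent wins (parsimony).  On data generated exactly by one of
    the candidate exponents, that model fits with R^2 = 1 and ranks first.
    """
    fits = [fit_power_law(records, exponent=n) for n in exponents]
    return sorted(fits, key=lambda f: (-round(f.r_squared, 12), f.model.exponent))


def validate_against(
    model: PowerLawModel,
    cell: CellSpec,
    observations: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Score the model against measured (gap um, critical pressure Pa) pairs.

    Returns ``(r_squared, pearson_r)`` where r_squared is the coefficient of
    determination of observed against predicted values (identity line, not a
    refit) and pearson_r is the Pearson correlation between them.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise InvalidInputError("observations must be (gap, pressure) pairs")
    gaps, measured = obs[:, 0], obs[:, 1]
    if len(np.unique(gaps)) < 3:
        raise InsufficientDataError("need at least 3 observations with distinct gaps")
    predicted = np.array(
        [
            predict_critical_pressure(model, cell, TrapGeometry(gap=g))
            for g in gaps
        ]
    )
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedCorrelationError(
            "observations are constant; correlation is undefined"
        )
    ss_res = float(np.sum((measured - predicted) ** 2))
    r_squared = 1.0 - ss_res / ss_tot
    pearson_r = float(stats.pearsonr(measured, predicted).statistic)
    return float(r_squared), pearson_r


# ---------------------------------------------------------------------------
# dataset / report I/O

SWEEP_COLUMNS = ["E_pa", "nu", "diameter_um", "gap_um", "pc_pa"]


def write_sweep_csv(records: Sequence[SweepRecord], path: str | Path, header: str | None = None) -> None:
    """Write sweep records with columns E_pa, nu, diameter_um, gap_um, pc_pa."""
    df = pd.DataFrame(
        {
            "E_pa": [r.cell.youngs_modulus for r in records],
            "nu": [r.cell.poisson_ratio for r in records],
            "diameter_um": [r.cell.diameter for r in records],
            "gap_um": [r.geometry.gap for r in records],
            "pc_pa": [r.critical_pressure for r in records],
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_sweep_csv(path: str | Path, geometry_defaults: TrapGeometry | None = None) -> list[SweepRecord]:
    """Read sweep records; pillar dimensions not stored in the CSV are taken
    from ``geometry_defaults`` (package defaults if omitted)."""
    df = pd.read_csv(path, comment="#")
    missing = set(SWEEP_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"sweep CSV missing columns: {sorted(missing)}")
    base = geometry_defaults or TrapGeometry(gap=8.0)
    out = []
    for row in df.itertuples(index=False):
        cell = CellSpec(
            diameter=row.diameter_um, youngs_modulus=row.E_pa, poisson_ratio=row.nu
        )
        geom = TrapGeometry(
            gap=row.gap_um,
            diagonal_major=base.diagonal_major,
            diagonal_minor=base.diagonal_minor,
            height=base.height,
            fillet_radius=base.fillet_radius,
        )
        out.append(SweepRecord(cell=cell, geometry=geom, critical_pressure=row.pc_pa))
    return out


def write_fit_report(fit: FitResult, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a fit as JSON (coefficient, exponent, r_squared, se, n_points)."""
    payload = {
        "coefficient": fit.model.coefficient,
        "exponent": fit.model.exponent,
        "r_squared": fit.r_squared,
        "se": fit.standard_error,
        "se_log": fit.log_standard_error,
        "n_points": fit.n_points,
        "exponent_mode": fit.exponent_mode,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
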