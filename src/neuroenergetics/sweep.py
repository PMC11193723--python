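"""Substrate phase diagrams and glucose-fitness thresholds.

Sweeps the kinetic model over grids of extracellular glucose and lactate
at a named energy-demand level, records steady glucose influx, signed
lactate flux and cytosolic ATP per grid cell, classifies cells against
the 1 mM ATP energy-deficit criterion, and locates the minimal glucose
concentration sustaining fitness by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    DemandSpec,
    ExternalConditions,
    MetabolicState,
    ModelParameters,
    SteadyStateError,
    demand_level,
    steady_state,
)

__all__ = [
    "SweepGrid", "PhaseMap", "ThresholdResult",
    "run_sweep", "classify_deficit", "glucose_threshold",
    "phase_map_to_csv", "plot_phase_map",
]

#: The observed operational criterion for neuronal energy deficit:
#: steady-state cytosolic ATP below 1 mM.
ATP_DEFICIT_MM = 1.0

DEFAULT_AXIS_MM = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class SweepGrid:
    """Glucose x lactate grid (mM, ascending) and the demand levels swept."""

    glc_values: tuple = DEFAULT_AXIS_MM
    lac_values: tuple = DEFAULT_AXIS_MM
    demand_levels: tuple = ("low", "intermediate", "high")

    def __post_init__(self) -> None:
        for name, vals in (("glc_values", self.glc_values),
                           ("lac_values", self.lac_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs at least 2 points")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        for lvl in self.demand_levels:
            if lvl not in ("low", "intermediate", "high"):
                raise ValueError(f"unknown demand level {lvl!r}")


@dataclass
class PhaseMap:
    """Gridded steady-state outputs at one demand level.

    Matrices are indexed [i_glc, j_lac]; non-converged cells are NaN with
    converged_map False.
    """

    grid: SweepGrid
    demand: str
    j_glc_map: np.ndarray
    j_lac_map: np.ndarray
    atp_map: np.ndarray
    converged_map: np.ndarray


def run_sweep(grid: SweepGrid, params: ModelParameters,
              level: Literal["low", "intermediate", "high"], *,
              warm_start: bool = True,
              max_fail_fraction: float = 0.2) -> PhaseMap:
    """One steady-state solve per (glucose, lactate) cell.

    Cells reuse the previous solution along the glucose axis as a warm
    start (the converged result is warm-start independent; see tests).
    Per-cell non-convergence is recorded in converged_map; the sweep
    aborts only if more than ``max_fail_fraction`` of cells fail.
    """
    demand = demand_level(level, params)
    ng, nl = len(grid.glc_values), len(grid.lac_values)
    j_glc = np.full((ng, nl), np.nan)
    j_lac = np.full((ng, nl), np.nan)
    atp = np.full((ng, nl), np.nan)
    ok = np.zeros((ng, nl), dtype=bool)

    n_fail = 0
    for j, lac in enumerate(grid.lac_values):
        prev: MetabolicState | None = None
        for i, glc in enumerate(grid.glc_values):
            cond = ExternalConditions(glc_ext=float(glc), lac_ext=float(lac))
            try:
                init = prev if (warm_start and prev is not None) else "energized"
                state, flux = steady_state(params, cond, demand, initial=init)
            except SteadyStateError:
                n_fail += 1
                prev = None
                if n_fail > max_fail_fraction * ng * nl:
                    raise
                continue
            prev = state
            j_glc[i, j] = flux.j_glc
            j_lac[i, j] = flux.j_lac
            atp[i, j] = state.atp_cyt
            ok[i, j] = True

    return PhaseMap(grid=grid, demand=level, j_glc_map=j_glc,
                    j_lac_map=j_lac, atp_map=atp, converged_map=ok)


def classify_deficit(pmap: PhaseMap, atp_min: float = ATP_DEFICIT_MM,
                     ) -> np.ndarray:
    """True where steady cytosolic ATP fell below the deficit criterion.

    Non-converged cells are False (they carry no numeric value).
    """
    with np.errstate(invalid="ignore"):
        return (pmap.atp_map < atp_min) & pmap.converged_map


@dataclass(frozen=True)
class ThresholdResult:
    """Minimal glucose sustaining energy fitness at fixed lactate."""

    demand: str
    lac_ext: float
    glc_star: float
    bracket: tuple
    achieved_tol: float
    degenerate: bool = False


def _fit_at(glc: float, lac: float, params: ModelParameters,
            demand: DemandSpec, atp_min: float) -> bool:
    cond = ExternalConditions(glc_ext=glc, lac_ext=lac)
    state, _ = steady_state(params, cond, demand)
    return state.atp_cyt >= atp_min


def glucose_threshold(level: Literal["low", "intermediate", "high"],
                      lac_ext: float, params: ModelParameters,
                      tol: float = 0.01, *,
                      glc_hi: float = 5.0,
                      atp_min: float = ATP_DEFICIT_MM) -> ThresholdResult:
    """Bisect extracellular glucose for the fitness boundary.

    Assumes (and exploits) that steady ATP is monotone in glucose; the
    bracket endpoints are verified.  If the neuron is already fit at zero
    glucose the threshold is 0 with a degenerate flag; if it is unfit even
    at ``glc_hi`` the result is degenerate with glc_star = glc_hi.
    """
    demand = demand_level(level, params)
    fit_lo = _fit_at(0.0, lac_ext, params, demand, atp_min)
    if fit_lo:
        return ThresholdResult(level, lac_ext, 0.0, (0.0, 0.0), tol,
                               degenerate=True)
    fit_hi = _fit_at(glc_hi, lac_ext, params, demand, atp_min)
    if not fit_hi:
        return ThresholdResult(level, lac_ext, glc_hi, (glc_hi, glc_hi), tol,
                               degenerate=True)

    lo, hi = 0.0, glc_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fit_at(mid, lac_ext, params, demand, atp_min):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(level, lac_ext, 0.5 * (lo + hi), (lo, hi),
                           hi - lo)


def phase_map_to_csv(pmaps: Sequence[PhaseMap], path,
                     atp_min: float = ATP_DEFICIT_MM) -> pd.DataFrame:
    """Long-format table (glc, lac, demand, j_glc, j_lac, atp, converged,
    deficit); written to ``path`` if given."""
    rows = []
    for pm in pmaps:
        deficit = classify_deficit(pm, atp_min)
        for i, glc in enumerate(pm.grid.glc_values):
            for j, lac in enumerate(pm.grid.lac_values):
                rows.append({
                    "glc": glc, "lac": lac, "demand": pm.demand,
                    "j_glc": pm.j_glc_map[i, j], "j_lac": pm.j_lac_map[i, j],
                    "atp": pm.atp_map[i, j],
                    "converged": bool(pm.converged_map[i, j]),
                    "deficit": bool(deficit[i, j]),
                })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def plot_phase_map(pmap: PhaseMap, quantity: str = "atp", path=None,
                   atp_min: float = ATP_DEFICIT_MM):
    """Render one phase-diagram panel as a heatmap.

    quantity: "atp", "j_glc", "j_lac" or "deficit".  Returns the
    matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = {
        "atp": (pmap.atp_map, "steady ATP (mM)", "viridis"),
        "j_glc": (pmap.j_glc_map, "glucose influx (mM/s)", "magma"),
        "j_lac": (pmap.j_lac_map,
                  "lactate flux (mM/s; <0 uptake)", "coolwarm"),
        "deficit": (classify_deficit(pmap, atp_min).astype(float),
                    f"energy deficit (ATP < {atp_min} mM)", "Reds"),
    }
    if quantity not in data:
        raise ValueError(f"unknown quantity {quantity!r}")
    matrix, label, cmap = data[quantity]

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pmap.grid.lac_values, pmap.grid.glc_values, matrix,
                       shading="nearest", cmap=cmap)
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("extracellular lactate (mM)")
    ax.set_ylabel("extracellular glucose (mM)")
    ax.set_title(f"{pmap.demand} energy demand")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
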