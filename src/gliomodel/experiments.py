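"""Parameter studies on synthetic tissue: onset of malignancy and maps.

Reproduces the model's experiment designs on the shipped synthetic
scenarios: a Gaussian tumour seed, solution difference maps between
parameter settings, and the estimation of the malignancy-onset time
``tau_OSM`` — the first instant at which the low-grade-glioma density
exceeds a critical fraction of the carrying capacity (default 0.6 K_M),
used as a proxy for the low-grade to high-grade transition — swept over
the turning-rate parameters lambda0, lambda1 and the stochastic velocity
amplitude sigma.

Time is exposed in days here (the solver works in seconds); parameters are
SI throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .macro_pde import (
    MacroCoefficients,
    MacroSolution,
    build_coefficients,
    solve,
)
from .pdifmp import DAY, ModelParams
from .tensor_fields import (
    DiffusionTensorField,
    TissueEnvironment,
    environment_from_field,
    make_brain_slice_field,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "NOT_REACHED",
    "brain_slice_scenario",
    "initial_condition",
    "tau_osm",
    "parameter_sweep",
    "difference_map",
    "default_sweep_values",
]

#: Sentinel for sweeps whose density never crosses the threshold.
NOT_REACHED = float("nan")

#: Default sweep grids for the onset-time studies.
default_sweep_values = {
    "lambda1": [-5.0, -1.0, -0.1, -0.01, 0.0, 0.01, 0.1, 0.8, 1.0, 5.0],
    "sigma": [0.01, 0.02, 0.05, 0.1, 0.15, 0.2],
    "lambda0": [0.25, 0.5, 0.8, 1.0, 5.0],
}


def brain_slice_scenario(
    shape: Tuple[int, int] = (96, 96),
    spacing: float = 0.5,
    seed: int = 0,
) -> Tuple[DiffusionTensorField, TissueEnvironment]:
    """The shipped brain-slice-like synthetic scenario (field + tissue)."""
    field = make_brain_slice_field(shape=shape, spacing=spacing, seed=seed)
    return field, environment_from_field(field)


def initial_condition(
    coeffs: MacroCoefficients,
    center: Tuple[float, float] = (-35.0, -41.0),
    width: float = 8.0,
    peak: Optional[float] = None,
) -> np.ndarray:
    """Gaussian-like tumour seed M0 = peak * exp(-((x-x0)^2+(y-y0)^2)/width).

    ``center`` is in mm and must lie inside the mask; ``width`` (mm^2) is
    the exponential denominator; the default peak is 0.1 K_M, low enough
    that reaching the malignancy threshold is growth-limited.  The field is
    radially symmetric about the centre and zero outside the mask.
    """
    if peak is None:
        peak = 0.1 * coeffs.K_M
    ny, nx = coeffs.shape
    x = coeffs.origin[0] + coeffs.spacing[0] * np.arange(nx)
    y = coeffs.origin[1] + coeffs.spacing[1] * np.arange(ny)
    X, Y = np.meshgrid(x, y)
    ix = int(round((center[0] - coeffs.origin[0]) / coeffs.spacing[0]))
    iy = int(round((center[1] - coeffs.origin[1]) / coeffs.spacing[1]))
    if not (0 <= ix < nx and 0 <= iy < ny) or not coeffs.mask[iy, ix]:
        raise ValueError(f"initial-condition centre {center} is outside the mask")
    M0 = peak * np.exp(-(((X - center[0]) ** 2 + (Y - center[1]) ** 2) / width))
    M0[~coeffs.mask] = 0.0
    return M0


def tau_osm(
    solution: MacroSolution,
    M_crit: float,
    reduce: str = "max",
) -> float:
    """Malignancy-onset time in days: first crossing of M_crit.

    The density is reduced over masked nodes per time step (``max`` — the
    first location to cross — or ``mean``), and the crossing instant is
    linearly interpolated between the bracketing steps.  Returns
    :data:`NOT_REACHED` (NaN) if the threshold is never exceeded.
    """
    if reduce == "max":
        series = solution.max_series
    elif reduce == "mean":
        area_mask = solution.mask.sum()
        series = np.array([M[solution.mask].sum() / area_mask for M in solution.M])
        # mean reduction only available at saved snapshots
        t = solution.times
        above = series > M_crit
        if not above.any():
            return NOT_REACHED
        i = int(np.argmax(above))
        if i == 0:
            return 0.0
        f = (M_crit - series[i - 1]) / (series[i] - series[i - 1])
        return float((t[i - 1] + f * (t[i] - t[i - 1])) / DAY)
    else:
        raise ValueError("reduce must be 'max' or 'mean'")
    t = solution.step_times
    above = series > M_crit
    if not above.any():
        return NOT_REACHED
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    f = (M_crit - series[i - 1]) / (series[i] - series[i - 1])
    return float((t[i - 1] + f * (t[i] - t[i - 1])) / DAY)


@dataclass
class SweepSpec:
    """One-parameter-at-a-time onset-time sweep.

    ``parameter`` is one of ``lambda0``, ``lambda1``, ``sigma``; ``values``
    must be non-empty and sorted.  ``baseline`` holds every other parameter
    fixed (the shipped studies use lambda0 = lambda1 = 0.8 and sigma = 0 for
    the turning-rate sweeps, and vary sigma at lambda0 = lambda1 = 0.8).
    ``m_crit_fraction`` is the onset threshold as a fraction of K_M.
    """

    parameter: str
    values: Sequence[float]
    baseline: ModelParams = dc_field(default_factory=ModelParams)
    field: Optional[DiffusionTensorField] = None
    env: Optional[TissueEnvironment] = None
    t_end_days: float = 1500.0
    dt_days: float = 1.0
    m_crit_fraction: float = 0.6
    ic_center: Tuple[float, float] = (-35.0, -41.0)
    ic_peak_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.parameter not in ("lambda0", "lambda1", "sigma"):
            raise ValueError("parameter must be lambda0, lambda1 or sigma")
        vals = list(self.values)
        if not vals or sorted(vals) != vals:
            raise ValueError("values must be non-empty and sorted ascending")
        if not 0 < self.m_crit_fraction < 1:
            raise ValueError("m_crit_fraction must lie in (0, 1)")


@dataclass
class SweepResult:
    """Onset times per parameter value, as a tidy table."""

    parameter: str
    table: pd.DataFrame

    def tau_values(self) -> np.ndarray:
        return self.table["tau_osm_days"].to_numpy()

    def tau_range(self) -> float:
        """Spread of the onset time over the sweep (NaN-aware)."""
        tau = self.tau_values()
        tau = tau[np.isfinite(tau)]
        if tau.size == 0:
            return float("nan")
        return float(tau.max() - tau.min())


def _run_one(
    params: ModelParams,
    field: DiffusionTensorField,
    env: TissueEnvironment,
    spec: SweepSpec,
) -> Tuple[float, float]:
    coeffs = build_coefficients(field, env, params)
    M0 = initial_condition(
        coeffs, center=spec.ic_center, peak=spec.ic_peak_fraction * params.K_M
    )
    m_crit = spec.m_crit_fraction * params.K_M
    sol = solve(
        M0,
        t_end=spec.t_end_days * DAY,
        dt=spec.dt_days * DAY,
        coeffs=coeffs,
        save_every=max(int(round(spec.t_end_days / spec.dt_days)) // 4, 1),
        stop_when_max_exceeds=m_crit,
    )
    return tau_osm(sol, m_crit), float(sol.mass_series[-1])


def parameter_sweep(spec: SweepSpec) -> SweepResult:
    """Run the onset-time study over ``spec.values`` (all else fixed).

    Each value re-derives the macroscopic coefficients (lambda0 rescales
    D_T, lambda1 the haptotaxis, sigma the isotropic addition), solves the
    macroscopic equation from the shared seed, and records tau_OSM.  The
    table has one row per value, with a
    NaN onset where the threshold is never reached.  Identical specs give
    identical tables (the scenario generator is seeded; the solver is
    deterministic).
    """
    field = spec.field
    env = spec.env
    if field is None or env is None:
        field, env = brain_slice_scenario()
    rows = []
    for v in spec.values:
        params = replace(spec.baseline, **{spec.parameter: v}, strict_turning=False)
        try:
            tau, final_mass = _run_one(params, field, env, spec)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"sweep failed at {spec.parameter} = {v!r}: {exc}"
            ) from exc
        rows.append(
            {
                "parameter": spec.parameter,
                "value": v,
                "tau_osm_days": tau,
                "reached": np.isfinite(tau),
                "final_mass": final_mass,
            }
        )
    return SweepResult(parameter=spec.parameter, table=pd.DataFrame(rows))


def difference_map(
    solution_a: MacroSolution, solution_b: MacroSolution, t_days: float
) -> np.ndarray:
    """Pointwise difference M_a(t) - M_b(t) at a shared saved instant."""
    Ma = solution_a.at_time(t_days)
    Mb = solution_b.at_time(t_days)
    if Ma.shape != Mb.shape:
        raise ValueError("solutions are not co-registered")
    return Ma - Mb
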