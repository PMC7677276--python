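"""PK metric extraction, parameter sensitivity sweeps, and ointment fitting.

``pk_metrics`` reduces a simulated concentration profile to Cmax / Tmax /
AUC (linear trapezoid on the output grid, no extrapolation).  ``psa_sweep``
reruns a scenario across values of one ointment parameter.  ``fit_ointment``
estimates ointment parameters (Higuchi constant, application time and/or
application surface area) from observed aqueous-humor concentrations by
bounded least squares on log-transformed parameters with Latin-hypercube
multi-starts, so the "manual optimization" workflow becomes reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .engine import ProfileSet, simulate
from .scenario import Scenario

__all__ = [
    "PKMetrics",
    "PSAEntry",
    "PSAResult",
    "FitResult",
    "pk_metrics",
    "psa_sweep",
    "fit_ointment",
    "OINTMENT_PARAMETERS",
    "DEFAULT_FIT_BOUNDS",
]

OINTMENT_PARAMETERS = ("application_surface_area", "application_time", "higuchi_constant")

#: default (lower, upper) fit bounds, in the parameter's native units
DEFAULT_FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "higuchi_constant": (1e-8, 1e-3),     # mg/(s^1/2 cm^2)
    "application_time": (0.25, 24.0),     # h
    "application_surface_area": (0.1, 5.0),  # cm^2
}


@dataclass(frozen=True)
class PKMetrics:
    """Cmax (mg/mL), Tmax (h), AUC up to the last sample (mg*h/mL)."""

    cmax: float
    tmax_h: float
    auc: float
    t_last_h: float


@dataclass(frozen=True)
class PSAEntry:
    value: float
    metrics: PKMetrics
    profile: ProfileSet
    is_baseline: bool = False


@dataclass(frozen=True)
class PSAResult:
    parameter: str
    compartment: str
    entries: tuple[PSAEntry, ...]

    def frame(self) -> pd.DataFrame:
        """Tidy metric table: one row per swept value."""
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "value": [e.value for e in self.entries],
                "cmax_mg_per_mL": [e.metrics.cmax for e in self.entries],
                "tmax_h": [e.metrics.tmax_h for e in self.entries],
                "auc_mg_h_per_mL": [e.metrics.auc for e in self.entries],
                "is_baseline": [e.is_baseline for e in self.entries],
            }
        )


@dataclass(frozen=True)
class FitResult:
    """Bounded least-squares estimate of ointment parameters."""

    parameters: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    objective: float                  # weighted residual sum of squares
    converged: bool
    residuals: np.ndarray             # weighted, one per observation
    message: str
    n_starts: int
    start_objectives: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "objective": self.objective,
            "converged": self.converged,
            "residuals": self.residuals.tolist(),
            "message": self.message,
            "n_starts": self.n_starts,
            "start_objectives": list(self.start_objectives),
        }


def pk_metrics(profile: ProfileSet, compartment: str) -> PKMetrics:
    """Cmax/Tmax from the sampled maximum; AUC by linear trapezoid.

    Ties in Cmax are broken by the earliest time.  Requires at least two
    time points; raises ``KeyError`` for an unknown compartment.
    """
    if compartment not in profile.concentrations:
        raise KeyError(
            f"unknown compartment {compartment!r}; "
            f"available: {sorted(profile.concentrations)}"
        )
    t = np.asarray(profile.times_h, dtype=float)
    c = np.asarray(profile.concentrations[compartment], dtype=float)
    if t.size < 2:
        raise ValueError("pk_metrics requires at least 2 time points")
    imax = int(np.argmax(c))  # argmax returns the first occurrence
    return PKMetrics(
        cmax=float(c[imax]),
        tmax_h=float(t[imax]),
        auc=float(np.trapezoid(c, t)),
        t_last_h=float(t[-1]),
    )


def _set_parameter(scenario: Scenario, parameter: str, value: float) -> Scenario:
    """Return a copy of the scenario with one scalar parameter replaced."""
    s = copy.deepcopy(scenario)
    if hasattr(s.formulation, parameter) and parameter != "variant":
        setattr(s.formulation, parameter, value)
    elif hasattr(s.physiology, parameter):
        setattr(s.physiology, parameter, value)
    elif hasattr(s.drug, parameter):
        setattr(s.drug, parameter, value)
    else:
        raise KeyError(f"unknown scalar scenario parameter {parameter!r}")
    return s


def _current_value(scenario: Scenario, parameter: str) -> float:
    for block in (scenario.formulation, scenario.physiology, scenario.drug):
        if hasattr(block, parameter):
            return float(getattr(block, parameter))
    raise KeyError(f"unknown scalar scenario parameter {parameter!r}")


def psa_sweep(
    scenario: Scenario,
    parameter: str,
    values: Sequence[float],
    compartment: str = "aqueous_humor",
) -> PSAResult:
    """One-at-a-time sensitivity sweep of a scalar scenario parameter.

    Runs one simulation per value plus the baseline (the scenario's current
    value, flagged), returning profiles and PK metrics for each.
    """
    if len(values) == 0:
        raise ValueError("psa_sweep requires a non-empty value list")
    baseline_value = _current_value(scenario, parameter)
    entries = []
    for v in values:
        prof = simulate(_set_parameter(scenario, parameter, float(v)))
        entries.append(PSAEntry(float(v), pk_metrics(prof, compartment), prof))
    base_prof = simulate(scenario)
    entries.append(
        PSAEntry(baseline_value, pk_metrics(base_prof, compartment), base_prof, True)
    )
    return PSAResult(parameter=parameter, compartment=compartment, entries=tuple(entries))


def _weights(y: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones_like(y)
    guard = np.where(y > 0, y, np.max(y) if np.max(y) > 0 else 1.0)
    if weighting == "1/y":
        return 1.0 / guard
    if weighting == "1/y^2":
        return 1.0 / guard**2
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_ointment(
    observed: pd.DataFrame,
    scenario: Scenario,
    free_params: Sequence[str] = ("higuchi_constant", "application_time"),
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    weighting: str = "1/y",
    compartment: str = "aqueous_humor",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit ointment parameters to observed concentration data.

    Parameters
    ----------
    observed : DataFrame
        Columns ``time_h``, ``concentration``, ``compartment`` (optional
        ``weight`` is not consumed here; use ``weighting``).
    scenario : Scenario
        Ointment scenario providing everything that is not fitted.
    free_params : subset of {"higuchi_constant", "application_time",
        "application_surface_area"}
    bounds : dict, optional
        Per-parameter (lower, upper) in native units; defaults from
        :data:`DEFAULT_FIT_BOUNDS`.
    weighting : {"uniform", "1/y", "1/y^2"}
        Residual weights; ``1/y`` (concentration-proportional error) is the
        PK convention and the default.
    n_starts : int
        Latin-hypercube multi-starts in log-parameter space (seeded), so the
        result is deterministic for a given seed.

    Returns
    -------
    FitResult
        Best parameters, weighted RSS, convergence flag and residuals.
        Non-convergence is reported via ``converged=False`` with the best
        point found, never silently as success.
    """
    free_params = tuple(free_params)
    for p in free_params:
        if p not in OINTMENT_PARAMETERS:
            raise ValueError(f"cannot fit parameter {p!r}")
    if scenario.formulation.variant != "ointment":
        raise ValueError("fit_ointment requires an ointment scenario")

    if "compartment" in observed.columns:
        obs = observed[observed["compartment"] == compartment]
    else:
        obs = observed
    obs = obs.sort_values("time_h")
    t_obs = obs["time_h"].to_numpy(dtype=float)
    y_obs = obs["concentration"].to_numpy(dtype=float)
    if t_obs.size < 3:
        raise ValueError("fit_ointment requires at least 3 observations")
    if np.all(y_obs == 0):
        raise ValueError("no information in data: all observed concentrations are zero")

    bnds = dict(DEFAULT_FIT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.log10([bnds[p][0] for p in free_params])
    hi = np.log10([bnds[p][1] for p in free_params])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite, positive and ordered")

    # simulate on a grid containing every observation time
    base = copy.deepcopy(scenario)
    duration = max(base.settings.duration, float(np.max(t_obs)))
    grid = np.union1d(np.linspace(0.0, duration, 121), t_obs)
    base.settings = base.settings.model_copy(
        update={"duration": duration, "output_grid": grid.tolist()}
    )
    w = _weights(y_obs, weighting)

    def residuals(x_log: np.ndarray) -> np.ndarray:
        s = base
        for p, xv in zip(free_params, 10.0**x_log):
            s = _set_parameter(s, p, float(xv))
        prof = simulate(s)
        pred = np.interp(t_obs, prof.times_h, prof.concentrations[compartment])
        return w * (pred - y_obs)

    sampler = qmc.LatinHypercube(d=len(free_params), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)

    best = None
    start_objs = []
    for x0 in starts:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
        )
        start_objs.append(float(res.cost * 2))  # cost is 0.5 * RSS
        if best is None or res.cost < best.cost:
            best = res

    params = {p: float(10.0**x) for p, x in zip(free_params, best.x)}
    return FitResult(
        parameters=params,
        bounds={p: bnds[p] for p in free_params},
        objective=float(2 * best.cost),
        converged=bool(best.success),
        residuals=np.asarray(best.fun),
        message=str(best.message),
        n_starts=n_starts,
        start_objectives=tuple(start_objs),
    )
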