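"""Synthetic observed datasets and randomized scenarios.

In vivo aqueous-humor profiles for the published case studies were
digitized from third-party figures and are not shipped; this module
generates synthetic "observed" datasets with known ground-truth
parameters by simulating a scenario and applying multiplicative
log-normal noise, and randomized-but-physiological scenarios for
property testing.  All randomness flows through a single seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import simulate
from .presets import preset
from .scenario import Scenario

__all__ = ["ObservedDataset", "generate_synthetic_observed", "random_scenario"]


@dataclass(frozen=True)
class ObservedDataset:
    """Observed concentration records with provenance tag."""

    frame: pd.DataFrame  # columns: time_h, compartment, concentration, replicate
    provenance: str      # "synthetic" | "user"

    def __post_init__(self):
        df = self.frame
        if (df["time_h"] < 0).any():
            raise ValueError("observation times must be non-negative")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        for _, sub in df.groupby("replicate"):
            if not sub["time_h"].is_monotonic_increasing:
                raise ValueError("times must be sorted within each replicate")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "user") -> "ObservedDataset":
        df = pd.read_csv(path)
        if "replicate" not in df.columns:
            df["replicate"] = 0
        if "compartment" not in df.columns:
            df["compartment"] = "aqueous_humor"
        return cls(frame=df.sort_values(["replicate", "time_h"]).reset_index(drop=True),
                   provenance=provenance)


def generate_synthetic_observed(
    scenario: Scenario,
    compartment: str,
    sample_times_h: Sequence[float],
    noise_cv: float,
    n_replicates: int = 1,
    seed: int = 0,
) -> ObservedDataset:
    """Simulate a scenario and sample it with multiplicative noise.

    Noise is log-normal with unit mean and coefficient of variation
    ``noise_cv`` per observation (``sigma^2 = ln(1 + cv^2)``), so
    ``noise_cv = 0`` reproduces the simulation exactly and the same seed
    always yields the same dataset.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(sorted(sample_times_h), dtype=float)
    if times.size == 0:
        raise ValueError("sample_times_h must be non-empty")
    if times[-1] > scenario.settings.duration + 1e-12:
        raise ValueError("sample time beyond simulation duration")

    s = scenario.model_copy(deep=True)
    grid = np.union1d(np.linspace(0.0, s.settings.duration, 121), times)
    s.settings = s.settings.model_copy(update={"output_grid": grid.tolist()})
    prof = simulate(s)
    truth = np.interp(times, prof.times_h, prof.concentrations[compartment])

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.size)
        else:
            factors = np.ones_like(times)
        rows.append(
            pd.DataFrame(
                {
                    "time_h": times,
                    "compartment": compartment,
                    "concentration": truth * factors,
                    "replicate": rep,
                }
            )
        )
    return ObservedDataset(frame=pd.concat(rows, ignore_index=True), provenance="synthetic")


def random_scenario(seed: int | np.random.Generator = 0, variant: str | None = None) -> Scenario:
    """A randomized but physiological scenario for property testing.

    Starts from the fluorometholone preset and perturbs every transfer
    parameter log-normally (geometric SD ~1.3), draws a random dose form,
    dose strength and volume.  Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if variant is None:
        variant = rng.choice(["solution", "suspension", "ointment"])

    s = preset("flm_table1", variant=variant, dose_ug=50.0)

    def jitter(x: float) -> float:
        return float(x * rng.lognormal(0.0, 0.25))

    phys = s.physiology
    for name in type(phys).model_fields:
        if name.startswith(("perm_", "sar_")) or name in ("tear_flow", "gut_absorption_rate"):
            setattr(phys, name, jitter(getattr(phys, name)))

    form = s.formulation
    form.dose_concentration = jitter(form.dose_concentration)
    form.instilled_volume = float(rng.uniform(20.0, 60.0))
    if variant == "suspension":
        form.particle_radius = float(rng.uniform(1.0, 12.0))
    if variant == "ointment":
        form.application_time = float(rng.uniform(1.0, 8.0))
        form.higuchi_constant = jitter(form.higuchi_constant)
        form.application_surface_area = float(rng.uniform(0.4, 1.763))

    s.settings = s.settings.model_copy(update={"duration": 24.0})
    return s
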