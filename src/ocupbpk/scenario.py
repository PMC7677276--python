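"""Typed parameter sets for ocular PBPK scenarios.

A *scenario* bundles four blocks:

``DrugProperties``
    physicochemistry and systemic disposition of one active ingredient,
``OcularPhysiology``
    rabbit eye anatomy and transfer parameters (permeabilities, systemic
    absorption rates, tear dynamics, tissue volumes),
``Formulation``
    the administered dose form — solution, suspension or ointment,
``SimulationSettings``
    integration horizon, output grid and solver tolerances.

All fields are entered in the customary units of ocular PK tables
(uL/min tear flow, min^-1 drainage, L/h clearance, h application time ...)
and converted once, by :func:`validate_scenario` / :meth:`Scenario.compiled`,
onto the internal mg / mL / cm / s system used by the ODE engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import units

__all__ = [
    "DrugProperties",
    "OcularPhysiology",
    "Formulation",
    "SimulationSettings",
    "Scenario",
    "CompiledScenario",
    "ScenarioError",
    "validate_scenario",
    "load_scenario",
    "save_scenario",
]

#: ocular tissues that carry a distribution volume (mL)
TISSUES = (
    "cornea_epithelium",
    "cornea_stroma",
    "aqueous_humor",
    "iris_ciliary_body",
    "conjunctiva",
    "sclera",
    "choroid",
    "retina",
    "vitreous_humor",
)

#: tissues with a direct first-order systemic absorption route
SAR_TISSUES = ("choroid", "retina", "conjunctiva", "iris_ciliary_body")

# Rabbit tissue volumes are not published alongside the transfer parameters;
# these are standard rabbit anatomy figures, each overridable per scenario.
DEFAULT_TISSUE_VOLUMES_ML: dict[str, float] = {
    "cornea_epithelium": 0.015,
    "cornea_stroma": 0.055,
    "aqueous_humor": 0.31,
    "iris_ciliary_body": 0.06,
    "conjunctiva": 0.2,
    "sclera": 0.18,
    "choroid": 0.065,
    "retina": 0.05,
    "vitreous_humor": 1.5,
}


class ScenarioError(ValueError):
    """A scenario violates a type invariant; the message names the field."""


class _Base(BaseModel):
    model_config = ConfigDict(
        extra="forbid", validate_assignment=True, revalidate_instances="always"
    )


class DrugProperties(_Base):
    """Physicochemical and systemic-disposition constants for one API."""

    molecular_weight: float = Field(gt=0, description="g/mol")
    logP: float = Field(description="octanol/water log partition coefficient")
    fraction_unbound_plasma: float = Field(gt=0, le=1, description="fraction")
    blood_to_plasma_ratio: float = Field(gt=0, description="dimensionless")
    aqueous_solubility: float = Field(gt=0, description="mg/mL")
    systemic_clearance: float = Field(gt=0, description="L/h")
    central_volume: float = Field(gt=0, description="L/kg")
    body_weight: float = Field(default=2.5, gt=0, description="kg")
    #: diffusion coefficient of the API in the ointment base (cm^2/s); only
    #: needed for the closed-form Higuchi-constant estimate
    diffusion_coeff_in_base: Optional[float] = Field(default=None, gt=0)
    #: true density of suspended drug particles (g/mL)
    particle_density: float = Field(default=1.2, gt=0)
    #: diffusion coefficient of dissolved API in tear fluid (cm^2/s), used by
    #: the particle dissolution model — a different medium from the base
    aqueous_diffusion_coeff: float = Field(default=5e-6, gt=0)


class OcularPhysiology(_Base):
    """Rabbit ocular transfer parameters, tear dynamics and anatomy.

    Permeabilities are membrane permeabilities in cm/s; systemic absorption
    rates (SAR) are first-order rate constants (s^-1) on tissue amount,
    draining into the central compartment.
    """

    perm_cornea_epithelium: float = Field(gt=0, description="cm/s")
    perm_cornea_stroma: float = Field(gt=0, description="cm/s")
    perm_conjunctiva: float = Field(gt=0, description="cm/s")
    perm_aqueous_humor: float = Field(gt=0, description="cm/s")
    perm_iris_ciliary_body: float = Field(gt=0, description="cm/s")
    perm_sclera: float = Field(gt=0, description="cm/s")
    perm_choroid: float = Field(gt=0, description="cm/s")
    perm_retina: float = Field(gt=0, description="cm/s")
    perm_vitreous_humor: float = Field(gt=0, description="cm/s")

    sar_choroid: float = Field(gt=0, description="s^-1")
    sar_retina: float = Field(gt=0, description="s^-1")
    sar_conjunctiva: float = Field(gt=0, description="s^-1")
    sar_iris_ciliary_body: float = Field(gt=0, description="s^-1")

    tear_flow: float = Field(gt=0, description="uL/min")
    drainage_rate: float = Field(gt=0, description="min^-1")
    max_precorneal_volume: float = Field(gt=0, description="uL")
    baseline_tear_volume: float = Field(default=7.5, gt=0, description="uL")
    cornea_surface_area: float = Field(default=1.763, gt=0, description="cm^2")

    #: per-tissue distribution volumes (mL); missing keys take defaults
    tissue_volumes: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TISSUE_VOLUMES_ML)
    )
    #: per-interface exchange areas (cm^2), keyed "donor:receiver"; the
    #: tear->cornea->AH chain defaults to the cornea surface area, all other
    #: interfaces to 1.0 cm^2
    exchange_areas: dict[str, float] = Field(default_factory=dict)

    gut_absorption_rate: float = Field(default=1.0, gt=0, description="h^-1")

    @model_validator(mode="after")
    def _check(self) -> "OcularPhysiology":
        if not self.baseline_tear_volume < self.max_precorneal_volume:
            raise ValueError(
                "baseline_tear_volume must be smaller than max_precorneal_volume"
            )
        for key, vol in self.tissue_volumes.items():
            if key not in TISSUES:
                raise ValueError(f"tissue_volumes: unknown tissue {key!r}")
            if vol <= 0:
                raise ValueError(f"tissue_volumes[{key!r}] must be positive")
        for key, area in self.exchange_areas.items():
            if area <= 0:
                raise ValueError(f"exchange_areas[{key!r}] must be positive")
        return self


class Formulation(_Base):
    """Administered dose form: solution, suspension or ointment.

    Ointments carry the three release parameters — application surface area
    (cm^2), application time (h, the duration over which the base is cleared
    from the ocular surface) and the Higuchi release constant
    (mg s^-1/2 cm^-2).  Suspensions carry a monodisperse particle radius.
    """

    variant: Literal["solution", "suspension", "ointment"]
    dose_concentration: float = Field(gt=0, description="mg/mL")
    instilled_volume: float = Field(description="uL")
    particle_radius: Optional[float] = Field(default=None, gt=0, description="um")
    application_surface_area: Optional[float] = Field(default=None, gt=0, description="cm^2")
    application_time: Optional[float] = Field(default=None, gt=0, description="h")
    higuchi_constant: Optional[float] = Field(default=None, gt=0, description="mg/(s^1/2 cm^2)")

    @model_validator(mode="after")
    def _check(self) -> "Formulation":
        if self.instilled_volume <= 0:
            raise ValueError("dose must be positive: instilled_volume <= 0")
        if self.variant == "suspension" and self.particle_radius is None:
            raise ValueError("particle_radius is required for a suspension formulation")
        if self.variant == "ointment":
            for name in ("application_surface_area", "application_time", "higuchi_constant"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} is required for an ointment formulation")
        return self

    @property
    def dose_mg(self) -> float:
        """Total administered dose in mg."""
        return self.dose_concentration * units.to_internal(self.instilled_volume, "uL->mL")


class SimulationSettings(_Base):
    """Integration horizon, output grid and solver tolerances."""

    duration: float = Field(default=24.0, gt=0, description="h")
    #: strictly increasing output times in hours, starting at 0; ``None``
    #: selects a uniform grid with 0.05 h spacing
    output_grid: Optional[list[float]] = None
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-12, gt=0, description="mg")
    #: singularity guard for the t^(-1/2) release rate (seconds)
    release_time_floor: float = Field(default=0.1, gt=0, description="s")

    @model_validator(mode="after")
    def _check(self) -> "SimulationSettings":
        if self.output_grid is not None:
            grid = np.asarray(self.output_grid, dtype=float)
            if grid.size < 2 or grid[0] != 0.0:
                raise ValueError("output_grid must start at 0 and have >= 2 points")
            if not np.all(np.diff(grid) > 0):
                raise ValueError("output_grid must be strictly increasing")
            if grid[-1] > self.duration + 1e-12:
                raise ValueError("output_grid extends beyond duration")
        return self

    def grid_h(self) -> np.ndarray:
        if self.output_grid is not None:
            return np.asarray(self.output_grid, dtype=float)
        n = int(round(self.duration / 0.05)) + 1
        return np.linspace(0.0, self.duration, n)


class Scenario(_Base):
    """A validated simulation scenario (drug + physiology + dose form)."""

    drug: DrugProperties
    physiology: OcularPhysiology
    formulation: Formulation
    settings: SimulationSettings = Field(default_factory=SimulationSettings)

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.formulation.variant in ("suspension", "ointment"):
            # solubility is always >0 by DrugProperties, but keep the message
            # explicit for dissolution-limited dose forms
            if self.drug.aqueous_solubility <= 0:
                raise ValueError(
                    "aqueous_solubility must be positive for suspension/ointment"
                )
        return self

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls.model_validate(data)

    def compiled(self) -> "CompiledScenario":
        return compile_scenario(self)


@dataclass(frozen=True)
class CompiledScenario:
    """A scenario normalized to internal units (mg / mL / cm / s).

    This is what the ODE engine consumes; construct via
    :meth:`Scenario.compiled` or :func:`validate_scenario`.
    """

    scenario: Scenario

    variant: str
    dose_mg: float
    dose_concentration: float            # mg/mL
    instilled_volume_ml: float

    solubility: float                    # mg/mL

    # tear dynamics
    v_tear_ml: float
    v_max_ml: float
    tear_flow_ml_s: float
    drainage_per_s: float

    # membrane transfer
    perms: dict[str, float]              # cm/s, keyed by tissue
    sars: dict[str, float]               # s^-1
    volumes_ml: dict[str, float]         # incl. "tears"
    cornea_sa_cm2: float
    exchange_areas: dict[str, float]     # keyed "donor:receiver"

    # systemic
    cl_ml_s: float
    vc_ml: float
    k_gut_per_s: float

    # formulation
    app_sa_cm2: float = 0.0
    app_time_s: float = 0.0
    k_higuchi: float = 0.0
    particle_radius_cm: float = 0.0
    particle_density_mg_ml: float = 0.0
    d_aq: float = 0.0

    # solver
    duration_s: float = 0.0
    grid_s: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    rtol: float = 1e-8
    atol: float = 1e-12
    release_floor_s: float = 0.1


#: interfaces on the reconstructed compartment topology:
#: (donor, receiver, permeability key, area key).  Anterior route
#: tears -> cornea epithelium -> stroma -> aqueous humor; conjunctival/
#: scleral route tears -> conjunctiva -> sclera -> choroid -> retina ->
#: vitreous; AH exchanges with the iris-ciliary body and the vitreous.
DEFAULT_INTERFACES: tuple[tuple[str, str, str, str], ...] = (
    ("tears", "cornea_epithelium", "cornea_epithelium", "cornea"),
    ("cornea_epithelium", "cornea_stroma", "cornea_stroma", "cornea"),
    ("cornea_stroma", "aqueous_humor", "aqueous_humor", "cornea"),
    ("aqueous_humor", "iris_ciliary_body", "iris_ciliary_body", "default"),
    ("tears", "conjunctiva", "conjunctiva", "default"),
    ("conjunctiva", "sclera", "sclera", "default"),
    ("sclera", "choroid", "choroid", "default"),
    ("choroid", "retina", "retina", "default"),
    ("retina", "vitreous_humor", "vitreous_humor", "default"),
    ("vitreous_humor", "aqueous_humor", "vitreous_humor", "default"),
)


def compile_scenario(scenario: Scenario) -> CompiledScenario:
    """Normalize a validated scenario onto internal units."""
    d, p, f, s = scenario.drug, scenario.physiology, scenario.formulation, scenario.settings

    volumes = dict(DEFAULT_TISSUE_VOLUMES_ML)
    volumes.update(p.tissue_volumes)
    volumes["tears"] = units.to_internal(p.baseline_tear_volume, "uL->mL")

    areas: dict[str, float] = {}
    for donor, receiver, _, area_kind in DEFAULT_INTERFACES:
        key = f"{donor}:{receiver}"
        default = p.cornea_surface_area if area_kind == "cornea" else 1.0
        areas[key] = p.exchange_areas.get(key, default)

    kwargs: dict = {}
    if f.variant == "ointment":
        app_time_s = units.to_internal(f.application_time, "h->s")
        kwargs.update(
            app_sa_cm2=f.application_surface_area,
            app_time_s=app_time_s,
            k_higuchi=f.higuchi_constant,
        )
    elif f.variant == "suspension":
        kwargs.update(
            particle_radius_cm=units.to_internal(f.particle_radius, "um->cm"),
            particle_density_mg_ml=units.to_internal(d.particle_density, "g/mL->mg/mL"),
            d_aq=d.aqueous_diffusion_coeff,
        )

    grid_s = units.to_internal(s.grid_h(), "h->s")

    return CompiledScenario(
        scenario=scenario,
        variant=f.variant,
        dose_mg=f.dose_mg,
        dose_concentration=f.dose_concentration,
        instilled_volume_ml=units.to_internal(f.instilled_volume, "uL->mL"),
        solubility=d.aqueous_solubility,
        v_tear_ml=volumes["tears"],
        v_max_ml=units.to_internal(p.max_precorneal_volume, "uL->mL"),
        tear_flow_ml_s=units.to_internal(p.tear_flow, "uL/min->mL/s"),
        drainage_per_s=units.to_internal(p.drainage_rate, "1/min->1/s"),
        perms={t: getattr(p, f"perm_{t}") for t in TISSUES},
        sars={t: getattr(p, f"sar_{t}") for t in SAR_TISSUES},
        volumes_ml=volumes,
        cornea_sa_cm2=p.cornea_surface_area,
        exchange_areas=areas,
        cl_ml_s=units.to_internal(d.systemic_clearance, "L/h->mL/s"),
        vc_ml=units.to_internal(d.central_volume * d.body_weight, "L->mL"),
        k_gut_per_s=units.to_internal(p.gut_absorption_rate, "1/h->1/s"),
        duration_s=units.to_internal(s.duration, "h->s"),
        grid_s=grid_s,
        rtol=s.rtol,
        atol=s.atol,
        release_floor_s=s.release_time_floor,
        **kwargs,
    )


def validate_scenario(
    drug: DrugProperties,
    physio: OcularPhysiology,
    form: Formulation,
    settings: Optional[SimulationSettings] = None,
) -> Scenario:
    """Assemble and validate a scenario from its four blocks.

    Raises :class:`ScenarioError` (a ``ValueError``) with a message naming
    the offending field on any invariant violation.
    """
    try:
        return Scenario(
            drug=drug,
            physiology=physio,
            formulation=form,
            settings=settings or SimulationSettings(),
        )
    except ValueError as exc:  # includes pydantic ValidationError
        raise ScenarioError(str(exc)) from exc


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a JSON or YAML file (by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        return Scenario.from_dict(data)
    except ValueError as exc:
        raise ScenarioError(str(exc)) from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario to JSON or YAML (by suffix)."""
    path = Path(path)
    data = scenario.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
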