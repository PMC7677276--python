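"""Dosage-form source-term kinetics.

Pure functions implementing the formulation physics that feed the
pre-corneal tear compartment:

* ointment release by the Higuchi square-root-of-time law,
  ``dm_free/dt = SA * kH * t**(-1/2)``, with the matching closed-form
  cumulative ``2 * SA * kH * sqrt(t)``;
* zero-order clearance of the ointment base from the ocular surface at
  ``dose / application_time``;
* the closed-form estimate of the Higuchi constant from ointment-base
  properties, ``sqrt(2 * C_ini * D * C_s)``;
* solubility-capped splitting of a suspension dose into dissolved and
  suspended mass;
* Lu–Frisella–Johnson (LFJ) dissolution of monodisperse suspended
  particles;
* instantaneous pre-corneal overflow of instilled liquid doses.

All functions operate in internal units (mg, mL, cm, s) unless a parameter
is documented otherwise.
"""

from __future__ import annotations

import math

__all__ = [
    "k_ointment",
    "higuchi_release_rate",
    "higuchi_cumulative",
    "siepmann_khiguchi",
    "split_suspension_dose",
    "lfj_dissolution_rate",
    "overflow_retained_fraction",
]

#: diffusion-layer thickness cap for particle dissolution (cm) — 30 um
LFJ_MAX_BOUNDARY_LAYER_CM = 30e-4


def k_ointment(dose: float, application_time: float) -> float:
    """Zero-order ointment removal rate, mg/s.

    The ointment base is cleared from the ocular surface (blinking plus
    nasolacrimal transport) over a user-set *application time*; the removal
    rate is simply ``dose / application_time``.

    Parameters
    ----------
    dose : float
        Total dose in the applied ointment, mg.
    application_time : float
        Duration over which the base is cleared, s.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if application_time <= 0:
        raise ValueError("application_time must be positive")
    return dose / application_time


def higuchi_release_rate(
    t: float,
    surface_area: float,
    k_higuchi: float,
    unreleased_mass: float,
    *,
    time_floor: float = 0.1,
) -> float:
    """Instantaneous Higuchi release rate ``SA * kH * t**(-1/2)``, mg/s.

    The rate is singular at ``t = 0``; ``t`` is clamped to ``time_floor``
    (seconds) so the ODE right-hand side stays finite.  Once the unreleased
    reservoir is exhausted the rate is zero.
    """
    if surface_area < 0:
        raise ValueError("surface_area must be non-negative")
    if k_higuchi < 0:
        raise ValueError("k_higuchi must be non-negative")
    if t < 0:
        raise ValueError("t must be non-negative")
    if unreleased_mass <= 0:
        return 0.0
    return surface_area * k_higuchi / math.sqrt(max(t, time_floor))


def higuchi_cumulative(t: float, surface_area: float, k_higuchi: float) -> float:
    """Closed-form cumulative Higuchi release ``2 * SA * kH * sqrt(t)``, mg.

    This is the exact integral of :func:`higuchi_release_rate` from an
    unbounded reservoir; against a finite reservoir the caller caps it at
    the dose.
    """
    if surface_area < 0 or k_higuchi < 0 or t < 0:
        raise ValueError("t, surface_area and k_higuchi must be non-negative")
    return 2.0 * surface_area * k_higuchi * math.sqrt(t)


def siepmann_khiguchi(c_ini: float, diffusion_coeff: float, c_s: float) -> float:
    """Closed-form Higuchi-constant estimate ``sqrt(2 * C_ini * D * C_s)``.

    Parameters
    ----------
    c_ini : float
        Initial API concentration in the ointment base, mg/mL.
    diffusion_coeff : float
        API diffusion coefficient in the base, cm^2/s.
    c_s : float
        API solubility in the base, mg/mL.

    Returns
    -------
    float
        Estimated Higuchi constant, mg s^-1/2 cm^-2.
    """
    if c_ini < 0 or diffusion_coeff < 0 or c_s < 0:
        raise ValueError("all inputs must be non-negative")
    return math.sqrt(2.0 * c_ini * diffusion_coeff * c_s)


def split_suspension_dose(
    dose_concentration: float, volume: float, solubility: float
) -> tuple[float, float]:
    """Split a suspension dose into (dissolved, suspended) mass, mg.

    The dissolved fraction is capped at saturation of the instilled volume:
    ``dissolved = min(total, solubility * volume)``.

    Parameters
    ----------
    dose_concentration : float
        Label strength, mg/mL.
    volume : float
        Instilled volume, mL.
    solubility : float
        Aqueous solubility, mg/mL.
    """
    if dose_concentration < 0 or volume < 0 or solubility < 0:
        raise ValueError("all inputs must be non-negative")
    total = dose_concentration * volume
    dissolved = min(total, solubility * volume)
    return dissolved, total - dissolved


def lfj_dissolution_rate(
    suspended_mass: float,
    initial_mass: float,
    initial_radius_um: float,
    d_aq: float,
    density_g_ml: float,
    c_s: float,
    c_bulk: float,
    v_fluid: float | None = None,
) -> float:
    """Lu–Frisella–Johnson dissolution rate of monodisperse particles, mg/s.

    Returns the (non-negative) mass-transfer rate from suspended particles
    into solution; the suspended-mass balance is ``dm/dt = -rate``:

    ``rate = (3 D / (rho h r0)) * m0**(1/3) * m**(2/3) * (C_s - C_bulk)``

    with diffusion-layer thickness ``h`` equal to the current particle
    radius ``r0 * (m/m0)**(1/3)``, capped at 30 um.  The rate is zero when
    nothing is suspended or the bulk is at saturation.

    Parameters
    ----------
    suspended_mass, initial_mass : float
        Current and initial suspended mass, mg.
    initial_radius_um : float
        Initial (monodisperse) particle radius, um.
    d_aq : float
        API diffusion coefficient in tear fluid, cm^2/s.
    density_g_ml : float
        Particle true density, g/mL.
    c_s, c_bulk : float
        Solubility and bulk dissolved concentration, mg/mL.
    v_fluid : float, optional
        Dissolution-medium volume, mL.  Accepted for interface completeness;
        saturation is handled through ``c_bulk`` by the caller.
    """
    if initial_radius_um <= 0:
        raise ValueError("initial_radius_um must be positive")
    if density_g_ml <= 0:
        raise ValueError("density_g_ml must be positive")
    if suspended_mass <= 0 or initial_mass <= 0 or c_bulk >= c_s:
        return 0.0
    m = min(suspended_mass, initial_mass)
    r0_cm = initial_radius_um * 1e-4
    density_mg_ml = density_g_ml * 1e3
    radius_cm = r0_cm * (m / initial_mass) ** (1.0 / 3.0)
    h_cm = min(radius_cm, LFJ_MAX_BOUNDARY_LAYER_CM)
    return (
        3.0 * d_aq / (density_mg_ml * h_cm * r0_cm)
        * initial_mass ** (1.0 / 3.0)
        * m ** (2.0 / 3.0)
        * (c_s - c_bulk)
    )


def overflow_retained_fraction(
    instilled_volume: float,
    baseline_tear_volume: float,
    max_precorneal_volume: float,
    *,
    variant: str = "solution",
) -> float:
    """Fraction of an instilled dose retained after pre-corneal overflow.

    The tear sac holds at most ``max_precorneal_volume``; any instilled
    liquid beyond that spills immediately.  Ointments adhere to the ocular
    surface and are exempt (fraction 1).  Volumes in uL (or any consistent
    unit).
    """
    if instilled_volume <= 0 or baseline_tear_volume <= 0 or max_precorneal_volume <= 0:
        raise ValueError("volumes must be positive")
    if baseline_tear_volume >= max_precorneal_volume:
        raise ValueError("baseline_tear_volume must be below max_precorneal_volume")
    if variant == "ointment":
        return 1.0
    retained_volume = min(instilled_volume + baseline_tear_volume, max_precorneal_volume)
    # guard float round-off when nothing overflows
    return min(1.0, (retained_volume - baseline_tear_volume) / instilled_volume)
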