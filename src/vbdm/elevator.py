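"""Order-of-magnitude habitability chain for a sub-ice biosphere.

Desk calculations that bracket the plausibility of an upward, lysis-driven
DOM supply ("viral elevator") on an icy ocean world:

* diffusion timescale of DOM through a stagnant freshwater layer,
* viral infection rate from an observed daily lysed fraction,
* specific viral decay rate from areal sediment decay measurements,
* benthic biomass synthesis rate from the seafloor reductant (H2) flux,
* the elevator flux required to sustain a sub-ice biofilm of given
  global-equivalent-layer (GEL) thickness, and the resulting feasibility
  map over biomass rate and biofilm depth.

All functions are pure arithmetic on scalars or numpy arrays; units are
stated per function and converted at this boundary only (the dynamical
model in :mod:`vbdm.model` works exclusively in hours and per-mL units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElevatorScenario",
    "diffusion_timescale",
    "infection_rate",
    "viral_decay_rate",
    "benthic_biomass_rate",
    "required_elevator_flux",
    "feasibility_map",
    "convective_depth_limit",
]

#: Julian year, seconds.
YEAR_S = 3.1557e7
#: Hours per year used in the biomass-to-flux conversion.
YEAR_HR = 8760.0
HOURS_PER_DAY = 24.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class ElevatorScenario:
    """Inputs of the habitability chain with literature-based defaults.

    Defaults describe a Europa-like scenario: DOM diffusivity typical of
    organic solutes in cold water, the freshwater-layer thickness bounds
    of stratified-ocean models, Arctic/deep-sea virology observations, a
    serpentinization-scale H2 flux with aerobic respiration energetics,
    and Europa's radius.
    """

    C_diff: float = 0.5e-9            # DOM diffusivity, m^2 s^-1
    layer_thickness_min: float = 107.0    # freshwater layer, m
    layer_thickness_max: float = 8000.0   # freshwater layer, m
    L_B: float = 0.07                 # fraction of bacteria lysed, d^-1
    V_C: float = 2e7                  # viral concentration, cells mL^-1
    sediment_decay: float = 5.26e12   # areal viral decay, cells m^-2 d^-1
    sediment_abundance: float = 1.5e9 # viral abundance, cells g^-1
    sample_depth_cm: float = 1.0
    sample_field_cm3: float = 1e4
    sediment_density: float = 1.0     # g cm^-3 (assumed)
    r_flux: float = 1e10              # reductant (H2) flux, mol yr^-1
    G_free: float = 237.13            # Gibbs free energy H2+O2, kJ mol^-1
    c_anabolic: float = 1.0 / 4.1868  # anabolic conversion, g kJ^-1
    b_m: float = 1e-15                # bacterial cell mass, kg
    dom_per_cell: float = 6e-8        # DOM per cell, ug cell^-1
    r_body: float = 1.5e6             # body (Europa) radius, m
    convection_timescale_yr: tuple[float, float] = (1e3, 1e5)


def diffusion_timescale(layer_thickness: float, C_diff: float) -> float:
    """Diffusion timescale ``d^2 / C`` through a stagnant layer, years.

    Parameters
    ----------
    layer_thickness
        Layer thickness, m.
    C_diff
        Diffusion constant, m^2 s^-1.
    """
    if layer_thickness < 0:
        raise ValueError("layer_thickness must be >= 0")
    _require_positive(C_diff=C_diff)
    return layer_thickness**2 / C_diff / YEAR_S


def convective_depth_limit(scn: ElevatorScenario) -> float:
    """Layer thickness (m) whose diffusion time equals the slow end of the
    ice-convection timescale.

    A freshwater 'lid' thinner than this still passes DOM by diffusion on
    the same timescale as ice convection; thicker lids bottleneck the
    elevator.  Computed self-consistently from ``C_diff`` and the upper
    convection timescale rather than quoted.
    """
    tau_s = scn.convection_timescale_yr[1] * YEAR_S
    return float(np.sqrt(tau_s * scn.C_diff))


def infection_rate(L_B: float, V_C: float) -> float:
    """Adsorption/infection rate phi = (L_B / 24) / V_C, mL cell^-1 hr^-1.

    ``L_B`` is the fraction of the bacterial stock lysed per day and
    ``V_C`` the ambient viral concentration (cells mL^-1): the per-virus
    hourly infection rate is the hourly lysed fraction spread over the
    standing viral pool.
    """
    if L_B < 0:
        raise ValueError("L_B must be >= 0")
    _require_positive(V_C=V_C)
    return (L_B / HOURS_PER_DAY) / V_C


def viral_decay_rate(
    sediment_decay: float,
    sediment_abundance: float,
    sample_depth_cm: float = 1.0,
    sample_field_cm3: float = 1e4,
    sediment_density: float = 1.0,
) -> float:
    """Specific viral decay rate m (hr^-1) from areal sediment decay data.

    The areal decay (cells m^-2 d^-1) is referred to the sediment volume
    it was measured over: a sample field of ``sample_field_cm3`` at
    ``sample_depth_cm`` depth spans ``field/depth`` cm^2 of seafloor and
    holds ``abundance * density * field`` viruses.  Dividing total decay
    by total standing stock and converting days to hours gives the
    specific rate.
    """
    _require_positive(
        sediment_decay=sediment_decay,
        sediment_abundance=sediment_abundance,
        sample_depth_cm=sample_depth_cm,
        sample_field_cm3=sample_field_cm3,
        sediment_density=sediment_density,
    )
    area_m2 = (sample_field_cm3 / sample_depth_cm) / 1e4  # cm^2 -> m^2
    decay_per_day = sediment_decay * area_m2              # cells d^-1
    standing = sediment_abundance * sediment_density * sample_field_cm3
    return decay_per_day / standing / HOURS_PER_DAY


def benthic_biomass_rate(r_flux: float, G_free: float, c_anabolic: float) -> float:
    """Benthic biomass synthesis rate B_R = r * G * c * 1e-3, kg yr^-1.

    ``r`` is the reductant flux (mol yr^-1), ``G`` the free energy of the
    metabolic redox reaction (kJ mol^-1) and ``c`` the anabolic
    conversion (g of biomass per kJ); 1e-3 converts g to kg.
    """
    _require_positive(r_flux=r_flux, G_free=G_free, c_anabolic=c_anabolic)
    return r_flux * G_free * c_anabolic * 1e-3


def required_elevator_flux(
    B_R,
    biofilm_depth_mm,
    b_m: float = 1e-15,
    dom_per_cell: float = 6e-8,
    r_body: float = 1.5e6,
):
    """Elevator flux E needed to sustain a biofilm, ug mL^-1 hr^-1.

    The benthic biomass rate ``B_R`` (kg yr^-1) divided by the cell mass
    ``b_m`` (kg) and multiplied by the DOM content per cell (ug) gives
    the DOM production rate; dividing by 8760 converts to ug hr^-1.  The
    receiving volume is a global shell of ``biofilm_depth_mm`` over the
    body's surface, in mL.  Accepts arrays in either argument.

    E scales inversely with depth: the same flux spread through a thicker
    biofilm supports proportionally less per unit volume.
    """
    B_R = np.asarray(B_R, dtype=float)
    depth = np.asarray(biofilm_depth_mm, dtype=float)
    if np.any(B_R <= 0) or np.any(depth <= 0):
        raise ValueError("B_R and biofilm_depth_mm must be positive")
    _require_positive(b_m=b_m, dom_per_cell=dom_per_cell, r_body=r_body)
    production_ug_hr = (B_R / b_m) * dom_per_cell / YEAR_HR
    volume_ml = 4.0 * np.pi * r_body**2 * (depth * 1e-3) * 1e6
    out = production_ug_hr / volume_ml
    return float(out) if out.ndim == 0 else out


def feasibility_map(
    B_R_grid,
    depth_grid_mm,
    E_quantiles: dict[str, float],
    scn: ElevatorScenario | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Required-flux grid and supply contours over (B_R, biofilm depth).

    Parameters
    ----------
    B_R_grid, depth_grid_mm
        1-D grids of benthic biomass rate (kg yr^-1) and biofilm depth
        (mm GEL).
    E_quantiles
        Named elevator-supply levels (e.g. the ensemble's median and
        quartile averaged E), ug mL^-1 hr^-1.

    Returns
    -------
    grid
        DataFrame indexed by B_R with one column per depth, cell values =
        the elevator flux delivered per unit biofilm volume.  A cell is
        *feasible* at demand level q iff its delivered flux >= q: the
        same benthic production spread through a thicker shell dilutes
        below the per-volume supply a steady ecosystem needs, so
        infeasibility propagates toward larger depths.
    contours
        For each quantile, the curve ``depth(B_R)`` along which delivered
        flux equals the demand — the thickest sustainable biofilm at each
        B_R.  Exact inversion of the E ∝ 1/depth law, not interpolation.
    """
    if not E_quantiles:
        raise ValueError("at least one E quantile is required")
    scn = scn or ElevatorScenario()
    B_R_grid = np.asarray(B_R_grid, dtype=float)
    depth_grid_mm = np.asarray(depth_grid_mm, dtype=float)
    req = required_elevator_flux(
        B_R_grid[:, None], depth_grid_mm[None, :],
        b_m=scn.b_m, dom_per_cell=scn.dom_per_cell, r_body=scn.r_body,
    )
    grid = pd.DataFrame(req, index=B_R_grid, columns=depth_grid_mm)
    grid.index.name = "B_R_kg_per_yr"
    grid.columns.name = "depth_mm"

    contours: dict[str, pd.DataFrame] = {}
    # E = k * B_R / depth with k independent of both; invert for depth.
    k = required_elevator_flux(
        1.0, 1.0, b_m=scn.b_m, dom_per_cell=scn.dom_per_cell, r_body=scn.r_body
    )
    for name, q in E_quantiles.items():
        if not q > 0:
            raise ValueError(f"E quantile {name!r} must be positive, got {q}")
        contours[name] = pd.DataFrame(
            {"B_R_kg_per_yr": B_R_grid, "depth_mm": k * B_R_grid / q}
        )
    return grid, contours


def feasible_region(grid: pd.DataFrame, demand: float) -> pd.DataFrame:
    """Boolean feasibility mask: delivered flux meets the demand level."""
    if not demand > 0:
        raise ValueError(f"demand must be positive, got {demand}")
    return grid >= demand
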