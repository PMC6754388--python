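"""Global extrapolation arithmetic: mat areal rates to planetary fluxes.

Scales a measured areal rate (mmol m⁻² d⁻¹) to global annual fluxes under
user-stated land-coverage scenarios, evaluates cellular-carbon stocks and
division budgets, and converts net C production to nutrient export via C:N
stoichiometry.  Everything here is exact linear arithmetic on user inputs —
the module makes no claim about actual Precambrian land area or climate.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import units

#: Earth surface area [km²]
EARTH_SURFACE_KM2 = 5.10e8

#: late Archean land surface area used for the scenarios [km²]
ARCHEAN_LAND_KM2 = 2.5e7


@dataclass(frozen=True)
class CoverageScenario:
    """Land area [km²], mat coverage fraction and areal rate [mmol m⁻² d⁻¹]."""

    land_area: float = ARCHEAN_LAND_KM2
    coverage_fraction: float = 0.05
    areal_rate: float = 38.0
    label: str = ""

    def __post_init__(self):
        if self.land_area <= 0:
            raise ValueError("land_area must be > 0")
        if not 0 <= self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CellCarbonBudget:
    """Cell-density and per-cell-carbon ranges for biomass bookkeeping.

    Defaults: 10⁸–10⁹ cells cm⁻³, 1–150 fg C per cell, TOC 1–12 wt% of dry
    mass at porosity 0.97 and particle density 2.65 g cm⁻³.
    """

    cell_density_min: float = 1e8       # cells cm-3
    cell_density_max: float = 1e9
    carbon_per_cell_min: float = 1.0    # fg C
    carbon_per_cell_max: float = 150.0
    toc_wt_min: float = 1.0             # wt% dry mass
    toc_wt_max: float = 12.0
    porosity: float = 0.97
    particle_density: float = 2.65      # g cm-3

    def __post_init__(self):
        for lo, hi in ((self.cell_density_min, self.cell_density_max),
                       (self.carbon_per_cell_min, self.carbon_per_cell_max),
                       (self.toc_wt_min, self.toc_wt_max)):
            if lo < 0 or lo > hi:
                raise ValueError("ranges must satisfy 0 <= min <= max")


@dataclass(frozen=True)
class OceanComparison:
    """Earth surface partition for land/ocean comparisons."""

    earth_surface_area: float = EARTH_SURFACE_KM2   # km2
    ocean_fraction: float = 0.95
    ocean_cell_total: float = 4.8e27                # cells
    ocean_divisions_per_day: float = 5e26           # d-1

    def __post_init__(self):
        if not 0 < self.ocean_fraction < 1:
            raise ValueError("ocean_fraction must be in (0, 1)")


def areal_to_annual(areal_rate: float) -> dict:
    """mmol m⁻² d⁻¹ → {mol m⁻² yr⁻¹, Mmol km⁻² yr⁻¹} (365-day year)."""
    if areal_rate < 0:
        raise ValueError("areal_rate must be >= 0")
    return {
        "mol_m2_yr": units.mmolm2d_to_molm2yr(areal_rate),
        "Mmol_km2_yr": units.mmolm2d_to_mmol_km2yr(areal_rate),
    }


def global_production(scenario: CoverageScenario) -> float:
    """Global flux [Tmol yr⁻¹] for an areal rate over covered land area."""
    mol_m2_yr = areal_to_annual(scenario.areal_rate)["mol_m2_yr"]
    area_m2 = scenario.land_area * scenario.coverage_fraction * 1e6
    return mol_m2_yr * area_m2 / 1e12


def biomass_carbon_density(budget: CellCarbonBudget) -> tuple[float, float]:
    """(min, max) cellular carbon density [g C cm⁻³ wet mat]."""
    fg_to_g = 1e-15
    return (budget.cell_density_min * budget.carbon_per_cell_min * fg_to_g,
            budget.cell_density_max * budget.carbon_per_cell_max * fg_to_g)


def toc_carbon_density(wt_percent: float, porosity: float = 0.97,
                       particle_density: float = 2.65) -> float:
    """Total organic carbon density [g C cm⁻³ wet mat] from wt% dry mass."""
    if wt_percent < 0 or not 0 < porosity < 1 or particle_density <= 0:
        raise ValueError("invalid TOC density inputs")
    return wt_percent / 100.0 * (1 - porosity) * particle_density


def biomass_fraction(budget: CellCarbonBudget) -> tuple[float, float]:
    """(min, max) cellular biomass as % of total organic carbon.

    The minimum pairs the lowest biomass density with the highest TOC
    density, the maximum the reverse.
    """
    bio_lo, bio_hi = biomass_carbon_density(budget)
    toc_lo = toc_carbon_density(budget.toc_wt_min, budget.porosity,
                                budget.particle_density)
    toc_hi = toc_carbon_density(budget.toc_wt_max, budget.porosity,
                                budget.particle_density)
    if toc_lo == 0 or toc_hi == 0:
        raise ZeroDivisionError("TOC density is zero; fraction undefined")
    return (bio_lo / toc_hi * 100.0, bio_hi / toc_lo * 100.0)


def division_budget(areal_c_rate: float, carbon_per_cell: float,
                    scenario: CoverageScenario) -> float:
    """Global cell divisions per day from an areal C-fixation rate.

    ``areal_c_rate`` [mmol C m⁻² d⁻¹] × molar mass × covered area, divided
    by the carbon content of one cell [fg].
    """
    if carbon_per_cell <= 0:
        raise ValueError("carbon_per_cell must be > 0")
    g_per_m2_d = areal_c_rate / 1e3 * units.MOLAR_MASS_C
    area_m2 = scenario.land_area * scenario.coverage_fraction * 1e6
    return g_per_m2_d * area_m2 / (carbon_per_cell * 1e-15)


def turnover_time(cell_density: float, carbon_per_cell: float,
                  layer_thickness: float, gross_c_rate: float) -> dict:
    """Cell-carbon turnover of the photosynthetic layer.

    stock [g C m⁻²] = density [cells cm⁻³] × per-cell C [fg] × thickness
    [cm]; turnover [d] = stock / (gross C rate); divisions per cell per day
    = 1/turnover.  A zero rate flags an infinite turnover.
    """
    stock_g_m2 = cell_density * carbon_per_cell * 1e-15 * layer_thickness * 1e4
    rate_g_m2_d = gross_c_rate / 1e3 * units.MOLAR_MASS_C
    if rate_g_m2_d == 0:
        return {"turnover_d": float("inf"), "divisions_per_day": 0.0,
                "infinite": True}
    t = stock_g_m2 / rate_g_m2_d
    return {"turnover_d": t, "divisions_per_day": 1.0 / t, "infinite": False}


def ocean_area(comparison: OceanComparison) -> float:
    """Ocean area [km²] = earth surface × ocean fraction."""
    return comparison.earth_surface_area * comparison.ocean_fraction


def nitrate_export(net_c_rate: float, c_to_n: float,
                   scenario: CoverageScenario) -> float:
    """Nitrogen export [Tmol N yr⁻¹] from net C production via C:N ratio."""
    if c_to_n <= 0:
        raise ValueError("c_to_n must be > 0")
    n_scenario = CoverageScenario(scenario.land_area,
                                  scenario.coverage_fraction,
                                  net_c_rate / c_to_n, scenario.label)
    return global_production(n_scenario)


def reference_flux_comparison(scenario: CoverageScenario,
                              references: dict[str, float]) -> list[dict]:
    """Compare the scenario's global flux against named reference fluxes.

    For each reference [Tmol yr⁻¹]: the ratio scenario/reference and the
    break-even coverage fraction at which the mat flux would match it.
    Zero references are skipped with a flag.
    """
    global_flux = global_production(scenario)
    annual_per_km2 = areal_to_annual(scenario.areal_rate)["mol_m2_yr"] * 1e6
    rows = []
    for name, ref in references.items():
        if ref == 0:
            rows.append({"reference": name, "value_Tmol_yr": 0.0,
                         "skipped": True})
            continue
        rows.append({
            "reference": name,
            "value_Tmol_yr": ref,
            "ratio": global_flux / ref,
            "breakeven_coverage": ref * 1e12 / (annual_per_km2
                                                * scenario.land_area),
            "skipped": False,
        })
    return rows
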