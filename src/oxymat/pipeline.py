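"""Configuration handling and the end-to-end pipeline.

``run_pipeline`` ties the stages together — synthetic input generation (or
profile loading), scenario simulations, profile flux/rate inversion, the
O₂-equivalent balance, and the global extrapolations — and emits a single
JSON-serialisable report.  Every reported number carries both its full
precision and a printed-precision rendering (2 significant figures unless
noted), the lossy rounding being confined to the report layer.
"""

from __future__ import annotations

import decimal
import hashlib
import json
import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import budget, extrapolation, inversion, synthetic, transport
from .profiles import read_profile

logger = logging.getLogger("oxymat")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Report-time rendering only; internal values stay full-precision.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exp = sig - 1 - int(math.floor(math.log10(abs(x))))
    q = decimal.Decimal(repr(x)).scaleb(exp).quantize(
        decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP)
    return float(q.scaleb(-exp))


def default_config() -> dict:
    """The packaged defaults configuration as a dict."""
    text = resources.files("oxymat").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying the packaged defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def _build_model(cfg: dict):
    k = cfg["kinetics"]
    kinetics = transport.KineticParameters(
        vmax_prod=k["vmax_prod"], km_prod=k["km_prod"],
        vmax_resp=k["vmax_resp"], km_resp=k["km_resp"],
        par_surface=k["par_surface"],
        par_attenuation_fraction=k["par_attenuation_fraction"],
        attenuation_step=k["attenuation_step_mm"])
    t = cfg["transport"]
    trans = transport.TransportParameters(porosity=t["porosity"],
                                          diffusivity=t["diffusivity_cm2s"])
    g = cfg["grid"]
    grid = transport.Grid1D.from_depth(g["depth_mm"], g["spacing_mm"])
    return kinetics, trans, grid


def _scenario_summary(res: transport.SteadyStateResult) -> dict:
    return {
        "converged": res.converged,
        "iterations": res.iterations,
        "residual_nM_s": res.residual,
        "interface_slope_uM_mm": res.interface_slope,
        "efflux_top_mmol_m2_d": res.efflux_top,
        "flux_bottom_mmol_m2_d": res.flux_bottom,
        "areal_net_production_mmol_m2_d": res.areal_net_production,
    }


def run_pipeline(config: dict | None = None, seed: int | None = None) -> dict:
    """Execute the full analysis chain and return the structured report."""
    cfg = config if config is not None else default_config()
    if seed is None:
        seed = int(cfg.get("run", {}).get("seed", 0))
    run_cfg = cfg.get("run", {})
    mode = run_cfg.get("mode", "converge")
    tolerance = float(run_cfg.get("tolerance", 1e-4))
    dt = float(run_cfg.get("dt_s", 1.0))

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
        },
        "inputs": {"config": cfg},
    }

    # --- scenario simulations ----------------------------------------------
    try:
        kinetics, trans, grid = _build_model(cfg)
        bcfg = cfg["boundary"]
        scen_results = {}
        for scen in ("oxic_day", "anoxic_day", "night"):
            scen_results[scen] = transport.simulate_scenario(
                kinetics, trans, grid, scen,
                top_oxic_um=bcfg["top_um"], bottom=bcfg["bottom"],
                mode=mode, tolerance=tolerance, dt=dt)
            logger.info("scenario %s: efflux_top %.3g mmol/m2/d", scen,
                        scen_results[scen].efflux_top)
        report["model"] = {s: _scenario_summary(r)
                           for s, r in scen_results.items()}
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- profile flux / rate inversion -------------------------------------
    try:
        prof_cfg = cfg.get("profile", {})
        if prof_cfg.get("path"):
            day_profile = read_profile(prof_cfg["path"])
        else:
            spec = synthetic.SyntheticProfileSpec(
                kinetics=kinetics, transport=trans, grid=grid,
                bc=transport.BoundaryConditions(top=bcfg["top_um"],
                                                bottom=bcfg["bottom"]),
                noise_sd=float(prof_cfg.get("noise_sd_um", 0.0)),
                seed=seed, dt=dt, tolerance=tolerance)
            day_profile = synthetic.gen_o2_profile(spec)
        flux_top = inversion.fick_flux(day_profile, trans,
                                       interface="top_atmosphere")
        rates = inversion.invert_net_rates(day_profile, trans)
        report["fluxes"] = {
            "efflux_top_mmol_m2_d": flux_top.value,
            "gradient_uM_mm": flux_top.gradient_used,
            "inverted_areal_net_mmol_m2_d": rates.areal_integral,
        }
    except Exception as exc:
        raise PipelineError("invert", str(exc)) from exc

    # --- O2-equivalent balance ---------------------------------------------
    try:
        bal = cfg["balance"]
        wtc_cfg = cfg["wtc"]
        wtc = synthetic.gen_wtc_profile(
            surface_wt=wtc_cfg["surface_wt"], deep_wt=wtc_cfg["deep_wt"],
            decay_depth=wtc_cfg["decay_depth_mm"],
            noise_sd=wtc_cfg.get("noise_sd", 0.0), seed=seed)
        om_from_profile = budget.om_accretion_rate(
            budget.AccretionInputs(wtc, thickness=bal["mat_thickness_cm"],
                                   age=bal["age_yr"]))
        om = float(bal["om_override"]) if bal.get("om_override") is not None \
            else om_from_profile
        ch4 = budget.ch4_areal_flux(budget.MethaneIncubation(
            areal_rate_dark=bal["ch4_dark"],
            mat_thickness=bal["mat_thickness_cm"],
            inhibition_factor=bal["inhibition_factor"]))
        ledger = budget.O2EquivalentLedger()
        ledger.add("OM accretion", "Corg", om, "source")
        ledger.add("CH4 efflux", "CH4", ch4, "source")
        totals = budget.to_o2_equivalents(ledger)
        gross = budget.reconcile_gross(
            {"ch4_plus_om": totals["sources"]},
            respiration=float(bal["respiration"]))
        report["balance"] = {
            "om_accretion_mmol_m2_d": om,
            "om_from_wtc_profile_mmol_m2_d": om_from_profile,
            "ch4_flux_mmol_m2_d": ch4,
            "entries": ledger.to_records(),
            "net_o2eq_mmol_m2_d": totals["sources"],
            "gross_o2eq_mmol_m2_d": gross["gross"]["ch4_plus_om"],
        }
    except Exception as exc:
        raise PipelineError("balance", str(exc)) from exc

    # --- global extrapolation ----------------------------------------------
    try:
        glb = cfg["global"]
        annual = extrapolation.areal_to_annual(float(glb["gross_rate"]))
        coverages = {}
        for cov in glb["coverages"]:
            scen = extrapolation.CoverageScenario(
                land_area=float(glb["land_area_km2"]), coverage_fraction=cov,
                areal_rate=float(glb["gross_rate"]))
            coverages[str(cov)] = extrapolation.global_production(scen)
        ocean = extrapolation.ocean_area(extrapolation.OceanComparison(
            earth_surface_area=float(glb["earth_surface_km2"]),
            ocean_fraction=float(glb["ocean_fraction"])))
        cells = cfg["cells"]
        cell_budget = extrapolation.CellCarbonBudget(
            cell_density_min=float(cells["density_min"]),
            cell_density_max=float(cells["density_max"]),
            carbon_per_cell_min=cells["c_per_cell_min"],
            carbon_per_cell_max=cells["c_per_cell_max"],
            toc_wt_min=cells["toc_wt_min"], toc_wt_max=cells["toc_wt_max"])
        bio_lo, bio_hi = extrapolation.biomass_carbon_density(cell_budget)
        frac_lo, frac_hi = extrapolation.biomass_fraction(cell_budget)
        nitrate = extrapolation.nitrate_export(
            float(glb["net_c_rate"]), float(glb["c_to_n"]),
            extrapolation.CoverageScenario(
                land_area=float(glb["land_area_km2"]),
                coverage_fraction=float(glb["nitrate_coverage"]),
                areal_rate=float(glb["net_c_rate"])))
        report["global"] = {
            "gross_mol_m2_yr": annual["mol_m2_yr"],
            "gross_Mmol_km2_yr": annual["Mmol_km2_yr"],
            "global_Tmol_yr_by_coverage": coverages,
            "ocean_area_km2": ocean,
            "biomass_density_g_cm3": {"min": bio_lo, "max": bio_hi},
            "biomass_fraction_pct": {"min": frac_lo, "max": frac_hi},
            "nitrate_export_Tmol_yr": nitrate,
        }
        refs = cfg.get("references") or {}
        if refs:
            scen = extrapolation.CoverageScenario(
                land_area=float(glb["land_area_km2"]),
                coverage_fraction=float(glb["coverages"][0]),
                areal_rate=float(glb["gross_rate"]))
            report["global"]["reference_comparison"] = \
                extrapolation.reference_flux_comparison(scen, refs)
    except Exception as exc:
        raise PipelineError("global", str(exc)) from exc

    report["printed"] = _printed_rendering(report)
    return report


def _printed_rendering(report: dict) -> dict:
    """Printed-precision (2 s.f.; 3 for the ocean area) headline numbers."""
    glb = report["global"]
    printed = {
        "gross_Mmol_km2_yr": round_sig(glb["gross_Mmol_km2_yr"], 2),
        "ocean_area_km2": round_sig(glb["ocean_area_km2"], 3),
        "biomass_density_max_g_cm3": round_sig(
            glb["biomass_density_g_cm3"]["max"], 2),
        "biomass_fraction_min_pct": round_sig(
            glb["biomass_fraction_pct"]["min"], 1),
        "biomass_fraction_max_pct": round_sig(
            glb["biomass_fraction_pct"]["max"], 2),
        "net_o2eq_mmol_m2_d": round_sig(
            report["balance"]["net_o2eq_mmol_m2_d"], 2),
    }
    for cov, val in glb["global_Tmol_yr_by_coverage"].items():
        printed[f"global_Tmol_yr_at_{cov}"] = round_sig(val, 2)
    return printed


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default)
                          + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
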