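"""Seeded synthetic-data generators emulating the field measurements.

Every generator is a pure function of its specification and seed, so the
whole pipeline can be exercised end to end without any instrument data:
O₂ microprofiles are forward model runs plus Gaussian sensor noise, wt%C
profiles decline exponentially from their surface value, and per-layer cell
counts are log-uniform draws across the observed order-of-magnitude range,
sorted to decrease with depth.  Generated artifacts carry their generating
parameters in metadata so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import DepthProfile
from .transport import (BoundaryConditions, Grid1D, KineticParameters,
                        ModelState, TransportParameters, run_to_steady_state)


@dataclass
class SyntheticProfileSpec:
    """Forward-model configuration plus sensor noise level and seed."""

    kinetics: KineticParameters = field(default_factory=KineticParameters)
    transport: TransportParameters = field(default_factory=TransportParameters)
    grid: Grid1D = field(default_factory=Grid1D)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    noise_sd: float = 2.0           # uM
    seed: int = 0
    dt: float = 1.0                 # s
    tolerance: float = 1e-4         # nM/s

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DielSchedule:
    """Clock times over 24 h and the surface PAR at each [µE m⁻² s⁻¹]."""

    times: list
    par_surface: list

    def __post_init__(self):
        if len(self.times) != len(self.par_surface):
            raise ValueError("times and par_surface must have equal length")
        if any(p < 0 for p in self.par_surface):
            raise ValueError("PAR must be >= 0")

    @classmethod
    def sinusoidal(cls, n: int = 12, peak_par: float = 1500.0,
                   sunrise: float = 6.0, sunset: float = 18.0) -> "DielSchedule":
        """Half-sine daylight PAR between sunrise and sunset, 0 at night."""
        times = list(np.linspace(0, 24, n, endpoint=False))
        par = []
        for t in times:
            if sunrise <= t <= sunset:
                par.append(peak_par * np.sin(np.pi * (t - sunrise)
                                             / (sunset - sunrise)))
            else:
                par.append(0.0)
        return cls(times, par)


def gen_o2_profile(spec: SyntheticProfileSpec) -> DepthProfile:
    """Steady-state O₂ microprofile with additive Gaussian sensor noise."""
    initial = ModelState(np.full(spec.grid.n_nodes, spec.bc.top),
                         step_size=spec.dt)
    result = run_to_steady_state(initial, spec.kinetics, spec.transport,
                                 spec.grid, spec.bc, mode="converge",
                                 tolerance=spec.tolerance)
    if not result.converged:
        raise RuntimeError("forward model did not converge; refine the spec")
    rng = np.random.default_rng(spec.seed)
    noisy = result.final_state.o2 + rng.normal(0.0, spec.noise_sd,
                                               spec.grid.n_nodes) \
        if spec.noise_sd > 0 else result.final_state.o2.copy()
    noisy = np.clip(noisy, 0.0, None)
    meta = {
        "generator": "gen_o2_profile",
        "seed": spec.seed,
        "noise_sd_uM": spec.noise_sd,
        "vmax_prod": spec.kinetics.vmax_prod,
        "vmax_resp": spec.kinetics.vmax_resp,
        "km_prod": spec.kinetics.km_prod,
        "km_resp": spec.kinetics.km_resp,
        "par_surface": spec.kinetics.par_surface,
        "top_uM": spec.bc.top,
        "bottom": spec.bc.bottom,
        "true_efflux_top": result.efflux_top,
        "true_areal_net_production": result.areal_net_production,
    }
    return DepthProfile(spec.grid.depths_mm, noisy, kind="o2_concentration",
                        metadata=meta)


def gen_diel_profiles(spec: SyntheticProfileSpec,
                      schedule: DielSchedule) -> list[DepthProfile]:
    """One steady-state profile per schedule entry, PAR overridden per time."""
    profiles = []
    for i, (t, par) in enumerate(zip(schedule.times, schedule.par_surface)):
        sub = replace(spec, kinetics=replace(spec.kinetics, par_surface=par),
                      seed=spec.seed + i)
        p = gen_o2_profile(sub)
        p.metadata["time_h"] = t
        profiles.append(p)
    return profiles


def gen_wtc_profile(surface_wt: float = 12.0, deep_wt: float = 1.0,
                    decay_depth: float = 5.0,
                    grid: Grid1D | None = None,
                    noise_sd: float = 0.0, seed: int = 0) -> DepthProfile:
    """Organic-carbon wt% profile: exponential decline from surface to depth.

    ``wt(z) = deep + (surface - deep) * exp(-z / decay_depth)`` with optional
    Gaussian noise, clipped at 0.  Defaults anchor 12 wt% at the surface
    declining to 1 wt% at depth.
    """
    if not surface_wt >= deep_wt >= 0:
        raise ValueError("need surface_wt >= deep_wt >= 0")
    if decay_depth <= 0:
        raise ValueError("decay_depth must be > 0")
    if grid is None:
        grid = Grid1D.from_depth(60.0, spacing=2.0)
    z = grid.depths_mm
    wt = deep_wt + (surface_wt - deep_wt) * np.exp(-z / decay_depth)
    if noise_sd > 0:
        wt = wt + np.random.default_rng(seed).normal(0.0, noise_sd, z.size)
    wt = np.clip(wt, 0.0, None)
    meta = {"generator": "gen_wtc_profile", "seed": seed,
            "surface_wt": surface_wt, "deep_wt": deep_wt,
            "decay_depth_mm": decay_depth, "noise_sd": noise_sd}
    return DepthProfile(z, wt, kind="organic_carbon", metadata=meta)


def gen_cell_counts(layers: list[tuple[float, float]],
                    density_range: tuple[float, float] = (1e8, 1e9),
                    seed: int = 0) -> pd.DataFrame:
    """Per-layer cell densities [cells cm⁻³], non-increasing with depth.

    Log-uniform draws within ``density_range``, sorted so the shallowest
    layer is densest.  Layers are (top, bottom) depth ranges in mm and must
    be ordered and non-overlapping.
    """
    if not layers:
        raise ValueError("need at least one layer")
    prev_bottom = -np.inf
    for top, bottom in layers:
        if bottom <= top:
            raise ValueError(f"layer ({top}, {bottom}) has bottom <= top")
        if top < prev_bottom:
            raise ValueError("layers must be ordered and non-overlapping")
        prev_bottom = bottom
    lo, hi = density_range
    if not 0 < lo <= hi:
        raise ValueError("density_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)
    draws = 10 ** rng.uniform(np.log10(lo), np.log10(hi), len(layers))
    draws = np.sort(draws)[::-1]
    return pd.DataFrame({
        "layer_top_mm": [l[0] for l in layers],
        "layer_bottom_mm": [l[1] for l in layers],
        "cells_per_cm3": draws,
    })
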