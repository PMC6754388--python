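"""Flux and rate estimation directly from measured O₂ depth profiles.

Two inverse views of a microsensor profile:

* :func:`fick_flux` — Fick's first law across an interface,
  ``J = -φ D' (δc/δx)``, with the gradient taken by least squares over a
  window of points adjacent to the interface.
* :func:`invert_net_rates` — at steady state, diffusion balances reaction, so
  the net volumetric rate is ``-φ D' d²C/dx²``: centred second differences of
  the (optionally smoothed) profile give a depth-resolved net
  production/consumption profile.  Double differentiation amplifies sensor
  noise; smooth noisy profiles before inverting.

Plus the gross-production bookkeeping: gross = daytime net + night-time
respiration (a lower limit, since respiration can slow at night).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .profiles import DepthProfile
from .transport import TransportParameters


@dataclass
class FluxEstimate:
    """Areal diffusive flux across a named interface.

    ``value`` is in mmol m⁻² d⁻¹, positive out of the mat through the
    interface.  The stored gradient [µM mm⁻¹] and window make the number
    reproducible: value = ∓ φ D' × gradient (sign per interface).
    """

    value: float
    interface: str                  # 'top_atmosphere' | 'bottom_rock'
    gradient_used: float            # [uM mm-1]
    window: int
    porosity: float
    diffusivity: float              # [cm2 s-1]


@dataclass
class NetRateProfile:
    """Depth-resolved net volumetric O₂ rate, positive = net production.

    The rates already include the porosity factor of the steady-state
    balance (``-φ D' C''``), so the areal integral is the plain trapezoidal
    integral of the rate column — it matches the difference of the Fick
    fluxes through the two interfaces.
    """

    depths: np.ndarray              # [mm]
    rates: np.ndarray               # [nM s-1]
    areal_integral: float = field(init=False)   # [mmol m-2 d-1]

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        si = np.trapezoid(units.nmps_to_molm3s(self.rates),
                          units.mm_to_m(self.depths))
        self.areal_integral = units.molm2s_to_mmolm2d(si)

    def as_profile(self) -> DepthProfile:
        return DepthProfile(self.depths, self.rates, kind="net_rate")


def fick_flux(profile: DepthProfile, transport: TransportParameters,
              interface: str = "top_atmosphere", window: int = 2) -> FluxEstimate:
    """Diffusive O₂ flux across an interface by Fick's first law.

    The concentration gradient is estimated over the ``window`` points
    nearest the interface (least squares; default 2 = two-point difference)
    and converted as ``J = -φ D' δc/δx``.  Positive values are fluxes out of
    the mat through that interface.
    """
    if profile.kind != "o2_concentration":
        raise ValueError("fick_flux requires an O2 concentration profile")
    if interface not in ("top_atmosphere", "bottom_rock"):
        raise ValueError(f"unknown interface {interface!r}")
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(profile) < window:
        raise ValueError(
            f"profile has {len(profile)} points; window {window} needs more")
    if interface == "bottom_rock":
        z, c = profile.depths[-window:], profile.values[-window:]
    else:
        z, c = profile.depths[:window], profile.values[:window]
    grad = float(np.polyfit(z, c, 1)[0])
    # grad [uM/mm] == [mol m-4]; J = -phi D' grad, positive downward (+z)
    j_si = -transport.porosity * transport.diffusivity_m2s \
        * units.umpermm_to_molm4(grad)
    # out-of-mat convention: top interface outward is -z, bottom outward is +z
    outward = -j_si if interface == "top_atmosphere" else j_si
    return FluxEstimate(
        value=units.molm2s_to_mmolm2d(outward),
        interface=interface,
        gradient_used=grad,
        window=window,
        porosity=transport.porosity,
        diffusivity=transport.diffusivity,
    )


def smooth_profile(profile: DepthProfile, window: int = 3) -> DepthProfile:
    """Centred moving-average smoothing (edges keep shorter windows)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    half = window // 2
    vals = profile.values
    out = np.empty_like(vals)
    for i in range(vals.size):
        lo, hi = max(0, i - half), min(vals.size, i + half + 1)
        out[i] = vals[lo:hi].mean()
    return DepthProfile(profile.depths, np.clip(out, 0, None)
                        if profile.kind == "o2_concentration" else out,
                        kind=profile.kind, metadata=dict(profile.metadata))


def _cubic_curvature(z, c, z0) -> float:
    """Second derivative at ``z0`` of the cubic through four (z, c) points."""
    coef = np.polyfit(z - z0, c, 3)   # highest degree first
    return 2.0 * coef[1]


def invert_net_rates(profile: DepthProfile, transport: TransportParameters,
                     smooth: bool = False,
                     smooth_window: int = 3) -> NetRateProfile:
    """Net volumetric rate profile from profile curvature.

    At steady state ``φ D' d²C/dx² + R = 0``, so the net rate (positive =
    production) is ``-φ D' d²C/dx²`` — concave-down curvature means net
    production.  Centred second differences on interior nodes; the edge
    nodes use the curvature of the cubic through their nearest four points.
    """
    if profile.kind != "o2_concentration":
        raise ValueError("invert_net_rates requires an O2 concentration profile")
    if len(profile) < 3:
        raise ValueError("inversion needs at least 3 points")
    if smooth:
        profile = smooth_profile(profile, smooth_window)
    z_m = units.mm_to_m(profile.depths)
    c_si = units.um_to_molm3(profile.values)
    d2 = np.empty_like(c_si)
    # non-uniform-grid-safe second derivative
    dz0 = z_m[1:-1] - z_m[:-2]
    dz1 = z_m[2:] - z_m[1:-1]
    d2[1:-1] = 2 * (dz0 * c_si[2:] - (dz0 + dz1) * c_si[1:-1]
                    + dz1 * c_si[:-2]) / (dz0 * dz1 * (dz0 + dz1))
    # edges: curvature of the cubic through the nearest four points
    # (second-order one-sided; falls back to the neighbour for short profiles)
    if c_si.size >= 4:
        d2[0] = _cubic_curvature(z_m[:4], c_si[:4], z_m[0])
        d2[-1] = _cubic_curvature(z_m[-4:], c_si[-4:], z_m[-1])
    else:
        d2[0] = d2[1]
        d2[-1] = d2[-2]
    rate_si = -transport.porosity * transport.diffusivity_m2s * d2
    return NetRateProfile(profile.depths, units.molm3s_to_nmps(rate_si))


def integrate_areal_rate(rates: NetRateProfile,
                         layer: tuple[float, float] | None = None) -> float:
    """Trapezoidal areal rate [mmol m⁻² d⁻¹] over a depth layer [mm].

    No porosity factor is applied: the stored rates already carry it.
    """
    z, r = rates.depths, rates.rates
    if layer is not None:
        lo, hi = layer
        if hi <= lo:
            raise ValueError("layer must satisfy lo < hi")
        if hi < z[0] or lo > z[-1]:
            raise ValueError("layer does not intersect the profile support")
        lo, hi = max(lo, z[0]), min(hi, z[-1])
        zz = np.unique(np.concatenate([[lo], z[(z > lo) & (z < hi)], [hi]]))
        rr = np.interp(zz, z, r)
        z, r = zz, rr
    si = np.trapezoid(units.nmps_to_molm3s(r), units.mm_to_m(z))
    return units.molm2s_to_mmolm2d(si)


def day_night_gross(net_day: float, resp_night: float) -> float:
    """Gross photosynthesis = daytime net production + night respiration.

    ``resp_night`` is the night-time respiration magnitude (positive
    consumption, mmol m⁻² d⁻¹).  The result is a lower limit for gross
    production because respiration can be slower at night when O₂ is low.
    """
    if resp_night < 0:
        raise ValueError("night respiration must be a positive magnitude")
    return net_day + resp_night
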