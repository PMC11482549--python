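"""Laminar flow and wall shear stress in the rectangular perfusion channel.

The perfusion channel is a shallow rectangular duct (typically 1 mm wide,
50 um high).  In the fully developed laminar limit the axial velocity
u(y, z) solves a Poisson problem over the cross-section with no-slip walls:

    mu * laplacian(u) = -G,   G = dP/dx (constant pressure gradient)

whose classical Fourier-series solution (width coordinate y in [-w/2, w/2],
height coordinate z in [0, h]) is

    u(y,z) = (4 G h^2 / (pi^3 mu)) * sum_{n odd} 1/n^3
             * [1 - cosh(n pi y / h)/cosh(n pi w / (2h))] * sin(n pi z / h)

The series is scaled so the cross-section flux equals the prescribed
volumetric flow rate Q.  Wall shear is the normal derivative of u at the
wall times mu; in the wide-channel limit the wall-centre value reduces to
the parallel-plates formula tau = 6 mu Q / (w h^2).

Units: SI internally; shear is reported in dyn/cm^2 (1 Pa = 10 dyn/cm^2)
and flow rates at the interface in uL/min, the conventions of the
organ-on-chip literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelGeometry",
    "FlowConditions",
    "VelocityField",
    "WallShearProfile",
    "mean_inlet_velocity",
    "plates_wall_shear",
    "duct_velocity_field",
    "duct_wall_shear_profile",
    "reynolds_number",
    "design_flow_rate",
    "PA_TO_DYN_CM2",
    "UL_MIN_TO_M3_S",
]

PA_TO_DYN_CM2 = 10.0
UL_MIN_TO_M3_S = 1e-9 / 60.0


class FlowError(ValueError):
    """Invalid geometry or flow inputs."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct: width, height, length in metres."""

    width_m: float
    height_m: float
    length_m: float = 15e-3
    pillar_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.width_m, self.height_m, self.length_m) <= 0:
            raise FlowError("channel dimensions must be positive")

    @property
    def aspect_ratio(self) -> float:
        return self.width_m / self.height_m

    @property
    def hydraulic_diameter_m(self) -> float:
        w, h = self.width_m, self.height_m
        return 2.0 * w * h / (w + h)


@dataclass(frozen=True)
class FlowConditions:
    """Volumetric flow rate and Newtonian fluid properties.

    Defaults are cell culture medium at 37 C: rho = 1012 kg/m^3,
    mu = 0.964 mPa s.
    """

    q_m3_s: float
    rho_kg_m3: float = 1012.0
    mu_pa_s: float = 0.964e-3

    def __post_init__(self) -> None:
        if self.q_m3_s < 0 or self.rho_kg_m3 <= 0 or self.mu_pa_s <= 0:
            raise FlowError("flow rate must be >= 0; rho, mu must be > 0")

    @classmethod
    def from_ul_min(cls, q_ul_min: float, rho_kg_m3: float = 1012.0,
                    mu_pa_s: float = 0.964e-3) -> "FlowConditions":
        return cls(q_ul_min * UL_MIN_TO_M3_S, rho_kg_m3, mu_pa_s)


@dataclass(frozen=True)
class VelocityField:
    """Axial velocity samples over the cross-section; u[i, j] = u(y[i], z[j])."""

    y_m: np.ndarray
    z_m: np.ndarray
    u_m_s: np.ndarray


@dataclass(frozen=True)
class WallShearProfile:
    """Wall shear along the bottom wall (vs y) and a side wall (vs z)."""

    y_m: np.ndarray
    bottom_dyn_cm2: np.ndarray
    z_m: np.ndarray
    side_dyn_cm2: np.ndarray


# ---------------------------------------------------------------------------
# bulk formulas
# ---------------------------------------------------------------------------

def mean_inlet_velocity(geom: ChannelGeometry, flow: FlowConditions) -> float:
    """Mean axial velocity u = Q / (w h), m/s."""
    return flow.q_m3_s / (geom.width_m * geom.height_m)


def plates_wall_shear(geom: ChannelGeometry, flow: FlowConditions) -> float:
    """Parallel-plates wall shear tau = 6 mu Q / (w h^2), dyn/cm^2.

    Valid in the wide-channel limit; a warning is raised for w/h < 5 where
    side walls visibly reduce the wall-centre shear.
    """
    if geom.aspect_ratio < 5:
        warnings.warn(
            f"aspect ratio w/h = {geom.aspect_ratio:.2f} < 5; the "
            "parallel-plates formula overestimates the wall shear",
            stacklevel=2)
    tau_pa = 6.0 * flow.mu_pa_s * flow.q_m3_s / (
        geom.width_m * geom.height_m ** 2)
    return tau_pa * PA_TO_DYN_CM2


def design_flow_rate(geom: ChannelGeometry, mu_pa_s: float,
                     target_shear_dyn_cm2: float) -> float:
    """Flow rate (uL/min) producing a target wall shear via the plates formula.

    Inverts tau = 6 mu Q / (w h^2): Q = tau w h^2 / (6 mu).
    """
    if target_shear_dyn_cm2 <= 0:
        raise FlowError("target shear must be positive")
    tau_pa = target_shear_dyn_cm2 / PA_TO_DYN_CM2
    q = tau_pa * geom.width_m * geom.height_m ** 2 / (6.0 * mu_pa_s)
    return q / UL_MIN_TO_M3_S


def reynolds_number(geom: ChannelGeometry, flow: FlowConditions,
                    characteristic_length_mode: str = "hydraulic_diameter",
                    ) -> float:
    """Re = rho u_mean l / mu with l the hydraulic diameter or the height.

    The characteristic length is an explicit mode because conventions differ
    and reported chip Reynolds numbers rarely state which was used.
    """
    u = mean_inlet_velocity(geom, flow)
    if characteristic_length_mode == "hydraulic_diameter":
        ell = geom.hydraulic_diameter_m
    elif characteristic_length_mode == "height":
        ell = geom.height_m
    else:
        raise FlowError(
            f"unknown characteristic length mode "
            f"{characteristic_length_mode!r}; use 'hydraulic_diameter' or "
            "'height'")
    return flow.rho_kg_m3 * u * ell / flow.mu_pa_s


# ---------------------------------------------------------------------------
# Fourier-series duct solution
# ---------------------------------------------------------------------------

def _series_flux_factor(w: float, h: float, n_terms: int) -> float:
    """Q / (G w h^3 / (12 mu)): the bracketed correction of the duct law."""
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    corr = np.sum(np.tanh(n * math.pi * w / (2.0 * h)) / n ** 5)
    return 1.0 - (192.0 * h / (math.pi ** 5 * w)) * corr


def _pressure_gradient(geom: ChannelGeometry, flow: FlowConditions,
                       n_terms: int = 2000) -> float:
    """G = dP/dx that carries the prescribed Q through the duct."""
    w, h = geom.width_m, geom.height_m
    factor = _series_flux_factor(w, h, n_terms)
    return 12.0 * flow.mu_pa_s * flow.q_m3_s / (w * h ** 3 * factor)


def duct_velocity_field(geom: ChannelGeometry, flow: FlowConditions,
                        resolution: int = 65, n_terms: int = 400,
                        ) -> VelocityField:
    """Fully developed axial velocity over the cross-section.

    Samples u(y, z) on a ``resolution x resolution`` grid spanning the full
    cross-section; the underlying pressure gradient is scaled so the exact
    series flux equals Q.  No-slip holds on all four walls.
    """
    if resolution < 8:
        warnings.warn("resolution < 8 points across the cross-section is "
                      "too coarse to resolve the profile", stacklevel=2)
    w, h = geom.width_m, geom.height_m
    g = _pressure_gradient(geom, flow)

    y = np.linspace(-w / 2.0, w / 2.0, resolution)
    z = np.linspace(0.0, h, resolution)
    n = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd harmonics

    b = n * math.pi * w / (2.0 * h)
    # cosh(n pi y / h) / cosh(n pi w / 2h), overflow-safe: exp(|a|-b) form
    a = np.abs(np.outer(n, y)) * math.pi / h          # (n, y)
    ratio = np.exp(a - b[:, None]) * (1.0 + np.exp(-2.0 * a)) / (
        1.0 + np.exp(-2.0 * b[:, None]))
    sin_z = np.sin(np.outer(n, z) * math.pi / h)       # (n, z)
    coef = 4.0 * g * h ** 2 / (math.pi ** 3 * flow.mu_pa_s) / n ** 3
    u = np.einsum("n,ny,nz->yz", coef, 1.0 - ratio, sin_z)
    # clamp tiny negative truncation residue at the walls
    u[np.abs(u) < 1e-30] = 0.0
    u[:, 0] = 0.0
    u[:, -1] = 0.0
    u[0, :] = 0.0
    u[-1, :] = 0.0
    return VelocityField(y_m=y, z_m=z, u_m_s=u)


def duct_wall_shear_profile(geom: ChannelGeometry, flow: FlowConditions,
                            resolution: int = 65, n_terms: int = 4000,
                            ) -> WallShearProfile:
    """Wall shear tau = mu du/dn from the analytic series derivative.

    Bottom wall (z = 0), as a function of y:
        tau(y) = (4 h G / pi^2) sum 1/n^2 [1 - cosh(n pi y/h)/cosh(n pi w/2h)]
    Side wall (y = w/2), as a function of z:
        tau(z) = (4 h G / pi^2) sum 1/n^2 tanh(n pi w/2h) sin(n pi z/h)

    Maximum at the wall centres, zero at the corners.  Reported in dyn/cm^2.
    """
    if resolution < 8:
        warnings.warn("resolution < 8 samples along the wall is too coarse",
                      stacklevel=2)
    w, h = geom.width_m, geom.height_m
    g = _pressure_gradient(geom, flow)
    pref = 4.0 * h * g / math.pi ** 2

    y = np.linspace(-w / 2.0, w / 2.0, resolution)
    z = np.linspace(0.0, h, resolution)
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    b = n * math.pi * w / (2.0 * h)

    # bottom wall: use sum(1/n^2, odd) = pi^2/8 and subtract the fast-decaying
    # cosh-ratio tail so truncation error stays negligible away from corners
    a = np.abs(np.outer(n, y)) * math.pi / h
    ratio = np.exp(a - b[:, None]) * (1.0 + np.exp(-2.0 * a)) / (
        1.0 + np.exp(-2.0 * b[:, None]))
    bottom_pa = pref * (math.pi ** 2 / 8.0 - np.einsum(
        "n,ny->y", 1.0 / n ** 2, ratio))

    sin_z = np.sin(np.outer(n, z) * math.pi / h)
    side_pa = pref * np.einsum("n,nz->z", np.tanh(b) / n ** 2, sin_z)

    bottom_pa = np.clip(bottom_pa, 0.0, None)
    side_pa = np.clip(side_pa, 0.0, None)
    bottom_pa[[0, -1]] = 0.0
    side_pa[[0, -1]] = 0.0
    return WallShearProfile(y_m=y, bottom_dyn_cm2=bottom_pa * PA_TO_DYN_CM2,
                            z_m=z, side_dyn_cm2=side_pa * PA_TO_DYN_CM2)
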