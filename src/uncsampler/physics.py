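"""Particle sizing and deposition physics.

Chain of conversions used to turn a segmented projected area into an
airborne-mass contribution:

    area A  →  d_pa = √(4A/π)                      projected-area diameter
            →  d_ve = (6 f_V/π)^{1/3} d_pa          volume-equivalent diameter
            →  d_ae :  d_ae² C_c(d_ae) ρ₀ = d_ve² C_c(d_ve) ρ_p / χ
            →  mass = ρ_p f_V d_pa³                 (ng, with unit conversion)

together with the Cunningham slip correction, the gravitational-settling /
Brownian-diffusion deposition-velocity model, and the mesh-cap collection
efficiency lookup.  All diameters are in µm, velocities in m s⁻¹, masses
in ng unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

from .config import AirState, EfficiencyCurve, SamplerConfig

__all__ = [
    "projected_area_diameter",
    "particle_mass_ng",
    "cunningham",
    "volume_equivalent_diameter",
    "aerodynamic_diameter",
    "projected_area_diameter_from_aerodynamic",
    "deposition_velocity",
    "mesh_efficiency",
]

G_M_S2 = 9.80665          # standard gravity
K_BOLTZMANN = 1.380649e-23  # J/K

# Allen & Raabe solid-particle slip constants
_SLIP_A = 1.142
_SLIP_B = 0.558
_SLIP_C = 0.999


def projected_area_diameter(area_um2):
    """Diameter of the circle with the same area as the particle image.

    d_pa = √(4·A/π), area in µm², result in µm.
    """
    area_um2 = np.asarray(area_um2, dtype=float)
    if np.any(area_um2 <= 0):
        raise ValueError("projected area must be > 0")
    return np.sqrt(4.0 * area_um2 / np.pi)


def particle_mass_ng(d_pa_um, cfg: SamplerConfig):
    """Particle mass in ng from the projected-area diameter.

    Volume convention: V = f_V · d_pa³ (µm³); mass = ρ_p · V with
    ρ_p in g cm⁻³.  1 µm³ at 1 g cm⁻³ is 1e-3 ng, hence the factor.
    """
    d_pa_um = np.asarray(d_pa_um, dtype=float)
    if np.any(d_pa_um <= 0):
        raise ValueError("d_pa must be > 0")
    volume_um3 = cfg.volume_shape_factor * d_pa_um**3
    return cfg.particle_density_g_cm3 * volume_um3 * 1e-3


def cunningham(d_um, air: AirState = AirState()):
    """Cunningham slip correction factor.

    C_c = 1 + Kn (a + b e^{−c/Kn}) with Kn = 2λ/d and the Allen–Raabe
    solid-particle constants a = 1.142, b = 0.558, c = 0.999.
    """
    d_um = np.asarray(d_um, dtype=float)
    if np.any(d_um <= 0):
        raise ValueError("diameter must be > 0")
    kn = 2.0 * air.mean_free_path_um / d_um
    return 1.0 + kn * (_SLIP_A + _SLIP_B * np.exp(-_SLIP_C / kn))


def volume_equivalent_diameter(d_pa_um, cfg: SamplerConfig):
    """d_ve = (6 f_V / π)^{1/3} · d_pa — the sphere with the particle's volume."""
    return (6.0 * cfg.volume_shape_factor / np.pi) ** (1.0 / 3.0) * np.asarray(d_pa_um, dtype=float)


def _dae_fixed_point(d_ve, cfg: SamplerConfig, rtol: float = 1e-9, max_iter: int = 200):
    """Solve d_ae² C_c(d_ae) ρ₀ = d_ve² C_c(d_ve) ρ_p/χ by damped fixed point.

    Start at the no-slip solution d_ae = d_ve √(ρ_p/(χ ρ₀)); the slip-ratio
    map is strongly contracting for d ≳ 0.1 µm, so a half-step damping is
    ample.
    """
    rho_ratio = cfg.particle_density_g_cm3 / (cfg.dynamic_shape_factor * cfg.reference_density_g_cm3)
    rhs = d_ve * np.sqrt(rho_ratio)  # no-slip start
    cc_ve = cunningham(d_ve, cfg.air)
    d_ae = rhs
    for _ in range(max_iter):
        proposal = rhs * np.sqrt(cc_ve / cunningham(d_ae, cfg.air))
        new = 0.5 * (d_ae + proposal)
        converged = np.all(np.abs(new - d_ae) <= rtol * np.abs(new))
        d_ae = new
        if converged:
            return d_ae
    raise RuntimeError(
        f"aerodynamic-diameter iteration did not converge: d_ve={d_ve!r}, last={d_ae!r}"
    )


def aerodynamic_diameter(d_pa_um, cfg: SamplerConfig):
    """Aerodynamic diameter (µm) of a particle with projected-area diameter d_pa.

    The unit-density sphere with the same settling velocity:
    d_ae² C_c(d_ae) ρ₀ = d_ve² C_c(d_ve) ρ_p / χ, solved by damped
    fixed-point iteration to 1e-6 relative tolerance.
    """
    d_pa_um = np.asarray(d_pa_um, dtype=float)
    if np.any(d_pa_um <= 0):
        raise ValueError("d_pa must be > 0")
    d_ve = volume_equivalent_diameter(d_pa_um, cfg)
    return _dae_fixed_point(d_ve, cfg)


def projected_area_diameter_from_aerodynamic(d_ae_um, cfg: SamplerConfig):
    """Invert the d_pa → d_ae chain (vectorized).

    Used by the deposition simulator to render particles whose segmented
    area maps back exactly to the requested aerodynamic diameter.  Solves
    d_ve² C_c(d_ve) ρ_p/χ = d_ae² C_c(d_ae) ρ₀ for d_ve by the same
    damped fixed-point iteration as the forward chain (the implicit
    equation is strictly monotone, so the solution is unique), then
    divides out the volume-shape scaling.
    """
    d_ae_um = np.asarray(d_ae_um, dtype=float)
    if np.any(d_ae_um <= 0):
        raise ValueError("d_ae must be > 0")
    rho_ratio = cfg.particle_density_g_cm3 / (cfg.dynamic_shape_factor * cfg.reference_density_g_cm3)
    rhs = d_ae_um / np.sqrt(rho_ratio)  # no-slip start for d_ve
    cc_ae = cunningham(d_ae_um, cfg.air)
    d_ve = rhs
    for _ in range(100):
        proposal = rhs * np.sqrt(cc_ae / cunningham(d_ve, cfg.air))
        new = 0.5 * (d_ve + proposal)
        converged = np.all(np.abs(new - d_ve) <= 1e-9 * np.abs(new))
        d_ve = new
        if converged:
            break
    else:
        raise RuntimeError(f"d_ve inversion did not converge for d_ae={d_ae_um!r}")
    d_pa = d_ve / (6.0 * cfg.volume_shape_factor / np.pi) ** (1.0 / 3.0)
    return d_pa if d_pa.ndim else float(d_pa)


def _settling_velocity(d_ae_um, cfg: SamplerConfig):
    """Stokes settling velocity of the unit-density d_ae sphere, m s⁻¹."""
    d_m = np.asarray(d_ae_um, dtype=float) * 1e-6
    rho0 = cfg.reference_density_g_cm3 * 1000.0  # kg m⁻³
    cc = cunningham(d_ae_um, cfg.air)
    return rho0 * G_M_S2 * d_m**2 * cc / (18.0 * cfg.air.viscosity_pa_s)


def _diffusive_velocity(d_ae_um, cfg: SamplerConfig):
    """Brownian deposition velocity v_d = D/δ with D from Stokes–Einstein."""
    d_m = np.asarray(d_ae_um, dtype=float) * 1e-6
    cc = cunningham(d_ae_um, cfg.air)
    diffusivity = K_BOLTZMANN * cfg.air.temperature_k * cc / (3.0 * np.pi * cfg.air.viscosity_pa_s * d_m)
    delta_m = cfg.boundary_layer_mm * 1e-3
    return diffusivity / delta_m


def deposition_velocity(d_ae_um, cfg: SamplerConfig):
    """Effective deposition velocity (m s⁻¹) for an aerodynamic diameter.

    Pluggable model selected by ``cfg.deposition_model``:

    - ``settling_plus_diffusion`` (default): gravitational settling of the
      unit-density d_ae sphere plus a Brownian term D/δ across a laminar
      boundary layer of thickness δ (default 1 mm).  Settling dominates
      above ~1 µm, diffusion below ~0.1 µm, giving a single interior
      minimum in between.
    - ``settling_only``: the Stokes term alone.
    """
    d_ae_um = np.asarray(d_ae_um, dtype=float)
    if np.any(d_ae_um <= 0):
        raise ValueError("d_ae must be > 0")
    v = _settling_velocity(d_ae_um, cfg)
    if cfg.deposition_model == "settling_plus_diffusion":
        v = v + _diffusive_velocity(d_ae_um, cfg)
    return v


def mesh_efficiency(d_ae_um, curve: EfficiencyCurve):
    """Mesh-cap collection efficiency η(d_ae) ∈ [0, 1] from a knot table."""
    if curve is None:
        raise ValueError("efficiency curve is required")
    return curve(d_ae_um)
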