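"""From sized particles to blank-corrected PM₂.₅/PM₁₀ air concentrations.

The deposited mass on a stub is inverted to an airborne concentration
particle by particle:

    C_f = Σ_i m_i w_f(d_ae,i) / (η(d_ae,i) V_dep(d_ae,i)) / (A · T)

with m_i the particle mass, w_f the PM-fraction weight, η the mesh-cap
collection efficiency, V_dep the deposition velocity, A the analyzed
deposition area and T the sampling duration.  Field-blank means are
computed per collection surface (PC vs CT) and subtracted from every
result of that surface; negative corrected values are retained, since
clipping them would bias campaign means and blank-variation estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SamplerConfig, default_config
from . import physics
from .segmentation import ParticleRecord

log = logging.getLogger(__name__)

__all__ = [
    "SamplingOccasion",
    "SizedParticle",
    "ConcentrationResult",
    "BlankStats",
    "pm_weight",
    "size_particles",
    "stub_concentration",
    "blank_correct",
    "time_weighted_mean",
    "sampler_vs_reference_ratio",
]

#: smooth PM-convention penetration: lognormal ogive steepness (GSD-like)
_SMOOTH_CUT_GSD = 1.5


@dataclass(frozen=True)
class SamplingOccasion:
    """One sampling occasion: a stub exposed at a location for a duration."""

    occasion_id: str
    location: str
    surface: str                     # "PC" or "CT"
    role: str = "sample"             # sample | field_blank | transport_blank
    start: datetime | None = None
    end: datetime | None = None
    duration_h: float | None = None  # derived from start/end when present

    def __post_init__(self) -> None:
        if self.surface not in ("PC", "CT"):
            raise ValueError("surface must be 'PC' or 'CT'")
        if self.role not in ("sample", "field_blank", "transport_blank"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.start is not None and self.end is not None:
            if not self.end > self.start:
                raise ValueError("occasion end must be after start")
            derived = (self.end - self.start).total_seconds() / 3600.0
            object.__setattr__(self, "duration_h", derived)
        if self.duration_h is None or not self.duration_h > 0:
            raise ValueError("occasion needs a positive duration (start/end or duration_h)")


@dataclass(frozen=True)
class SizedParticle:
    """A detected particle with its derived diameters and mass."""

    pixel_count: int
    area_um2: float
    d_pa_um: float
    d_ve_um: float
    d_ae_um: float
    mass_ng: float
    tile_index: int = 0
    stub_id: str = "stub"


@dataclass(frozen=True)
class ConcentrationResult:
    """Per-occasion PM concentrations (mg m⁻³) with provenance."""

    occasion_id: str
    pm25_mg_m3: float
    pm10_mg_m3: float
    counts: dict = field(default_factory=dict)   # particle counts per fraction
    blank_corrected: bool = False
    config_id: str = ""
    warnings: tuple = ()


@dataclass(frozen=True)
class BlankStats:
    """Field-blank summary per surface type and PM fraction."""

    surface: str
    fraction: str
    mean_mg_m3: float
    sd_mg_m3: float
    n: int


def pm_weight(d_ae_um, cfg: SamplerConfig, fraction: str):
    """Weight of a particle in a PM fraction ("pm2.5" or "pm10").

    Sharp-cut default: 1 for d_ae ≤ cut (boundary inclusive), else 0.
    The "smooth" convention replaces the step with a lognormal ogive
    penetration centred on the cut, non-increasing in d_ae.
    """
    cuts = {"pm2.5": cfg.pm_cuts_um[0], "pm10": cfg.pm_cuts_um[1]}
    if fraction not in cuts:
        raise ValueError(f"unknown fraction {fraction!r}")
    cut = cuts[fraction]
    d = np.asarray(d_ae_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d_ae must be > 0")
    if cfg.pm_convention == "sharp":
        return np.where(d <= cut, 1.0, 0.0)
    return norm.sf(np.log(d / cut) / np.log(_SMOOTH_CUT_GSD))


def size_particles(records, cfg: SamplerConfig | None = None) -> list[SizedParticle]:
    """Attach d_pa, d_ve, d_ae and mass to raw segmentation records."""
    cfg = cfg or default_config()
    sized = []
    for r in records:
        d_pa = float(physics.projected_area_diameter(r.area_um2))
        d_ve = float(physics.volume_equivalent_diameter(d_pa, cfg))
        d_ae = float(physics.aerodynamic_diameter(d_pa, cfg))
        mass = float(physics.particle_mass_ng(d_pa, cfg))
        sized.append(
            SizedParticle(
                pixel_count=getattr(r, "pixel_count", 0),
                area_um2=r.area_um2,
                d_pa_um=d_pa,
                d_ve_um=d_ve,
                d_ae_um=d_ae,
                mass_ng=mass,
                tile_index=getattr(r, "tile_index", 0),
                stub_id=getattr(r, "stub_id", "stub"),
            )
        )
    return sized


def _fraction_efficiency(d_ae, cfg: SamplerConfig, fraction: str):
    if cfg.efficiency_mode == "per_particle":
        return physics.mesh_efficiency(d_ae, cfg.efficiency_curve)
    return np.full_like(np.asarray(d_ae, dtype=float), cfg.per_fraction_efficiency[fraction])


def stub_concentration(
    particles,
    analyzed_area_mm2: float,
    occasion: SamplingOccasion,
    cfg: SamplerConfig | None = None,
) -> ConcentrationResult:
    """Invert one stub's deposited particles into PM concentrations.

    Units: masses ng, area mm², duration h; the result is mg m⁻³.
    Raises if the efficiency or deposition velocity vanishes for a
    detected particle, since that particle's airborne contribution would
    be undefined.
    """
    cfg = cfg or default_config()
    if not analyzed_area_mm2 > 0:
        raise ValueError("analyzed_area_mm2 must be > 0")

    area_m2 = analyzed_area_mm2 * 1e-6
    duration_s = occasion.duration_h * 3600.0

    warnings_list: list[str] = []
    conc = {}
    counts = {}
    if len(particles) == 0:
        conc = {"pm2.5": 0.0, "pm10": 0.0}
        counts = {"pm2.5": 0, "pm10": 0}
    else:
        d_ae = np.array([p.d_ae_um for p in particles])
        mass_mg = np.array([p.mass_ng for p in particles]) * 1e-6
        v_dep = physics.deposition_velocity(d_ae, cfg)
        for fraction in ("pm2.5", "pm10"):
            w = pm_weight(d_ae, cfg, fraction)
            eta = _fraction_efficiency(d_ae, cfg, fraction)
            active = w > 0
            bad = active & ((eta <= 0) | (v_dep <= 0))
            if np.any(bad):
                i = int(np.nonzero(bad)[0][0])
                raise ValueError(
                    f"particle {i} (d_ae={d_ae[i]:.3g} µm) has zero efficiency or "
                    "deposition velocity; concentration undefined"
                )
            flux = np.where(active, mass_mg * w / np.where(active, eta * v_dep, 1.0), 0.0)
            conc[fraction] = float(flux.sum() / (area_m2 * duration_s))
            counts[fraction] = int(np.count_nonzero(active))

    thresholds = {"pm2.5": cfg.count_warning_pm25, "pm10": cfg.count_warning_pm10}
    for fraction, n in counts.items():
        if occasion.role == "sample" and n < thresholds[fraction]:
            msg = (
                f"{occasion.occasion_id}: {fraction} count {n} below the "
                f"counting-statistics adequacy threshold {thresholds[fraction]}"
            )
            warnings_list.append(msg)
            log.warning(msg)

    return ConcentrationResult(
        occasion_id=occasion.occasion_id,
        pm25_mg_m3=conc["pm2.5"],
        pm10_mg_m3=conc["pm10"],
        counts=counts,
        blank_corrected=False,
        config_id=cfg.config_id,
        warnings=tuple(warnings_list),
    )


def blank_correct(results, occasions, enabled: bool = True):
    """Subtract the per-surface field-blank mean from every result.

    Returns ``(corrected_results, blank_stats)``.  Blank means pool the
    field blanks of one surface type across locations; transport blanks
    are summarized but never subtracted.  Negative corrected values are
    retained.  With ``enabled=False`` the results pass through unchanged
    (the uncorrected reporting mode) while the blank statistics are still
    computed.
    """
    occ_by_id = {o.occasion_id: o for o in occasions}
    missing = [r.occasion_id for r in results if r.occasion_id not in occ_by_id]
    if missing:
        raise ValueError(f"results reference unknown occasions: {missing}")

    surfaces = {occ_by_id[r.occasion_id].surface for r in results}
    blank_values: dict[tuple, dict] = {}
    stats: list[BlankStats] = []
    for surface in sorted(surfaces):
        for role in ("field_blank", "transport_blank"):
            vals25 = [
                r.pm25_mg_m3 for r in results
                if occ_by_id[r.occasion_id].surface == surface and occ_by_id[r.occasion_id].role == role
            ]
            vals10 = [
                r.pm10_mg_m3 for r in results
                if occ_by_id[r.occasion_id].surface == surface and occ_by_id[r.occasion_id].role == role
            ]
            for fraction, vals in (("pm2.5", vals25), ("pm10", vals10)):
                if vals:
                    stats.append(
                        BlankStats(
                            surface=surface,
                            fraction=fraction if role == "field_blank" else f"{fraction}:{role}",
                            mean_mg_m3=float(np.mean(vals)),
                            sd_mg_m3=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                            n=len(vals),
                        )
                    )
                if role == "field_blank":
                    blank_values.setdefault(surface, {})[fraction] = (
                        float(np.mean(vals)) if vals else None
                    )

    if not enabled:
        return list(results), stats

    for surface in sorted(surfaces):
        means = blank_values.get(surface, {})
        if means.get("pm2.5") is None or means.get("pm10") is None:
            raise ValueError(
                f"no field blank for surface {surface!r}; "
                "run with blank correction disabled to report uncorrected values"
            )

    corrected = []
    for r in results:
        surface = occ_by_id[r.occasion_id].surface
        means = blank_values[surface]
        corrected.append(
            replace(
                r,
                pm25_mg_m3=r.pm25_mg_m3 - means["pm2.5"],
                pm10_mg_m3=r.pm10_mg_m3 - means["pm10"],
                blank_corrected=True,
            )
        )
    return corrected, stats


def time_weighted_mean(results, occasions) -> dict:
    """Duration-weighted mean concentration per fraction, mg m⁻³.

    Weights each occasion's concentration by its duration so occasions of
    unequal length average to the whole-period mean; equal durations
    reduce to the arithmetic mean.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to average")
    occ_by_id = {o.occasion_id: o for o in occasions}
    durations = np.array([occ_by_id[r.occasion_id].duration_h for r in results])
    pm25 = np.array([r.pm25_mg_m3 for r in results])
    pm10 = np.array([r.pm10_mg_m3 for r in results])
    wsum = durations.sum()
    return {
        "pm2.5": float(np.sum(pm25 * durations) / wsum),
        "pm10": float(np.sum(pm10 * durations) / wsum),
        "total_hours": float(wsum),
    }


def sampler_vs_reference_ratio(sampler_mean: float, reference_mean: float) -> float:
    """Sampler-to-reference concentration ratio in percent."""
    if not reference_mean > 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * sampler_mean / reference_mean


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "occasion_id": [r.occasion_id for r in results],
            "pm25_mg_per_m3": [r.pm25_mg_m3 for r in results],
            "pm10_mg_per_m3": [r.pm10_mg_m3 for r in results],
            "count_pm25": [r.counts.get("pm2.5") for r in results],
            "count_pm10": [r.counts.get("pm10") for r in results],
            "blank_corrected": [r.blank_corrected for r in results],
            "config_id": [r.config_id for r in results],
        }
    )
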