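"""Physical configuration for the passive-sampler analysis chain.

Every stage of the pipeline (sizing, deposition modelling, quantification)
reads its constants from a single :class:`SamplerConfig`.  The defaults are
the analysis constants for irregular heterogeneous mineral dust: volume
shape factor 1.6, dynamic shape factor 1.4, particle density 2.0 g cm⁻³,
a 12 mm stub imaged at 0.64 µm per pixel, and area filters 0.41–10000 µm².
Concentrations computed under two different configs carry different
``config_id`` values so results from mixed physics cannot be pooled
silently.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "AirState",
    "EfficiencyCurve",
    "SamplerConfig",
    "validate_config",
    "default_config",
    "STUB_AREA_MM2",
]

#: Area of the full 12 mm stub disc, mm².
STUB_AREA_MM2 = float(np.pi * 6.0**2)


@dataclass(frozen=True)
class AirState:
    """Ambient air state used by slip, settling and diffusion formulas.

    Defaults are standard indoor conditions: 293 K, 101.3 kPa, dynamic
    viscosity 1.81e-5 Pa·s and a gas mean free path of 0.0665 µm.
    """

    temperature_k: float = 293.0
    pressure_kpa: float = 101.3
    viscosity_pa_s: float = 1.81e-5
    mean_free_path_um: float = 0.0665

    def __post_init__(self) -> None:
        for name in ("temperature_k", "pressure_kpa", "viscosity_pa_s", "mean_free_path_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"air property {name} must be > 0")


class EfficiencyCurve:
    """Mesh-cap collection efficiency as a function of aerodynamic diameter.

    A monotone piecewise-linear interpolation between ``(diameter µm,
    efficiency)`` knots, clamped to the end values outside the knot range.
    The published efficiency curves for the mesh cap are not tabulated in
    any open source, so the default shipped here is an explicit placeholder
    (a gentle decline from 1.0 below 1 µm toward larger sizes); users who
    need fidelity to a specific cap must load their own table, e.g. with
    :meth:`from_csv`.
    """

    def __init__(self, diameters_um: Sequence[float], efficiencies: Sequence[float], name: str = "custom"):
        d = np.asarray(diameters_um, dtype=float)
        e = np.asarray(efficiencies, dtype=float)
        if d.size == 0:
            raise ValueError("efficiency curve needs at least one knot")
        if d.size != e.size:
            raise ValueError("diameters and efficiencies differ in length")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("knot diameters must be strictly increasing")
        if np.any((e < 0) | (e > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")
        self.diameters_um = d
        self.efficiencies = e
        self.name = name

    def __call__(self, d_ae_um):
        """Interpolated efficiency, clamped to end values outside the knots."""
        return np.interp(d_ae_um, self.diameters_um, self.efficiencies)

    @classmethod
    def unit(cls) -> "EfficiencyCurve":
        """η ≡ 1 for all sizes (no cap losses)."""
        return cls([1.0], [1.0], name="unit")

    @classmethod
    def default_placeholder(cls) -> "EfficiencyCurve":
        """Synthetic placeholder curve: unity below 1 µm, declining above."""
        return cls(
            [0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0],
            [1.0, 0.98, 0.90, 0.75, 0.55, 0.40, 0.30, 0.20],
            name="placeholder-decline",
        )

    @classmethod
    def from_csv(cls, path) -> "EfficiencyCurve":
        """Load a two-column (d_um, efficiency) CSV, header optional."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise ValueError("efficiency CSV needs two columns: d_um, efficiency")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), name=str(path))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "diameters_um": self.diameters_um.tolist(),
            "efficiencies": self.efficiencies.tolist(),
        }


@dataclass(frozen=True)
class SamplerConfig:
    """All physical constants and model choices of the analysis chain.

    ``volume_shape_factor`` uses the convention V = f_V · d_pa³, i.e. the
    particle volume is the cube of the projected-area diameter scaled by
    f_V; 1.6 is only meaningful under this convention (a sphere has
    f_V = π/6 ≈ 0.524).  ``dynamic_shape_factor`` χ ≥ 1 is the drag ratio
    to the volume-equivalent sphere.  Densities are in g cm⁻³.
    """

    volume_shape_factor: float = 1.6
    dynamic_shape_factor: float = 1.4
    particle_density_g_cm3: float = 2.0
    reference_density_g_cm3: float = 1.0
    air: AirState = field(default_factory=AirState)

    #: "settling_plus_diffusion" (default) or "settling_only"
    deposition_model: str = "settling_plus_diffusion"
    #: diffusive boundary-layer thickness, mm (Brownian term v_d = D/δ)
    boundary_layer_mm: float = 1.0

    efficiency_curve: EfficiencyCurve = field(default_factory=EfficiencyCurve.unit)
    #: "per_particle" applies η(d_ae) to every particle; "per_fraction"
    #: divides each PM fraction by a single scalar efficiency.
    efficiency_mode: str = "per_particle"
    per_fraction_efficiency: dict = field(default_factory=lambda: {"pm2.5": 1.0, "pm10": 1.0})

    stub_diameter_mm: float = 12.0
    pm_convention: str = "sharp"  # or "smooth"
    pm_cuts_um: tuple = (2.5, 10.0)

    # imaging / segmentation
    pixel_side_um: float = 0.64
    min_area_um2: float = 0.41
    max_area_um2: float = 10000.0
    connectivity: int = 2  # skimage connectivity: 2 == 8-neighbour
    foreground_polarity: str = "bright"
    #: minimum grey-level contrast between the two threshold classes for
    #: a tile to count as containing particles (blank-like guard)
    min_class_contrast: float = 25.0
    count_warning_pm25: int = 55
    count_warning_pm10: int = 71

    def __post_init__(self) -> None:
        if not self.volume_shape_factor > 0:
            raise ValueError("volume_shape_factor must be > 0")
        if not self.dynamic_shape_factor >= 1:
            raise ValueError("dynamic_shape_factor must be >= 1")
        if not self.particle_density_g_cm3 > 0:
            raise ValueError("particle_density_g_cm3 must be > 0")
        if not self.reference_density_g_cm3 > 0:
            raise ValueError("reference_density_g_cm3 must be > 0")
        if self.deposition_model not in ("settling_plus_diffusion", "settling_only"):
            raise ValueError(f"unknown deposition_model {self.deposition_model!r}")
        if self.efficiency_mode not in ("per_particle", "per_fraction"):
            raise ValueError(f"unknown efficiency_mode {self.efficiency_mode!r}")
        if self.pm_convention not in ("sharp", "smooth"):
            raise ValueError(f"unknown pm_convention {self.pm_convention!r}")
        if not self.pixel_side_um > 0:
            raise ValueError("pixel_side_um must be > 0")
        if not 0 <= self.min_area_um2 < self.max_area_um2:
            raise ValueError("area filter bounds must satisfy 0 <= min < max")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-neighbour) or 2 (8-neighbour)")
        if self.foreground_polarity not in ("bright", "dark"):
            raise ValueError("foreground_polarity must be 'bright' or 'dark'")

    @property
    def stub_area_mm2(self) -> float:
        return float(np.pi * (self.stub_diameter_mm / 2.0) ** 2)

    @property
    def config_id(self) -> str:
        """Short stable hash of every physical constant in the config."""
        payload = dict(asdict(self))
        payload["efficiency_curve"] = self.efficiency_curve.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_(self, **kwargs) -> "SamplerConfig":
        """Functional update (dataclasses.replace wrapper)."""
        return replace(self, **kwargs)


def default_config() -> SamplerConfig:
    return SamplerConfig()


# keys accepted by validate_config, with their SamplerConfig destination
_SCALAR_KEYS = {
    "volume_shape_factor": "volume_shape_factor",
    "dynamic_shape_factor": "dynamic_shape_factor",
    "particle_density_g_cm3": "particle_density_g_cm3",
    "reference_density_g_cm3": "reference_density_g_cm3",
    "deposition_model": "deposition_model",
    "boundary_layer_mm": "boundary_layer_mm",
    "efficiency_mode": "efficiency_mode",
    "stub_diameter_mm": "stub_diameter_mm",
    "pm_convention": "pm_convention",
    "pixel_side_um": "pixel_side_um",
    "min_area_um2": "min_area_um2",
    "max_area_um2": "max_area_um2",
    "connectivity": "connectivity",
    "foreground_polarity": "foreground_polarity",
    "min_class_contrast": "min_class_contrast",
    "count_warning_pm25": "count_warning_pm25",
    "count_warning_pm10": "count_warning_pm10",
}


def validate_config(raw: dict | None):
    """Normalize a raw (e.g. YAML-loaded) config mapping.

    Returns ``(SamplerConfig, warnings)``.  Unknown keys produce warnings;
    out-of-range values raise ``ValueError`` naming the offending key.
    An empty or ``None`` input yields the full defaults.
    """
    raw = dict(raw or {})
    warnings: list[str] = []
    kwargs: dict = {}

    air_raw = raw.pop("air", None)
    if air_raw is not None:
        known_air = {"temperature_k", "pressure_kpa", "viscosity_pa_s", "mean_free_path_um"}
        extra = set(air_raw) - known_air
        for k in sorted(extra):
            warnings.append(f"unknown air key: {k}")
        kwargs["air"] = AirState(**{k: v for k, v in air_raw.items() if k in known_air})

    curve_raw = raw.pop("efficiency_curve", None)
    if curve_raw is not None:
        if isinstance(curve_raw, str):
            if curve_raw == "unit":
                kwargs["efficiency_curve"] = EfficiencyCurve.unit()
            elif curve_raw in ("default", "placeholder"):
                kwargs["efficiency_curve"] = EfficiencyCurve.default_placeholder()
            else:
                kwargs["efficiency_curve"] = EfficiencyCurve.from_csv(curve_raw)
        else:
            kwargs["efficiency_curve"] = EfficiencyCurve(
                curve_raw["diameters_um"], curve_raw["efficiencies"],
                name=curve_raw.get("name", "config"),
            )

    if "pm_cuts_um" in raw:
        kwargs["pm_cuts_um"] = tuple(float(v) for v in raw.pop("pm_cuts_um"))
    if "per_fraction_efficiency" in raw:
        kwargs["per_fraction_efficiency"] = {
            str(k): float(v) for k, v in raw.pop("per_fraction_efficiency").items()
        }

    for key, value in raw.items():
        if key in _SCALAR_KEYS:
            kwargs[_SCALAR_KEYS[key]] = value
        else:
            warnings.append(f"unknown config key: {key}")

    try:
        cfg = SamplerConfig(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid config: {exc}") from exc
    return cfg, warnings


def dump_config(cfg: SamplerConfig) -> str:
    """YAML dump of a config, round-trippable through validate_config."""
    payload = asdict(cfg)
    payload["air"] = asdict(cfg.air)
    payload["efficiency_curve"] = cfg.efficiency_curve.to_dict()
    payload["pm_cuts_um"] = list(cfg.pm_cuts_um)
    buf = io.StringIO()
    yaml.safe_dump(payload, buf, sort_keys=True)
    return buf.getvalue()
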