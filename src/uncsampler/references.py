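"""Active-sampling reference computations.

Two references accompany the passive sampler: gravimetric impactor
filters (mass gain over a metered flow and duration) and an optical
particle counter whose bin number concentrations are converted to
cumulative PM mass fractions at 2.0 g cm⁻³.  PM₀.₇₅ — the proxy for
particles too small to resolve in the microscope images — is defined as
the mean of PM₀.₅ and PM₁.₀.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FilterWeighing",
    "OpcSpectrum",
    "impactor_concentration",
    "opc_to_pm",
    "fine_fraction_ratios",
    "PM_LEVELS_UM",
]

#: cumulative PM levels reported from the optical counter, µm
PM_LEVELS_UM = (0.5, 1.0, 2.5, 5.0, 10.0)


@dataclass(frozen=True)
class FilterWeighing:
    """Duplicate pre/post weighings of one impactor filter, mg."""

    filter_id: str
    pre_weights_mg: tuple
    post_weights_mg: tuple
    role: str = "sample"  # sample | transport_blank

    def __post_init__(self) -> None:
        if len(self.pre_weights_mg) != 2 or len(self.post_weights_mg) != 2:
            raise ValueError("filters are weighed twice before and twice after sampling")
        if self.role not in ("sample", "transport_blank"):
            raise ValueError(f"unknown weighing role {self.role!r}")

    @property
    def mass_gain_mg(self) -> float:
        return float(np.mean(self.post_weights_mg) - np.mean(self.pre_weights_mg))


@dataclass(frozen=True)
class OpcSpectrum:
    """Optical-particle-counter bin number concentrations.

    ``bin_edges_um`` are the n+1 edges of n bins within 0.3–10 µm;
    ``number_per_cm3`` are the per-bin number concentrations.  Density
    (g cm⁻³) is the value used for the count-to-mass conversion.
    """

    bin_edges_um: tuple
    number_per_cm3: tuple
    density_g_cm3: float = 2.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_um, dtype=float)
        counts = np.asarray(self.number_per_cm3, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least one bin (two edges)")
        if counts.size != edges.size - 1:
            raise ValueError("number_per_cm3 must have one entry per bin")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] < 0.3 - 1e-12 or edges[-1] > 10.0 + 1e-12:
            raise ValueError("bin edges must lie within [0.3, 10] µm")
        if np.any(counts < 0):
            raise ValueError("number concentrations must be >= 0")

    @classmethod
    def lighthouse_edges(cls) -> tuple:
        """The 0.3–10 µm six-channel layout of the handheld counter."""
        return (0.3, 0.5, 1.0, 2.5, 5.0, 10.0)


def impactor_concentration(
    weighing: FilterWeighing,
    flow_start_l_min: float,
    flow_end_l_min: float,
    duration_min: float,
    blank_mean_mg: float = 0.0,
    nominal_flow_l_min: float = 10.0,
    flow_tolerance_l_min: float = 0.5,
):
    """Gravimetric concentration, mg m⁻³, from one impactor filter.

    Δm = mean(post) − mean(pre) − blank_mean; the sampled volume uses the
    mean of the start and end flow-meter readings.  Flows outside the
    nominal ± tolerance band produce a warning flag but the concentration
    is still computed.  Returns ``(concentration_mg_m3, warnings)``.
    """
    if not duration_min > 0:
        raise ValueError("duration must be > 0")
    warnings = []
    for label_, flow in (("start", flow_start_l_min), ("end", flow_end_l_min)):
        if abs(flow - nominal_flow_l_min) > flow_tolerance_l_min:
            msg = (
                f"{weighing.filter_id}: {label_} flow {flow:.2f} L/min outside "
                f"{nominal_flow_l_min}±{flow_tolerance_l_min}"
            )
            warnings.append(msg)
            log.warning(msg)
    delta_m_mg = weighing.mass_gain_mg - blank_mean_mg
    volume_m3 = 0.5 * (flow_start_l_min + flow_end_l_min) * duration_min * 1e-3
    return delta_m_mg / volume_m3, warnings


def _representative_diameters(edges: np.ndarray, mode: str) -> np.ndarray:
    lo, hi = edges[:-1], edges[1:]
    if mode == "geometric":
        return np.sqrt(lo * hi)
    if mode == "arithmetic":
        return 0.5 * (lo + hi)
    raise ValueError(f"unknown representative-diameter mode {mode!r}")


def opc_to_pm(spectrum: OpcSpectrum, representative: str = "geometric") -> dict:
    """Convert OPC bin counts to cumulative PM masses, mg m⁻³.

    Per-bin mass = number × (π/6)·d_rep³·ρ with d_rep the geometric mean
    of the bin edges (arithmetic-mean mode available); spheres are
    assumed since density is the only stated conversion parameter.
    PM_x sums the bins whose upper edge is ≤ x; PM₀.₇₅ is exactly the
    mean of PM₀.₅ and PM₁.₀.  The representative-diameter mode is logged
    in the returned dict.
    """
    edges = np.asarray(spectrum.bin_edges_um, dtype=float)
    counts = np.asarray(spectrum.number_per_cm3, dtype=float)
    d_rep = _representative_diameters(edges, representative)
    # n [cm⁻³] × (π/6) d³ [µm³] × ρ [g cm⁻³]: 1 µm³ = 1e-12 cm³ and
    # 1 g cm⁻³(air) = 1e9 mg m⁻³, hence the net 1e-3.
    bin_mass_mg_m3 = counts * (np.pi / 6.0) * d_rep**3 * spectrum.density_g_cm3 * 1e-3

    pm = {}
    for level in PM_LEVELS_UM:
        pm[f"pm{level:g}"] = float(bin_mass_mg_m3[edges[1:] <= level + 1e-12].sum())
    pm["pm0.75"] = 0.5 * (pm["pm0.5"] + pm["pm1"])
    pm["representative_diameter"] = representative
    return pm


def fine_fraction_ratios(pm: dict) -> dict:
    """PM₀.₇₅/PM₂.₅ and PM₀.₇₅/PM₁₀ in percent (None when undefined)."""
    out = {}
    for denom_key, out_key in (("pm2.5", "pm0.75/pm2.5_pct"), ("pm10", "pm0.75/pm10_pct")):
        denom = pm.get(denom_key, 0.0)
        out[out_key] = None if denom <= 0 else 100.0 * pm["pm0.75"] / denom
    return out


def weighings_from_frame(df: pd.DataFrame) -> list[FilterWeighing]:
    """Build weighings from a CSV-loaded table with columns
    filter_id, pre1_mg, pre2_mg, post1_mg, post2_mg[, role]."""
    out = []
    for _, row in df.iterrows():
        out.append(
            FilterWeighing(
                filter_id=str(row["filter_id"]),
                pre_weights_mg=(float(row["pre1_mg"]), float(row["pre2_mg"])),
                post_weights_mg=(float(row["post1_mg"]), float(row["post2_mg"])),
                role=str(row.get("role", "sample")),
            )
        )
    return out
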