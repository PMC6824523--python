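"""Synthetic deposition: ground-truth particles, rendered tiles, references.

The generator is the inverse of the analysis chain.  A lognormal
count distribution of aerodynamic diameters is discretized into size
bins; the expected deposited count per bin follows the flux balance

    λ(d) = C · f_count(d) / E[m] · η(d) · V_dep(d) · A · T
         = C · f_mass(d) / m(d) · η(d) · V_dep(d) · A · T

(C the true mass concentration, m(d) the per-particle mass through the
same shape-factor chain the pipeline uses, η the mesh-cap efficiency,
V_dep the deposition velocity, A the deposition area, T the duration).
Realized counts are Poisson; placement is complete spatial randomness
(still air).  Each particle is rendered as a filled bright ellipse whose
target projected area is the exact inverse image of the segmentation →
aerodynamic-diameter chain, so a perfect segmentation recovers the truth
up to boundary discretization.  Matching gravimetric-impactor masses and
optical-counter spectra are fabricated from the same distribution.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.stats import lognorm

from .config import SamplerConfig, default_config, STUB_AREA_MM2
from . import physics
from .references import OpcSpectrum
from .segmentation import SemTile

log = logging.getLogger(__name__)

__all__ = [
    "TruthScenario",
    "DepositedParticle",
    "StubImageSet",
    "sample_population",
    "render_tiles",
    "fabricate_references",
    "expected_bin_counts",
    "true_pm_concentrations",
    "save_stub",
]


@dataclass(frozen=True)
class TruthScenario:
    """Ground-truth conditions for one synthetic stub.

    The size distribution is a count lognormal over aerodynamic diameter
    with median ``cmad_um`` and geometric standard deviation ``gsd``
    (``gsd == 1`` is an exact monodisperse population).  Concentration is
    the true airborne mass concentration of the truncated distribution
    over [d_min_um, d_max_um].
    """

    true_concentration_mg_m3: float
    cmad_um: float = 2.5
    gsd: float = 1.6
    duration_h: float = 24.0
    deposition_area_mm2: float = STUB_AREA_MM2
    contamination_rate: float = 0.0     # expected blank particles per stub
    background_mean: float = 60.0       # grey levels
    background_sd: float = 8.0
    particle_grey: float = 200.0
    particle_grey_sd: float = 8.0
    seed: int = 0
    tile_grid: tuple = (6, 5)           # columns × rows, 30 tiles
    pixel_side_um: float = 0.64
    d_min_um: float = 0.3
    d_max_um: float = 12.0
    n_size_bins: int = 160
    stub_id: str = "synthetic-stub"

    def __post_init__(self) -> None:
        if self.true_concentration_mg_m3 < 0:
            raise ValueError("true_concentration must be >= 0")
        if not self.gsd >= 1:
            raise ValueError("GSD must be >= 1")
        if not self.duration_h > 0:
            raise ValueError("duration must be > 0")
        if not self.deposition_area_mm2 > 0:
            raise ValueError("deposition_area must be > 0")
        if self.contamination_rate < 0:
            raise ValueError("contamination_rate must be >= 0")
        if not (0 < self.d_min_um < self.d_max_um):
            raise ValueError("need 0 < d_min < d_max")

    @property
    def n_tiles(self) -> int:
        return int(self.tile_grid[0] * self.tile_grid[1])

    def tile_side_px(self) -> int:
        """Tile side in pixels so the grid covers the deposition area."""
        area_um2 = self.deposition_area_mm2 * 1e6
        side_um = np.sqrt(area_um2 / self.n_tiles)
        return max(int(round(side_um / self.pixel_side_um)), 8)

    @property
    def realized_area_mm2(self) -> float:
        """Deposition area actually covered by the integer-sized tile grid."""
        side_um = self.tile_side_px() * self.pixel_side_um
        return self.n_tiles * side_um**2 * 1e-6


@dataclass(frozen=True)
class DepositedParticle:
    """One ground-truth particle placed on the stub."""

    d_ae_um: float
    d_pa_um: float
    area_um2: float        # target projected area (exact chain inverse)
    mass_ng: float
    center_xy_um: tuple    # global coordinates over the tiled region
    tile_index: int
    semi_axes_px: tuple    # ellipse semi-axes, px
    angle_rad: float


@dataclass
class StubImageSet:
    """Rendered tiles of one stub plus its truth table."""

    tiles: list
    truth: pd.DataFrame
    scenario: TruthScenario
    seed_log: dict = field(default_factory=dict)


def _size_bins(scenario: TruthScenario):
    """Log-spaced aerodynamic-diameter bins and their count weights."""
    if scenario.gsd == 1.0:
        return np.array([scenario.cmad_um]), np.array([1.0])
    edges = np.geomspace(scenario.d_min_um, scenario.d_max_um, scenario.n_size_bins + 1)
    dist = lognorm(s=np.log(scenario.gsd), scale=scenario.cmad_um)
    cdf = dist.cdf(edges)
    weights = np.diff(cdf)
    total = weights.sum()
    if total <= 0:
        raise ValueError("size distribution has no mass in [d_min, d_max]")
    mids = np.sqrt(edges[:-1] * edges[1:])
    return mids, weights / total


def _chain_inverse(d_ae: np.ndarray, cfg: SamplerConfig):
    """Per-size d_pa, projected area and mass through the inverse chain."""
    d_pa = np.atleast_1d(physics.projected_area_diameter_from_aerodynamic(d_ae, cfg))
    area = np.pi / 4.0 * d_pa**2
    mass_ng = physics.particle_mass_ng(d_pa, cfg)
    return d_pa, area, mass_ng


def expected_bin_counts(scenario: TruthScenario, cfg: SamplerConfig):
    """Poisson means per size bin (the analytic flux balance).

    Returns ``(d_ae_mids, lambdas, masses_ng)``.  Raises if the deposition
    velocity is non-finite anywhere in the size range.
    """
    mids, weights = _size_bins(scenario)
    _, _, mass_ng = _chain_inverse(mids, cfg)
    mass_mg = mass_ng * 1e-6

    v_dep = physics.deposition_velocity(mids, cfg)
    if not np.all(np.isfinite(v_dep)):
        raise ValueError("non-finite deposition velocity in the scenario size range")
    eta = physics.mesh_efficiency(mids, cfg.efficiency_curve)

    mean_mass_mg = float(np.sum(weights * mass_mg))
    if scenario.true_concentration_mg_m3 == 0 or mean_mass_mg == 0:
        n_total_per_m3 = 0.0
    else:
        n_total_per_m3 = scenario.true_concentration_mg_m3 / mean_mass_mg

    area_m2 = scenario.realized_area_mm2 * 1e-6
    duration_s = scenario.duration_h * 3600.0
    lambdas = n_total_per_m3 * weights * eta * v_dep * area_m2 * duration_s
    return mids, lambdas, mass_ng


def _rng_for(scenario: TruthScenario, stream: str) -> np.random.Generator:
    """Named child generator so every stage draws from its own stream.

    The stream key is a stable digest of the stream name, so the same
    scenario seed reproduces every stage bit-for-bit across processes.
    """
    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(scenario.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def sample_population(scenario: TruthScenario, cfg: SamplerConfig | None = None) -> list[DepositedParticle]:
    """Draw the deposited particle population for one stub.

    Counts per size bin are Poisson with the flux-balance means; each
    particle takes its bin's representative diameter, a uniform position
    over the tiled region, and an ellipse shape of aspect ratio U(1, 3)
    whose area is the exact inverse image of the sizing chain.
    Contamination (blank) particles are added on top with the same size
    distribution, Poisson(contamination_rate) in number.
    """
    cfg = cfg or default_config()
    mids, lambdas, mass_ng = expected_bin_counts(scenario, cfg)
    d_pa, area_um2, _ = _chain_inverse(mids, cfg)

    rng = _rng_for(scenario, "population")
    counts = rng.poisson(lambdas)

    n_contam = int(_rng_for(scenario, "contamination").poisson(scenario.contamination_rate))
    if n_contam > 0:
        _, weights = _size_bins(scenario)
        contam_bins = _rng_for(scenario, "contamination-sizes").choice(
            len(mids), size=n_contam, p=weights if len(mids) > 1 else None
        )
        counts = counts + np.bincount(np.atleast_1d(contam_bins), minlength=len(mids))

    side_um = scenario.tile_side_px() * scenario.pixel_side_um
    nx, ny = scenario.tile_grid
    width_um, height_um = nx * side_um, ny * side_um

    place_rng = _rng_for(scenario, "placement")
    shape_rng = _rng_for(scenario, "shape")
    particles: list[DepositedParticle] = []
    for i in range(len(mids)):
        for _ in range(int(counts[i])):
            x = place_rng.uniform(0.0, width_um)
            y = place_rng.uniform(0.0, height_um)
            col = min(int(x // side_um), nx - 1)
            row = min(int(y // side_um), ny - 1)
            tile_index = row * nx + col

            area_px = area_um2[i] / scenario.pixel_side_um**2
            aspect = shape_rng.uniform(1.0, 3.0)
            semi_a = np.sqrt(area_px * aspect / np.pi)
            semi_b = semi_a / aspect
            angle = shape_rng.uniform(0.0, np.pi)

            particles.append(
                DepositedParticle(
                    d_ae_um=float(mids[i]),
                    d_pa_um=float(d_pa[i]),
                    area_um2=float(area_um2[i]),
                    mass_ng=float(mass_ng[i]),
                    center_xy_um=(float(x), float(y)),
                    tile_index=int(tile_index),
                    semi_axes_px=(float(semi_a), float(semi_b)),
                    angle_rad=float(angle),
                )
            )
    return particles


_SUBGRID = 4  # subpixel sampling resolution for coverage ranking


def _draw_ellipse(canvas: np.ndarray, cx: float, cy: float, semi_a: float, semi_b: float,
                  angle: float, target_area_px: float) -> tuple:
    """Rasterize an ellipse to exactly ``round(target_area_px)`` pixels.

    Pixels are ranked by their subpixel coverage of the ellipse and the
    top-k are filled, so the rendered pixel count equals the target
    projected area up to rounding — a thin sub-pixel ellipse still
    renders its full area instead of collapsing between pixel centers.
    Returns (pixels set, pixels that were already foreground).
    """
    h, w = canvas.shape
    k = int(round(target_area_px))
    if k <= 0:
        return 0, 0
    r = max(semi_a, semi_b) + 1.5
    r0, r1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, h)
    c0, c1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return 0, 0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    offs = (np.arange(_SUBGRID) + 0.5) / _SUBGRID
    sub_y = yy[..., None, None] + offs[None, None, :, None]
    sub_x = xx[..., None, None] + offs[None, None, None, :]
    dx = sub_x - cx
    dy = sub_y - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    coverage = ((u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0).mean(axis=(2, 3))
    flat = coverage.ravel()
    candidates = np.nonzero(flat > 0)[0]
    if candidates.size == 0:  # sub-sampling missed a tiny ellipse: take center
        candidates = np.array([np.argmin(
            ((xx.ravel() + 0.5) - cx) ** 2 + ((yy.ravel() + 0.5) - cy) ** 2
        )])
    order = candidates[np.argsort(-flat[candidates], kind="stable")]
    chosen = order[: min(k, order.size)]
    rows, cols = np.unravel_index(chosen, coverage.shape)
    patch = canvas[r0:r1, c0:c1]
    overlap = int(np.count_nonzero(patch[rows, cols] == 1))
    patch[rows, cols] = 1
    return int(chosen.size), overlap


def render_tiles(particles, scenario: TruthScenario, cfg: SamplerConfig | None = None) -> StubImageSet:
    """Render deposited particles onto noisy 8-bit grayscale tiles.

    Particles are assigned to the tile containing their center and clipped
    at tile borders; particles whose footprints touch are flagged
    ``merged`` in the truth table (the segmenter will count them as one).
    With no particles the tiles contain only background noise.
    """
    cfg = cfg or default_config()
    side = scenario.tile_side_px()
    nx, ny = scenario.tile_grid
    rng = _rng_for(scenario, "render")

    masks = [np.zeros((side, side), dtype=np.uint8) for _ in range(scenario.n_tiles)]
    rows = []
    for pid, p in enumerate(particles):
        col = p.tile_index % nx
        row = p.tile_index // nx
        cx = p.center_xy_um[0] / scenario.pixel_side_um - col * side
        cy = p.center_xy_um[1] / scenario.pixel_side_um - row * side
        n_px, n_overlap = _draw_ellipse(
            masks[p.tile_index], cx, cy, p.semi_axes_px[0], p.semi_axes_px[1], p.angle_rad,
            p.area_um2 / scenario.pixel_side_um**2,
        )
        rows.append(
            {
                "particle_id": pid,
                "tile": p.tile_index,
                "d_ae_um": p.d_ae_um,
                "d_pa_um": p.d_pa_um,
                "area_um2": p.area_um2,
                "mass_ng": p.mass_ng,
                "rendered_px": n_px,
                "merged": n_overlap > 0,
            }
        )

    tiles = []
    for idx in range(scenario.n_tiles):
        # Grey-level spreads are truncated at 2 sd toward each other,
        # emulating the bounded brightness range of a uniform substrate
        # vs. dense particles under backscatter imaging: the two classes
        # never bleed into one another.
        background = np.minimum(
            rng.normal(scenario.background_mean, scenario.background_sd, size=(side, side)),
            scenario.background_mean + 2.0 * scenario.background_sd,
        )
        foreground = np.maximum(
            rng.normal(scenario.particle_grey, scenario.particle_grey_sd, size=(side, side)),
            scenario.particle_grey - 2.0 * scenario.particle_grey_sd,
        )
        img = np.where(masks[idx] == 1, foreground, background)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        tiles.append(
            SemTile(pixels=img, pixel_side_um=scenario.pixel_side_um, tile_index=idx, stub_id=scenario.stub_id)
        )

    truth = pd.DataFrame(
        rows,
        columns=["particle_id", "tile", "d_ae_um", "d_pa_um", "area_um2", "mass_ng", "rendered_px", "merged"],
    )
    return StubImageSet(tiles=tiles, truth=truth, scenario=scenario, seed_log={"seed": scenario.seed})


def true_pm_concentrations(scenario: TruthScenario, cfg: SamplerConfig | None = None) -> dict:
    """Analytic PM concentrations of the scenario distribution, mg m⁻³.

    Sharp-cut mass fractions of the binned distribution; these are the
    ground truth the pipeline and the fabricated references share.
    """
    cfg = cfg or default_config()
    mids, weights = _size_bins(scenario)
    _, _, mass_ng = _chain_inverse(mids, cfg)
    mass_w = weights * mass_ng
    total = mass_w.sum()
    out = {}
    for fraction, cut in (("pm2.5", cfg.pm_cuts_um[0]), ("pm10", cfg.pm_cuts_um[1])):
        frac = float(mass_w[mids <= cut].sum() / total) if total > 0 else 0.0
        out[fraction] = scenario.true_concentration_mg_m3 * frac
    return out


def fabricate_references(
    scenario: TruthScenario,
    cfg: SamplerConfig | None = None,
    flow_l_min: float = 10.0,
    gravimetric_noise_sd_mg: float = 0.0,
    opc_edges_um: tuple | None = None,
) -> tuple:
    """Fabricate impactor filter mass gains and an OPC spectrum.

    Filter gain (mg) per fraction is C_fraction × flow × duration with
    optional Gaussian weighing noise (default 0).  OPC bin counts are the
    number concentrations of the scenario distribution integrated over
    the counter's bins, clipped to 0.3–10 µm.

    Returns ``({"pm2.5": mg, "pm10": mg}, OpcSpectrum)``.
    """
    cfg = cfg or default_config()
    truth = true_pm_concentrations(scenario, cfg)
    duration_min = scenario.duration_h * 60.0
    volume_m3 = flow_l_min * duration_min * 1e-3

    rng = _rng_for(scenario, "gravimetry")
    gains = {}
    for fraction in ("pm2.5", "pm10"):
        gain = truth[fraction] * volume_m3
        if gravimetric_noise_sd_mg > 0:
            gain += rng.normal(0.0, gravimetric_noise_sd_mg)
        gains[fraction] = float(gain)

    mids, weights = _size_bins(scenario)
    _, _, mass_ng = _chain_inverse(mids, cfg)
    mean_mass_mg = float(np.sum(weights * mass_ng) * 1e-6)
    n_total_per_m3 = (
        scenario.true_concentration_mg_m3 / mean_mass_mg if mean_mass_mg > 0 else 0.0
    )

    edges = np.asarray(opc_edges_um if opc_edges_um is not None else OpcSpectrum.lighthouse_edges())
    if scenario.gsd == 1.0:
        in_bin = (edges[:-1] <= scenario.cmad_um) & (scenario.cmad_um < edges[1:])
        bin_counts = np.where(in_bin, n_total_per_m3, 0.0)
    else:
        dist = lognorm(s=np.log(scenario.gsd), scale=scenario.cmad_um)
        lo = dist.cdf(np.maximum(edges[:-1], scenario.d_min_um))
        hi = dist.cdf(np.minimum(edges[1:], scenario.d_max_um))
        norm_mass = dist.cdf(scenario.d_max_um) - dist.cdf(scenario.d_min_um)
        bin_counts = n_total_per_m3 * np.clip(hi - lo, 0.0, None) / norm_mass
    spectrum = OpcSpectrum(
        bin_edges_um=tuple(edges.tolist()),
        number_per_cm3=tuple((bin_counts / 1e6).tolist()),  # per m³ → per cm³
        density_g_cm3=cfg.particle_density_g_cm3,
    )
    return gains, spectrum


def save_stub(stub: StubImageSet, outdir, image_format: str = "png") -> None:
    """Write tiles, the truth table and the scenario file to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tile in stub.tiles:
        Image.fromarray(tile.pixels).save(outdir / f"tile_{tile.tile_index:03d}.{image_format}")
    stub.truth.to_csv(outdir / "truth.csv", index=False)
    scenario_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(stub.scenario).items()}
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(scenario_dict, sort_keys=True))
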