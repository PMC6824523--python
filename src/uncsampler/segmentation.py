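"""Particle detection on SEM tile images.

Tiles are thresholded independently with the maximum-Rényi-entropy
automatic threshold (the Sahoo-type three-order combination rule used by
the standard auto-threshold implementations), binarized with the bright
class as foreground (backscatter imaging: mineral particles on a carbon
background), labelled by 8-connectivity, and converted to physical areas.
Components outside the 0.41–10000 µm² window are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.measure import label, regionprops

from .config import SamplerConfig, default_config

log = logging.getLogger(__name__)

__all__ = [
    "SemTile",
    "ParticleRecord",
    "DegenerateHistogramError",
    "renyi_threshold",
    "extract_particles",
    "collect_stub",
    "load_tile",
    "particles_to_frame",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two populated grey levels."""


@dataclass(frozen=True)
class SemTile:
    """One SEM image tile with its physical scale."""

    pixels: np.ndarray          # 2-D integer grey levels
    pixel_side_um: float = 0.64
    tile_index: int = 0
    stub_id: str = "stub"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("tile pixels must be a non-empty 2-D array")
        if not self.pixel_side_um > 0:
            raise ValueError("pixel_side_um must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.size) * self.pixel_side_um**2

    def histogram(self, n_bins: int = 256) -> np.ndarray:
        return np.bincount(self.pixels.ravel().astype(np.int64), minlength=n_bins)


@dataclass(frozen=True)
class ParticleRecord:
    """One detected particle on one tile."""

    pixel_count: int
    area_um2: float
    centroid_rc: tuple
    tile_index: int
    stub_id: str


def _alpha_entropies(norm_histo: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Total two-class entropy vs. threshold for α = 1, 1/2, 2 (vectorized).

    Returns three arrays indexed by candidate threshold t; entries where a
    class is empty are NaN and never selected.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        # α → 1 (Shannon): -Σ (p/P) ln(p/P) = -S(t)/P + ln P with S = Σ p ln p
        plogp = np.where(norm_histo > 0, norm_histo * np.log(np.where(norm_histo > 0, norm_histo, 1.0)), 0.0)
        s_head = np.cumsum(plogp)
        s_tail = s_head[-1] - s_head
        ent1 = (-s_head / p1 + np.log(p1)) + (-s_tail / p2 + np.log(p2))

        # α = 1/2: term = 2, entropy = 2·ln(Σ√(p/P1) · Σ√(p/P2))
        sq_head = np.cumsum(np.sqrt(norm_histo))
        sq_tail = sq_head[-1] - sq_head
        prod_half = (sq_head / np.sqrt(p1)) * (sq_tail / np.sqrt(p2))
        ent_half = np.where(prod_half > 0, 2.0 * np.log(np.where(prod_half > 0, prod_half, 1.0)), 0.0)

        # α = 2: term = -1, entropy = -ln(Σ(p/P1)² · Σ(p/P2)²)
        s2_head = np.cumsum(norm_histo**2)
        s2_tail = s2_head[-1] - s2_head
        prod_two = (s2_head / p1**2) * (s2_tail / p2**2)
        ent_two = np.where(prod_two > 0, -np.log(np.where(prod_two > 0, prod_two, 1.0)), 0.0)

    return ent1, ent_half, ent_two


def _first_argmax(ent: np.ndarray, first_bin: int, last_bin: int) -> int:
    """First (lowest grey level) t in [first_bin, last_bin] with maximal
    entropy: strict improvement required, so ties break toward the lowest
    grey level; NaN entries are never selected."""
    best_t, best = first_bin, -np.inf
    for t in range(first_bin, last_bin + 1):
        v = ent[t]
        if np.isfinite(v) and v > best:
            best, best_t = float(v), t
    return best_t


def renyi_threshold(histogram) -> int:
    """Maximum-Rényi-entropy automatic threshold of a grey-level histogram.

    Computes the entropy-maximizing threshold for Rényi orders
    α = 1/2, 1 and 2 and combines the three estimates with the published
    β-weight rule; deterministic, ties broken toward the lowest grey
    level.  Foreground is conventionally the class above the returned
    level.

    Raises :class:`DegenerateHistogramError` when fewer than two grey
    levels are populated.
    """
    data = np.asarray(histogram, dtype=float)
    if data.ndim != 1 or data.size < 2:
        raise ValueError("histogram must be a 1-D array of at least 2 bins")
    if np.any(data < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(data) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 populated grey levels")

    total = data.sum()
    norm_histo = data / total
    p1 = np.cumsum(norm_histo)
    p2 = 1.0 - p1

    eps = 2.220446049250313e-16
    nonzero = np.nonzero(p1 > eps)[0]
    first_bin = int(nonzero[0])
    tail = np.nonzero(p2 > eps)[0]
    last_bin = int(tail[-1]) if tail.size else first_bin

    ent1, ent_half, ent_two = _alpha_entropies(norm_histo, p1, p2)
    t_star2 = _first_argmax(ent1, first_bin, last_bin)
    t_star1 = _first_argmax(ent_half, first_bin, last_bin)
    t_star3 = _first_argmax(ent_two, first_bin, last_bin)

    # sort the three estimates ascending
    if t_star2 < t_star1:
        t_star1, t_star2 = t_star2, t_star1
    if t_star3 < t_star2:
        t_star2, t_star3 = t_star3, t_star2
    if t_star2 < t_star1:
        t_star1, t_star2 = t_star2, t_star1

    # β weights: estimates within 5 grey levels are considered concordant
    if abs(t_star1 - t_star2) <= 5:
        if abs(t_star2 - t_star3) <= 5:
            beta1, beta2, beta3 = 1, 2, 1
        else:
            beta1, beta2, beta3 = 0, 1, 3
    else:
        if abs(t_star2 - t_star3) <= 5:
            beta1, beta2, beta3 = 3, 1, 0
        else:
            beta1, beta2, beta3 = 1, 2, 1

    omega = p1[t_star3] - p1[t_star1]
    opt = (
        t_star1 * (p1[t_star1] + 0.25 * omega * beta1)
        + 0.25 * t_star2 * omega * beta2
        + t_star3 * (p2[t_star3] + 0.25 * omega * beta3)
    )
    return int(math.floor(opt))


def extract_particles(tile: SemTile, cfg: SamplerConfig | None = None) -> list[ParticleRecord]:
    """Detect particles on one tile.

    Binarize at the Rényi-entropy threshold (bright class foreground by
    default), label connected components, convert pixel counts to µm²,
    and drop components outside [min_area_um2, max_area_um2].  A tile
    whose histogram is degenerate (blank-like, single grey level) yields
    an empty list with a logged warning rather than an error.
    """
    cfg = cfg or default_config()
    try:
        thr = renyi_threshold(tile.histogram())
    except DegenerateHistogramError:
        log.warning("tile %s/%d: degenerate histogram, treating as blank", tile.stub_id, tile.tile_index)
        return []

    if cfg.foreground_polarity == "bright":
        binary = tile.pixels > thr
    else:
        binary = tile.pixels <= thr

    # Blank-like guard: an automatic entropy threshold always splits the
    # histogram somewhere, so a tile with no real bright class gets cut
    # inside its background noise.  Such a split leaves the two class
    # means nearly equal; require a minimum grey-level contrast before
    # accepting any detection.
    if binary.any() and (~binary).any():
        contrast = float(tile.pixels[binary].mean()) - float(tile.pixels[~binary].mean())
        if contrast < cfg.min_class_contrast:
            log.warning(
                "tile %s/%d: class contrast %.1f below %.1f, treating as blank-like",
                tile.stub_id, tile.tile_index, contrast, cfg.min_class_contrast,
            )
            return []

    labelled = label(binary, connectivity=cfg.connectivity)
    px_area = tile.pixel_side_um**2
    records = []
    for region in regionprops(labelled):
        area_um2 = region.num_pixels * px_area
        if area_um2 < cfg.min_area_um2 or area_um2 > cfg.max_area_um2:
            continue
        records.append(
            ParticleRecord(
                pixel_count=int(region.num_pixels),
                area_um2=float(area_um2),
                centroid_rc=tuple(float(c) for c in region.centroid),
                tile_index=tile.tile_index,
                stub_id=tile.stub_id,
            )
        )
    return records


def collect_stub(tiles, cfg: SamplerConfig | None = None):
    """Run detection over all tiles of one stub.

    Returns ``(records, analyzed_area_mm2)``.  The analyzed area is the
    summed tile area, capped at the configured stub disc area (tiles at
    the stub rim image past the edge).  All tiles must share stub_id and
    pixel scale.
    """
    cfg = cfg or default_config()
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no tiles supplied")
    stub_ids = {t.stub_id for t in tiles}
    if len(stub_ids) > 1:
        raise ValueError(f"mixed stub_id in tile set: {sorted(stub_ids)}")
    scales = {t.pixel_side_um for t in tiles}
    if len(scales) > 1:
        raise ValueError(f"mixed pixel scales in tile set: {sorted(scales)}")

    records: list[ParticleRecord] = []
    for tile in tiles:
        records.extend(extract_particles(tile, cfg))

    analyzed_area_mm2 = min(sum(t.area_um2 for t in tiles) * 1e-6, cfg.stub_area_mm2)
    return records, analyzed_area_mm2


def load_tile(path, pixel_side_um: float = 0.64, tile_index: int = 0, stub_id: str | None = None) -> SemTile:
    """Read a grayscale TIFF/PNG tile from disk."""
    path = Path(path)
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return SemTile(
        pixels=arr,
        pixel_side_um=pixel_side_um,
        tile_index=tile_index,
        stub_id=stub_id or path.stem,
    )


def particles_to_frame(records) -> pd.DataFrame:
    """Particle table with units in the column names."""
    return pd.DataFrame(
        {
            "stub_id": [r.stub_id for r in records],
            "tile": [r.tile_index for r in records],
            "pixel_count": [r.pixel_count for r in records],
            "area_um2": [r.area_um2 for r in records],
            "centroid_row_px": [r.centroid_rc[0] for r in records],
            "centroid_col_px": [r.centroid_rc[1] for r in records],
        }
    )
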