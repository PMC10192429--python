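"""Mitotic-activity features (45 per patient).

Per tile: the mitosis detection count plus its ratios to epithelial-nuclei,
blue-ratio-nuclei and all-nuclei counts.  Per patient: the nine aggregation
statistics of the count and of each ratio, the proportion of tiles in eight
mitotic-count density bins, and a Nottingham-style proliferation score from
the hottest contiguous tile block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .aggregation import AGGREGATORS, aggregate
from .catalog import MITOSIS_BINS
from .config import FeatureConfig
from .datatypes import TileRecord

#: upper edges of the mitotic-count bins; the last bin is open-ended
_BIN_EDGES = (0, 2, 5, 10, 20, 50, 100)


def nucleus_centroids(label_mask: np.ndarray) -> np.ndarray:
    """(n, 2) integer-rounded (row, col) centroids of the labeled nuclei."""
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return np.empty((0, 2), dtype=int)
    com = ndimage.center_of_mass(label_mask > 0, label_mask, labels)
    return np.rint(np.asarray(com)).astype(int)


def blue_ratio_image(rgb: np.ndarray) -> np.ndarray:
    """Pixelwise blue-ratio transform emphasizing basophilic (nuclear) pixels.

    BR = (100 * B / (1 + R + G)) * (256 / (1 + R + G + B)).
    """
    rgb = rgb.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return (100.0 * b / (1.0 + r + g)) * (256.0 / (1.0 + r + g + b))


def blue_ratio_nuclei_count(tile: TileRecord, cfg: FeatureConfig | None = None) -> int:
    """Count nucleus-sized connected components of the thresholded blue-ratio map."""
    cfg = cfg or FeatureConfig()
    br = blue_ratio_image(tile.intensity)
    if np.ptp(br) == 0:
        return 0
    mask = br > threshold_otsu(br)
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum((areas >= cfg.blue_ratio_min_area_px)
                      & (areas <= cfg.blue_ratio_max_area_px)))


@dataclass
class MitosisTileStats:
    tile_id: str
    origin: tuple[int, int]
    tile_side_px: int
    mitotic_count: int
    epithelial_nuclei_count: int
    blue_ratio_count: int
    nuclei_count: int
    ratio_epithelial: float  # NaN when denominator 0 and count > 0
    ratio_blue_ratio: float
    ratio_all: float


def _safe_ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    return 0.0 if num == 0 else np.nan


def mitosis_tile_stats(tile: TileRecord, cfg: FeatureConfig | None = None
                       ) -> MitosisTileStats:
    cfg = cfg or FeatureConfig()
    k = len(tile.mitosis_points)
    cents = nucleus_centroids(tile.nuclei_mask)
    n_all = len(cents)
    n_epi = (int(tile.epithelium_mask[cents[:, 0], cents[:, 1]].sum())
             if n_all else 0)
    n_br = blue_ratio_nuclei_count(tile, cfg)
    return MitosisTileStats(
        tile_id=tile.tile_id,
        origin=tile.origin,
        tile_side_px=tile.shape[0],
        mitotic_count=k,
        epithelial_nuclei_count=n_epi,
        blue_ratio_count=n_br,
        nuclei_count=n_all,
        ratio_epithelial=_safe_ratio(k, n_epi),
        ratio_blue_ratio=_safe_ratio(k, n_br),
        ratio_all=_safe_ratio(k, n_all),
    )


def _row_major(tiles: list[MitosisTileStats]) -> list[MitosisTileStats]:
    return sorted(tiles, key=lambda t: (t.origin[0], t.origin[1], t.tile_id))


def proliferation_score(tiles: list[MitosisTileStats],
                        cfg: FeatureConfig | None = None) -> int:
    """Nottingham-style 1/2/3 proliferation score from the mitosis hotspot.

    The hotspot is the contiguous ``hotspot_block_tiles``-square block of the
    tile grid with the largest total mitosis count; the summed count is
    rescaled to the reference block area (2x2 canonical 2000-px tiles,
    approximately ten high-power fields) before applying the cutoffs.
    """
    cfg = cfg or FeatureConfig()
    if not tiles:
        return 1
    spacing = tiles[0].tile_side_px  # exhaustive tiling: spacing = tile side

    grid: dict[tuple[int, int], int] = {}
    for t in tiles:
        rc = (t.origin[0] // spacing, t.origin[1] // spacing)
        grid[rc] = grid.get(rc, 0) + t.mitotic_count
    rows = [rc[0] for rc in grid]
    cols = [rc[1] for rc in grid]
    k = cfg.hotspot_block_tiles
    ref_area = (cfg.hotspot_block_tiles * cfg.tile_side_px) ** 2
    if max(rows) - min(rows) < k and max(cols) - min(cols) < k:
        # whole slide fits inside one block: hotspot is the covered area
        best = sum(grid.values())
        block_area = len(grid) * spacing ** 2
    else:
        best = 0
        for r0 in range(min(rows) - k + 1, max(rows) + 1):
            for c0 in range(min(cols) - k + 1, max(cols) + 1):
                s = sum(grid.get((r0 + dr, c0 + dc), 0)
                        for dr in range(k) for dc in range(k))
                best = max(best, s)
        block_area = (k * spacing) ** 2
    scaled = best * ref_area / block_area
    c1, c2 = cfg.proliferation_cutoffs
    if scaled <= c1:
        return 1
    if scaled <= c2:
        return 2
    return 3


def mitosis_patient_features(tiles: list[MitosisTileStats],
                             cfg: FeatureConfig | None = None) -> dict[str, float]:
    """The 45 patient-level mitotic features (9 + 27 + 8 + 1)."""
    cfg = cfg or FeatureConfig()
    if not tiles:
        raise ValueError("at least one tile required")
    ordered = _row_major(tiles)
    counts = np.array([t.mitotic_count for t in ordered], dtype=float)
    out: dict[str, float] = {}
    for a in AGGREGATORS:
        out[f"count_{a}"] = aggregate(counts, a)
    for name, attr in (("epithelial", "ratio_epithelial"),
                       ("blue_ratio", "ratio_blue_ratio"), ("all", "ratio_all")):
        vals = np.array([getattr(t, attr) for t in ordered], dtype=float)
        vals = vals[~np.isnan(vals)]
        for a in AGGREGATORS:
            out[f"ratio_{name}_{a}"] = aggregate(vals, a) if vals.size else np.nan
    # proportion of tiles in each mitotic-count density bin
    edges = _BIN_EDGES
    props = np.zeros(len(MITOSIS_BINS))
    for c in counts:
        if c == 0:
            props[0] += 1
            continue
        for i, hi in enumerate(edges[1:], start=1):
            if c <= hi:
                props[i] += 1
                break
        else:
            props[len(edges)] += 1
    props /= len(counts)
    for b, p in zip(MITOSIS_BINS, props):
        out[f"count_bin_{b}"] = float(p)
    out["proliferation_score"] = float(proliferation_score(ordered, cfg))
    return out
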