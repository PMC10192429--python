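"""Extraction parameters shared by the three feature families."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class FeatureConfig:
    """Tunable constants of the feature extractor.

    ``tile_side_px`` is the canonical tumor-tile side (2000 px at x40,
    0.25 um per pixel); smaller tiles are accepted everywhere, the constant
    only anchors area-scaled quantities (proliferation hotspot).
    """

    microns_per_px: float = 0.25
    tile_side_px: int = 2000

    # cell cluster graph: edge (u,v) iff d_um^(-alpha) > r
    ccg_alpha: float = 0.5
    ccg_r: float = 0.16  # => edges for d < r^(-1/alpha) ~= 39 um

    # cell orientation entropy
    core_bins: int = 18  # 10-degree orientation bins over [0, pi)

    # Haralick texture
    glcm_levels: int = 32
    min_texture_area_px: int = 9  # nuclei below a 3x3 interior are skipped

    # nuclei
    min_nucleus_area_px: int = 3

    # blue-ratio nucleus counting
    blue_ratio_min_area_px: int = 3
    blue_ratio_max_area_px: int = 5000

    # proliferation score: hotspot block (in tiles) and Nottingham-style
    # cutoffs at the reference block area (2x2 tiles of tile_side_px)
    hotspot_block_tiles: int = 2
    proliferation_cutoffs: tuple[float, float] = (7.0, 14.0)  # <=c1 -> 1, <=c2 -> 2, else 3

    @property
    def ccg_distance_threshold_um(self) -> float:
        return self.ccg_r ** (-1.0 / self.ccg_alpha)
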