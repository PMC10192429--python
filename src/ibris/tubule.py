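"""Tubule-formation features (56 per patient).

Per tile: counts of nuclei on/off the tubule mask, the tubule area fraction,
and three ratios (tubule/non-tubule, tubule/epithelial, tubule/all nuclei).
Per patient: the nine aggregation statistics of each ratio (27) and of the
area fraction (9), plus the proportion of tiles in ten equal-width intervals
of the tubule/all ratio and of the area fraction (10 + 10).  Counts are
normalized to proportions so patients with different tile counts compare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregation import AGGREGATORS, aggregate
from .catalog import TUBULE_HIST_BINS
from .config import FeatureConfig
from .datatypes import TileRecord


@dataclass
class TubuleTileStats:
    tile_id: str
    tubule_nuclei_count: int
    non_tubule_nuclei_count: int
    epithelial_nuclei_count: int
    nuclei_count: int
    tubule_area_fraction: float
    ratio_non_tubule: float  # tubule / non-tubule nuclei; NaN if k/0 with k>0
    ratio_epithelial: float
    ratio_all: float


def _safe_ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    return 0.0 if num == 0 else np.nan


def tubule_tile_stats(tile: TileRecord, cfg: FeatureConfig | None = None
                      ) -> TubuleTileStats:
    cfg = cfg or FeatureConfig()
    from .mitosis import nucleus_centroids

    cents = nucleus_centroids(tile.nuclei_mask)
    n_all = len(cents)
    n_tub = int(tile.tubule_mask[cents[:, 0], cents[:, 1]].sum()) if n_all else 0
    n_epi = int(tile.epithelium_mask[cents[:, 0], cents[:, 1]].sum()) if n_all else 0
    tissue = tile.nuclei_mask.size  # tile area as the tissue reference
    return TubuleTileStats(
        tile_id=tile.tile_id,
        tubule_nuclei_count=n_tub,
        non_tubule_nuclei_count=n_all - n_tub,
        epithelial_nuclei_count=n_epi,
        nuclei_count=n_all,
        tubule_area_fraction=float(tile.tubule_mask.sum()) / tissue,
        ratio_non_tubule=_safe_ratio(n_tub, n_all - n_tub),
        ratio_epithelial=_safe_ratio(n_tub, n_epi),
        ratio_all=_safe_ratio(n_tub, n_all),
    )


def _interval_proportions(values: np.ndarray) -> np.ndarray:
    """Proportions over 10 equal-width [0,1] intervals, last bin closed."""
    idx = np.minimum((values * TUBULE_HIST_BINS).astype(int), TUBULE_HIST_BINS - 1)
    counts = np.bincount(idx, minlength=TUBULE_HIST_BINS).astype(float)
    return counts / len(values)


def tubule_patient_features(tiles: list[TubuleTileStats],
                            cfg: FeatureConfig | None = None) -> dict[str, float]:
    """The 56 patient-level tubule features (27 + 9 + 10 + 10)."""
    if not tiles:
        raise ValueError("at least one tile required")
    out: dict[str, float] = {}
    for name, attr in (("non_tubule", "ratio_non_tubule"),
                       ("epithelial", "ratio_epithelial"), ("all", "ratio_all")):
        vals = np.array([getattr(t, attr) for t in tiles], dtype=float)
        vals = vals[~np.isnan(vals)]
        for a in AGGREGATORS:
            out[f"ratio_{name}_{a}"] = aggregate(vals, a) if vals.size else np.nan
    frac = np.array([t.tubule_area_fraction for t in tiles], dtype=float)
    for a in AGGREGATORS:
        out[f"area_fraction_{a}"] = aggregate(frac, a)
    ratio_all = np.array([t.ratio_all for t in tiles], dtype=float)
    ratio_all = np.nan_to_num(ratio_all, nan=0.0)  # ratio_all NaN only if 0 nuclei
    for i, p in enumerate(_interval_proportions(np.clip(ratio_all, 0, 1))):
        out[f"ratio_all_hist_{i}"] = float(p)
    for i, p in enumerate(_interval_proportions(np.clip(frac, 0, 1))):
        out[f"area_fraction_hist_{i}"] = float(p)
    return out
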