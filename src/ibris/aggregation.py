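"""Tile -> patient aggregation and assembly of the 343-feature vector.

Nine aggregation statistics are available (mean, median, max, sum, SD,
skewness, kurtosis, histogram entropy, approximate entropy).  The nuclear
tile descriptors are aggregated by the mean across tiles; the full
nine-statistic scheme is applied within the mitotic and tubule families,
whose base-descriptor counts (9+27+8+1 = 45 and 27+9+20 = 56) together with
the 242 nuclear descriptors reproduce the 343-feature catalog exactly.

All moments are population moments; single-tile fallbacks: SD, skewness,
kurtosis and both entropies are 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from .catalog import AGGREGATORS, FeatureCatalog, default_catalog
from .config import FeatureConfig
from .datatypes import FeatureMatrix, PatientCase

__all__ = ["AGGREGATORS", "aggregate", "histogram_entropy", "approximate_entropy",
           "build_patient_vector", "extract_features"]

logger = logging.getLogger(__name__)


def histogram_entropy(values: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (nats) of the normalized histogram over [min, max]."""
    values = np.asarray(values, dtype=float)
    if values.size <= 1 or np.ptp(values) == 0:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log(p)))


def approximate_entropy(series: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Pincus approximate entropy with tolerance r = r_factor * SD(series).

    Computed on the series in its given (canonical row-major tile) order;
    constant or too-short series return 0.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    sd = np.std(x)
    if n <= m + 1 or sd == 0:
        return 0.0
    r = r_factor * sd

    def _phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return _phi(m) - _phi(m + 1)


def aggregate(values: np.ndarray, agg: str) -> float:
    """Apply one of the nine aggregation statistics to a non-empty series."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan
    if agg == "mean":
        return float(np.mean(v))
    if agg == "median":
        return float(np.median(v))
    if agg == "max":
        return float(np.max(v))
    if agg == "sum":
        return float(np.sum(v))
    if agg == "sd":
        return float(np.std(v))
    if agg == "skewness":
        return 0.0 if np.ptp(v) == 0 else float(sps.skew(v, bias=True))
    if agg == "kurtosis":
        return 0.0 if np.ptp(v) == 0 else float(sps.kurtosis(v, fisher=True, bias=True))
    if agg == "histogram_entropy":
        return histogram_entropy(v)
    if agg == "approximate_entropy":
        return approximate_entropy(v)
    raise ValueError(f"unknown aggregator {agg!r}")


def build_patient_vector(case: PatientCase, catalog: FeatureCatalog | None = None,
                         cfg: FeatureConfig | None = None) -> dict[str, float]:
    """The ordered 343-feature vector for one patient.

    Nuclear entries are the across-tile mean of each tile descriptor (tiles
    where a family is undefined are excluded from that family's mean);
    mitotic and tubule entries follow their modules.
    """
    from .mitosis import mitosis_patient_features, mitosis_tile_stats
    from .nuclear import nuclear_tile_vector
    from .tubule import tubule_patient_features, tubule_tile_stats

    catalog = catalog or default_catalog()
    cfg = cfg or FeatureConfig()
    if not case.tiles:
        raise ValueError(f"{case.patient_id}: no valid tiles")

    tile_vecs = [nuclear_tile_vector(t, cfg) for t in case.tiles]
    nuclear: dict[str, float] = {}
    for key in tile_vecs[0]:
        vals = np.array([tv[key] for tv in tile_vecs], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.debug("%s: feature %s undefined on every tile -> patient NA",
                         case.patient_id, key)
            nuclear[key] = np.nan
        else:
            nuclear[key] = float(np.mean(vals))

    mit = mitosis_patient_features([mitosis_tile_stats(t, cfg) for t in case.tiles], cfg)
    tub = tubule_patient_features([tubule_tile_stats(t, cfg) for t in case.tiles], cfg)

    out: dict[str, float] = {}
    for entry in catalog.entries:
        if entry.family == "nuclear":
            out[entry.name] = nuclear[entry.base]
        elif entry.family == "mitotic":
            key = entry.base if entry.aggregator == "none" else f"{entry.base.removeprefix('mitotic_')}_{entry.aggregator}"
            if entry.base == "mitotic_count":
                key = f"count_{entry.aggregator}"
            out[entry.name] = mit[key]
        else:
            key = entry.base if entry.aggregator == "none" else f"{entry.base}_{entry.aggregator}"
            out[entry.name] = tub[key]
    assert len(out) == len(catalog)
    return out


def extract_features(cohort: list[PatientCase], catalog: FeatureCatalog | None = None,
                     cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Run the full extractor over a cohort, in catalog column order."""
    catalog = catalog or default_catalog()
    rows = [build_patient_vector(case, catalog, cfg) for case in cohort]
    values = np.array([[r[n] for n in catalog.names] for r in rows], dtype=float)
    return FeatureMatrix([c.patient_id for c in cohort], catalog.names, values)
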