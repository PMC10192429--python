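"""The frozen, ordered catalog of the 343 patient-level features.

The score combines three histologic Nottingham axes measured computationally:
242 nuclear-morphology features, 45 mitotic-activity features and 56
tubule-formation features.  Each catalog entry records the feature's family,
the tile-level base descriptor it derives from, and the tile->patient
aggregation statistic applied to it.  The catalog order is the canonical
column order of every feature matrix, and its content hash is stored inside
locked models so a model can refuse to score a matrix built from a different
catalog version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterator

#: the nine tile->patient aggregation statistics
AGGREGATORS = (
    "mean",
    "median",
    "max",
    "sum",
    "sd",
    "skewness",
    "kurtosis",
    "histogram_entropy",
    "approximate_entropy",
)

#: per-nucleus shape descriptors (25): 16 scalars + 9 Fourier radial harmonics
SHAPE_DESCRIPTORS = (
    "area",
    "perimeter",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "elongation",
    "eccentricity",
    "solidity",
    "extent",
    "convexity",
    "circularity",
    "bending_energy",
    "radial_mean",
    "radial_sd",
    "radial_ratio",
    "boundary_smoothness",
) + tuple(f"fsd{k}" for k in range(1, 10))

#: the four summary statistics applied to shape descriptors across nuclei
SHAPE_STATS = ("mean", "sd", "median", "minmax_ratio")

_GRAPH_STATS = ("mean", "sd", "minmax_ratio", "disorder")

ARCHITECTURE_NAMES = tuple(
    [f"voronoi_{q}_{s}" for q in ("area", "perimeter", "chord") for s in _GRAPH_STATS]
    + [f"delaunay_{q}_{s}" for q in ("side", "area") for s in _GRAPH_STATS]
    + [f"mst_edge_{s}" for s in _GRAPH_STATS]
    + [f"knn{k}_{s}" for k in (3, 5, 7) for s in ("mean", "sd", "disorder")]
    + [f"nn_r{r}um_{s}" for r in (10, 20, 30, 40, 50) for s in ("mean", "sd", "disorder")]
    + ["density_value", "density_quadrant_sd", "density_quadrant_disorder"]
)

CCG_NAMES = (
    "node_count",
    "edge_count",
    "degree_mean",
    "degree_sd",
    "component_count",
    "giant_fraction",
    "isolated_fraction",
    "eccentricity_mean",
    "eccentricity_sd",
    "diameter",
    "radius",
    "clustering_mean",
    "transitivity",
    "path_length_mean",
    "path_length_sd",
    "assortativity",
    "component_size_mean",
    "component_size_disorder",
    "triangle_count",
    "edge_length_mean",
    "edge_length_sd",
    "edge_length_disorder",
    "kcore_max",
    "spectral_radius",
    "algebraic_connectivity",
    "betweenness_mean",
)

#: the 13 second-order co-occurrence statistics (Haralick set); "contrast_*"
#: are difference-distribution moments, "intensity_*" sum-distribution moments
COOCCURRENCE_STATS = (
    "energy",
    "entropy",
    "contrast",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "correlation",
    "info_measure_1",
    "info_measure_2",
)

CORE_STATS = ("mean", "sd", "disorder")

#: mitotic-count density bins: proportion of tiles whose count falls in each
MITOSIS_BINS = ("0", "1_2", "3_5", "6_10", "11_20", "21_50", "51_100", "gt100")

MITOSIS_RATIOS = ("epithelial", "blue_ratio", "all")
TUBULE_RATIOS = ("non_tubule", "epithelial", "all")
TUBULE_HIST_BINS = 10


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    family: str  # nuclear | mitotic | tubule
    base: str  # tile-level base descriptor
    aggregator: str  # tile->patient statistic ("none" for direct patient stats)


def _nuclear_entries() -> Iterator[CatalogEntry]:
    for d in SHAPE_DESCRIPTORS:
        for s in SHAPE_STATS:
            yield CatalogEntry(f"nuc:shape_{d}_{s}", "nuclear", f"shape_{d}_{s}", "mean")
    for n in ARCHITECTURE_NAMES:
        yield CatalogEntry(f"nuc:arch_{n}", "nuclear", f"arch_{n}", "mean")
    for n in CCG_NAMES:
        yield CatalogEntry(f"nuc:ccg_{n}", "nuclear", f"ccg_{n}", "mean")
    for st in COOCCURRENCE_STATS:
        for s in CORE_STATS:
            yield CatalogEntry(f"nuc:core_{st}_{s}", "nuclear", f"core_{st}_{s}", "mean")
    for st in COOCCURRENCE_STATS:
        for s in ("mean", "sd"):
            yield CatalogEntry(f"nuc:haralick_{st}_{s}", "nuclear", f"haralick_{st}_{s}", "mean")


def _mitotic_entries() -> Iterator[CatalogEntry]:
    for a in AGGREGATORS:
        yield CatalogEntry(f"mit:count_{a}", "mitotic", "mitotic_count", a)
    for r in MITOSIS_RATIOS:
        for a in AGGREGATORS:
            yield CatalogEntry(f"mit:ratio_{r}_{a}", "mitotic", f"ratio_{r}", a)
    for b in MITOSIS_BINS:
        yield CatalogEntry(f"mit:bin_{b}", "mitotic", f"count_bin_{b}", "none")
    yield CatalogEntry("mit:proliferation_score", "mitotic", "proliferation_score", "none")


def _tubule_entries() -> Iterator[CatalogEntry]:
    for r in TUBULE_RATIOS:
        for a in AGGREGATORS:
            yield CatalogEntry(f"tub:ratio_{r}_{a}", "tubule", f"ratio_{r}", a)
    for a in AGGREGATORS:
        yield CatalogEntry(f"tub:area_fraction_{a}", "tubule", "area_fraction", a)
    for i in range(TUBULE_HIST_BINS):
        yield CatalogEntry(f"tub:ratio_all_hist_{i}", "tubule", f"ratio_all_hist_{i}", "none")
    for i in range(TUBULE_HIST_BINS):
        yield CatalogEntry(
            f"tub:area_fraction_hist_{i}", "tubule", f"area_fraction_hist_{i}", "none"
        )


class FeatureCatalog:
    """Ordered, versioned list of the 343 patient-level feature definitions."""

    FAMILY_SIZES = {"nuclear": 242, "mitotic": 45, "tubule": 56}

    def __init__(self) -> None:
        self.entries: tuple[CatalogEntry, ...] = tuple(
            list(_nuclear_entries()) + list(_mitotic_entries()) + list(_tubule_entries())
        )
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("catalog contains duplicated feature names")
        counts = {f: sum(1 for e in self.entries if e.family == f) for f in self.FAMILY_SIZES}
        if counts != self.FAMILY_SIZES:
            raise ValueError(f"catalog family sizes {counts} != {self.FAMILY_SIZES}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def family_of(self, name: str) -> str:
        try:
            return self._by_name[name].family
        except AttributeError:
            self._by_name = {e.name: e for e in self.entries}
            return self._by_name[name].family

    def family_names(self, family: str) -> list[str]:
        return [e.name for e in self.entries if e.family == family]

    def version_hash(self) -> str:
        payload = json.dumps(
            [[e.name, e.family, e.base, e.aggregator] for e in self.entries]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_records(self) -> list[dict]:
        return [
            {"name": e.name, "family": e.family, "base": e.base, "aggregator": e.aggregator}
            for e in self.entries
        ]


_DEFAULT: FeatureCatalog | None = None


def default_catalog() -> FeatureCatalog:
    """Return the shared catalog instance (construction is cheap but hashed)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FeatureCatalog()
    return _DEFAULT
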