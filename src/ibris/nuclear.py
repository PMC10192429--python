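"""Nuclear-morphology tile descriptors (242 per tile).

Five families measured on the nuclei label mask and the underlying H&E
raster:

* shape — 25 per-nucleus boundary descriptors summarized across nuclei by
  {mean, SD, median, min/max ratio} (100 values);
* architecture — Voronoi / Delaunay / minimum-spanning-tree and nearest-
  neighbor statistics of the centroid point pattern (51);
* cell cluster graph (CCG) — metrics of a sparse distance-thresholded graph
  over centroids (26);
* cell orientation entropy (CORE) — second-order statistics of co-occurring
  nuclear orientations within CCG neighborhoods (39);
* Haralick texture — gray-level co-occurrence statistics of chromatin inside
  each nucleus (26).

Degenerate tiles (fewer than 4 nuclei, or no CCG edges) yield NaN for the
affected family; the patient-level aggregation excludes those tiles rather
than zero-filling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components as cs_components
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi, cKDTree
from skimage.measure import find_contours, perimeter as mask_perimeter

from .catalog import (ARCHITECTURE_NAMES, CCG_NAMES, COOCCURRENCE_STATS, CORE_STATS,
                      SHAPE_DESCRIPTORS, SHAPE_STATS)
from .config import FeatureConfig
from .datatypes import TileRecord

_EPS = 1e-12

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small statistics helpers (population moments throughout)

def _sd(x: np.ndarray) -> float:
    return float(np.std(x))


def disorder(x: np.ndarray) -> float:
    """Normalized dispersion SD/(mean+SD); 0 for an empty or constant input."""
    m, s = float(np.mean(x)), float(np.std(x))
    return s / (m + s) if (m + s) != 0 else 0.0


def _minmax_ratio(x: np.ndarray) -> float:
    mx = float(np.max(x))
    return float(np.min(x)) / mx if mx != 0 else 0.0


def _stats4(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, min/max ratio, disorder) of a non-empty sample."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (np.nan,) * 4
    return float(np.mean(x)), _sd(x), _minmax_ratio(x), disorder(x)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an RGB uint8 raster, as float in [0, 255]."""
    rgb = rgb.astype(float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


# ---------------------------------------------------------------------------
# per-nucleus shape

@dataclass
class NucleusDescriptor:
    label: int
    centroid: tuple[float, float]  # (x, y) px
    area: float
    orientation: float  # major-axis angle vs x-axis, in [0, pi)
    mean_intensity: float
    boundary: np.ndarray  # (n, 2) global (x, y) contour
    values: dict[str, float] = field(default_factory=dict)  # 25 shape descriptors


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced by arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(t, s, closed[:, 0])
    out[:, 1] = np.interp(t, s, closed[:, 1])
    return out


def _circ_neighbors(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nxt = np.concatenate([p[1:], p[:1]])
    prv = np.concatenate([p[-1:], p[:-1]])
    return nxt, prv


def _bending_energy(p: np.ndarray) -> float:
    """Mean squared curvature along the arc-length-resampled boundary."""
    nxt, prv = _circ_neighbors(p)
    d1 = (nxt - prv) / 2.0
    d2 = nxt - 2 * p + prv
    num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5 + _EPS
    return float(np.mean((num / den) ** 2))


def describe_nuclei(tile: TileRecord, cfg: FeatureConfig | None = None
                    ) -> list[NucleusDescriptor]:
    """One shape descriptor record per labeled nucleus (tiny labels dropped).

    Geometry comes from central second moments of the pixel coordinates
    (axis lengths 4*sqrt(eigenvalue), matching the filled-ellipse convention)
    and from the 0.5-level marching-squares boundary contour.
    """
    cfg = cfg or FeatureConfig()
    lum = luminance(tile.intensity)
    mask = tile.nuclei_mask
    out: list[NucleusDescriptor] = []
    for label, sl in enumerate(ndimage.find_objects(mask), start=1):
        if sl is None:
            continue
        crop = mask[sl] == label
        area = int(crop.sum())
        if area < cfg.min_nucleus_area_px:
            logger.debug("%s: nucleus label %d discarded (area %d px < %d)",
                         tile.tile_id, label, area, cfg.min_nucleus_area_px)
            continue
        ys, xs = np.nonzero(crop)
        minr, minc = sl[0].start, sl[1].start
        cy_l, cx_l = ys.mean(), xs.mean()
        cx, cy = cx_l + minc, cy_l + minr
        dx, dy = xs - cx_l, ys - cy_l
        # pixel-grid covariance with the 1/12 per-pixel correction
        mxx = float(np.mean(dx * dx)) + 1.0 / 12.0
        myy = float(np.mean(dy * dy)) + 1.0 / 12.0
        mxy = float(np.mean(dx * dy))
        tr, det = mxx + myy, mxx * myy - mxy * mxy
        disc = math.sqrt(max(tr * tr / 4.0 - det, 0.0))
        l1, l2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 0.0)
        major, minor = 4.0 * math.sqrt(l1), 4.0 * math.sqrt(l2)
        ecc = math.sqrt(max(1.0 - l2 / l1, 0.0)) if l1 > 0 else 0.0
        # angle of the major axis vs the x (column) axis in [0, pi), in the
        # rotation sense used when rasterizing (row, col) ellipses
        theta = 0.0 if ecc == 0 else (0.5 * math.atan2(-2.0 * mxy, mxx - myy)) % math.pi

        perim = float(max(mask_perimeter(crop), _EPS))
        contours = find_contours(np.pad(crop, 1).astype(float), 0.5)
        if not contours:
            continue
        cont = max(contours, key=len)
        boundary = np.column_stack([cont[:, 1] + minc - 1, cont[:, 0] + minr - 1])
        try:
            hull = ConvexHull(boundary)
            convex_perim = float(hull.area)  # 2-d hull "area" is its perimeter
            hull_area = float(hull.volume)
        except QhullError:
            convex_perim, hull_area = perim, float(area)
        r = np.hypot(boundary[:, 0] - cx, boundary[:, 1] - cy)
        r_max = float(np.max(r))
        r_nxt = np.concatenate([r[1:], r[:1]])
        r_prv = np.concatenate([r[-1:], r[:-1]])
        smooth = float(np.mean(np.abs(r - (r_prv + r_nxt) / 2.0)))
        # Fourier magnitudes of the arc-length-resampled radial signature,
        # harmonics 1..9 normalized by the DC term (size-invariant)
        resampled = _resample_closed(boundary, 32)
        rs = np.hypot(resampled[:, 0] - cx, resampled[:, 1] - cy)
        F = np.abs(np.fft.rfft(rs))
        fsd = F[1:10] / (F[0] + _EPS)

        vals = {
            "area": float(area),
            "perimeter": perim,
            "equivalent_diameter": math.sqrt(4.0 * area / math.pi),
            "major_axis": major,
            "minor_axis": minor,
            "elongation": major / minor if minor > 0 else 1.0,
            "eccentricity": ecc,
            "solidity": area / hull_area if hull_area > 0 else 1.0,
            "extent": area / crop.size,
            "convexity": convex_perim / perim,
            "circularity": 4.0 * math.pi * area / perim ** 2,
            "bending_energy": _bending_energy(resampled),
            "radial_mean": float(np.mean(r)),
            "radial_sd": _sd(r),
            "radial_ratio": float(np.min(r)) / r_max if r_max > 0 else 0.0,
            "boundary_smoothness": smooth,
        }
        for k in range(9):
            vals[f"fsd{k + 1}"] = float(fsd[k])
        out.append(NucleusDescriptor(
            label=label, centroid=(float(cx), float(cy)), area=float(area),
            orientation=theta, mean_intensity=float(lum[sl][crop].mean()),
            boundary=boundary, values=vals))
    return out


def shape_tile_features(descriptors: list[NucleusDescriptor]) -> dict[str, float]:
    """Summarize the 25 shape descriptors across nuclei (4 statistics each)."""
    out: dict[str, float] = {}
    for d in SHAPE_DESCRIPTORS:
        if descriptors:
            v = np.array([n.values[d] for n in descriptors])
            stats = {"mean": float(np.mean(v)), "sd": _sd(v),
                     "median": float(np.median(v)), "minmax_ratio": _minmax_ratio(v)}
        else:
            stats = {s: np.nan for s in SHAPE_STATS}
        for s in SHAPE_STATS:
            out[f"shape_{d}_{s}"] = stats[s]
    return out


# ---------------------------------------------------------------------------
# global architecture (Voronoi / Delaunay / MST / neighborhood)

def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _polygon_perimeter(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def architecture_features(centroids: np.ndarray, tile_shape: tuple[int, int],
                          cfg: FeatureConfig | None = None) -> dict[str, float]:
    """51 point-pattern statistics of nuclear centroids (distances in um)."""
    cfg = cfg or FeatureConfig()
    na = {f"arch_{n}": np.nan for n in ARCHITECTURE_NAMES}
    pts_px = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(pts_px)
    if n < 4:
        return na
    pts = pts_px * cfg.microns_per_px
    out: dict[str, float] = {}

    try:
        vor = Voronoi(pts)
        tri = Delaunay(pts)
    except QhullError:
        return na  # collinear / degenerate pattern

    # Voronoi: boundary-open cells (touching infinity) excluded
    areas, perims, chords = [], [], []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue
        poly = vor.vertices[region]
        areas.append(_polygon_area(poly))
        perims.append(_polygon_perimeter(poly))
        diff = poly[:, None, :] - poly[None, :, :]
        chords.append(float(np.sqrt((diff ** 2).sum(-1)).max()))
    for q, v in (("area", areas), ("perimeter", perims), ("chord", chords)):
        for s, val in zip(("mean", "sd", "minmax_ratio", "disorder"), _stats4(np.array(v))):
            out[f"arch_voronoi_{q}_{s}"] = val

    # Delaunay edges and triangles
    edges = set()
    tri_areas = []
    for simplex in tri.simplices:
        a, b, c = sorted(simplex)
        edges.update([(a, b), (a, c), (b, c)])
        p = pts[simplex]
        tri_areas.append(_polygon_area(p))
    e_idx = np.array(sorted(edges))
    side_len = np.linalg.norm(pts[e_idx[:, 0]] - pts[e_idx[:, 1]], axis=1)
    for q, v in (("side", side_len), ("area", np.array(tri_areas))):
        for s, val in zip(("mean", "sd", "minmax_ratio", "disorder"), _stats4(v)):
            out[f"arch_delaunay_{q}_{s}"] = val

    # Euclidean MST (a subgraph of the Delaunay graph)
    g = sparse.coo_matrix((side_len, (e_idx[:, 0], e_idx[:, 1])), shape=(n, n))
    mst = minimum_spanning_tree(g.tocsr())
    mst_len = mst.data
    for s, val in zip(("mean", "sd", "minmax_ratio", "disorder"), _stats4(mst_len)):
        out[f"arch_mst_edge_{s}"] = val

    # k-nearest-neighbor distances and neighbor counts within fixed radii
    tree = cKDTree(pts)
    for k in (3, 5, 7):
        if n > k:
            d, _ = tree.query(pts, k=k + 1)
            dk = d[:, k]
            out[f"arch_knn{k}_mean"] = float(np.mean(dk))
            out[f"arch_knn{k}_sd"] = _sd(dk)
            out[f"arch_knn{k}_disorder"] = disorder(dk)
        else:
            for s in ("mean", "sd", "disorder"):
                out[f"arch_knn{k}_{s}"] = np.nan
    for r in (10, 20, 30, 40, 50):
        counts = np.array(tree.query_ball_point(pts, r, return_length=True)) - 1.0
        out[f"arch_nn_r{r}um_mean"] = float(np.mean(counts))
        out[f"arch_nn_r{r}um_sd"] = _sd(counts)
        out[f"arch_nn_r{r}um_disorder"] = disorder(counts)

    # nuclear density overall and over 2x2 quadrants
    h_um = tile_shape[0] * cfg.microns_per_px
    w_um = tile_shape[1] * cfg.microns_per_px
    out["arch_density_value"] = n / (h_um * w_um)
    qc = np.zeros(4)
    half_r, half_c = tile_shape[0] / 2.0, tile_shape[1] / 2.0
    qi = (pts_px[:, 1] >= half_r).astype(int) * 2 + (pts_px[:, 0] >= half_c).astype(int)
    for i in range(4):
        qc[i] = np.sum(qi == i)
    qdens = qc / (h_um * w_um / 4.0)
    out["arch_density_quadrant_sd"] = _sd(qdens)
    out["arch_density_quadrant_disorder"] = disorder(qdens)
    return out


# ---------------------------------------------------------------------------
# cell cluster graph

def ccg_edges(centroids: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Deterministic CCG edge set: (u, v) iff d_um^(-alpha) > r."""
    cfg = cfg or FeatureConfig()
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2) * cfg.microns_per_px
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cfg.ccg_distance_threshold_um, output_type="ndarray")
    return pairs.reshape(-1, 2)


def ccg_features(centroids: np.ndarray, cfg: FeatureConfig | None = None,
                 edges: np.ndarray | None = None) -> dict[str, float]:
    """26 graph metrics of the cell cluster graph."""
    cfg = cfg or FeatureConfig()
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        return {f"ccg_{m}": np.nan for m in CCG_NAMES}
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate point pattern: all centroids identical")
    if edges is None:
        edges = ccg_edges(pts, cfg)
    m = len(edges)

    A = np.zeros((n, n))
    if m:
        A[edges[:, 0], edges[:, 1]] = 1.0
        A[edges[:, 1], edges[:, 0]] = 1.0
    deg = A.sum(axis=1)

    n_comp, comp_label = cs_components(sparse.csr_matrix(A), directed=False)
    comp_sizes = np.bincount(comp_label).astype(float)
    giant_label = int(np.argmax(comp_sizes))
    gi = np.nonzero(comp_label == giant_label)[0]

    out: dict[str, float] = {
        "ccg_node_count": float(n),
        "ccg_edge_count": float(m),
        "ccg_degree_mean": float(deg.mean()),
        "ccg_degree_sd": _sd(deg),
        "ccg_component_count": float(n_comp),
        "ccg_giant_fraction": len(gi) / n,
        "ccg_isolated_fraction": float(np.mean(deg == 0)),
        "ccg_component_size_mean": float(comp_sizes.mean()),
        "ccg_component_size_disorder": disorder(comp_sizes),
    }

    if m == 0:
        for k in ("eccentricity_mean", "eccentricity_sd", "diameter", "radius",
                  "clustering_mean", "transitivity", "path_length_mean",
                  "path_length_sd", "assortativity", "triangle_count",
                  "edge_length_mean", "edge_length_sd", "edge_length_disorder",
                  "kcore_max", "spectral_radius", "algebraic_connectivity",
                  "betweenness_mean"):
            out[f"ccg_{k}"] = 0.0
        return out

    # eccentricities within each node's own component; path statistics and
    # diameter/radius on the giant component
    D = shortest_path(sparse.csr_matrix(A), method="D", unweighted=True)
    finite = np.where(np.isfinite(D), D, -np.inf)
    ecc = finite.max(axis=1)
    out["ccg_eccentricity_mean"] = float(ecc.mean())
    out["ccg_eccentricity_sd"] = _sd(ecc)
    Dg = D[np.ix_(gi, gi)]
    ecc_g = Dg.max(axis=1)
    out["ccg_diameter"] = float(ecc_g.max())
    out["ccg_radius"] = float(ecc_g.min())
    pl = Dg[np.triu_indices(len(gi), k=1)]
    out["ccg_path_length_mean"] = float(pl.mean()) if pl.size else 0.0
    out["ccg_path_length_sd"] = _sd(pl) if pl.size else 0.0

    # clustering / transitivity / triangles from powers of the adjacency
    A2 = A @ A
    tri_node = np.einsum("ij,ij->i", A2, A) / 2.0  # triangles through each node
    possible = deg * (deg - 1) / 2.0
    clust = np.divide(tri_node, possible, out=np.zeros(n), where=possible > 0)
    out["ccg_clustering_mean"] = float(clust.mean())
    denom = float(possible.sum() * 2.0)
    out["ccg_transitivity"] = float(tri_node.sum() * 2.0 / denom) if denom > 0 else 0.0
    out["ccg_triangle_count"] = float(tri_node.sum() / 3.0)

    # degree assortativity: Pearson correlation of remaining-degree pairs
    du, dv = deg[edges[:, 0]], deg[edges[:, 1]]
    a = np.concatenate([du, dv]) - 1
    b = np.concatenate([dv, du]) - 1
    if a.std() > 0 and b.std() > 0:
        out["ccg_assortativity"] = float(np.corrcoef(a, b)[0, 1])
    else:
        out["ccg_assortativity"] = 0.0

    elen = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1) * cfg.microns_per_px
    out["ccg_edge_length_mean"] = float(elen.mean())
    out["ccg_edge_length_sd"] = _sd(elen)
    out["ccg_edge_length_disorder"] = disorder(elen)

    # max core number = degeneracy: peel the minimum-degree vertex repeatedly
    alive = np.ones(n, dtype=bool)
    d = deg.copy()
    kmax = 0
    for _ in range(n):
        idx = np.nonzero(alive)[0]
        v = idx[np.argmin(d[idx])]
        kmax = max(kmax, int(d[v]))
        alive[v] = False
        nb = (A[v] > 0) & alive
        d[nb] -= 1
    out["ccg_kcore_max"] = float(kmax)

    out["ccg_spectral_radius"] = float(np.linalg.eigvalsh(A).max())
    if len(gi) >= 2:
        Ag = A[np.ix_(gi, gi)]
        L = np.diag(Ag.sum(1)) - Ag
        out["ccg_algebraic_connectivity"] = float(np.sort(np.linalg.eigvalsh(L))[1])
    else:
        out["ccg_algebraic_connectivity"] = 0.0

    # betweenness (normalized as a fraction of pairs), via igraph's C core
    g = igraph.Graph(n=n, edges=[(int(u), int(v)) for u, v in edges])
    bc = np.asarray(g.betweenness())
    if n > 2:
        bc *= 2.0 / ((n - 1) * (n - 2))
    out["ccg_betweenness_mean"] = float(bc.mean())
    return out


# ---------------------------------------------------------------------------
# second-order co-occurrence statistics (shared by CORE and Haralick)

_IDX_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _index_cache(K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if K not in _IDX_CACHE:
        i = np.arange(K)
        diff = np.abs(i[:, None] - i[None, :])
        ssum = i[:, None] + i[None, :]
        _IDX_CACHE[K] = (diff, diff.ravel(), ssum.ravel())
    return _IDX_CACHE[K]


def cooccurrence_stats(P: np.ndarray) -> dict[str, float]:
    """The 13 second-order statistics of a normalized co-occurrence matrix.

    ``contrast_*`` are moments of the difference distribution p_{|i-j|},
    ``intensity_*`` of the sum distribution p_{i+j}.  Natural logarithms.
    """
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    tot = P.sum()
    if tot <= 0:
        return {s: 0.0 for s in COOCCURRENCE_STATS}
    P = P / tot
    i = np.arange(K)
    px, py = P.sum(1), P.sum(0)
    nz = P > 0

    diff, diff_flat, sum_flat = _index_cache(K)
    p_diff = np.bincount(diff_flat, weights=P.ravel(), minlength=K)
    p_sum = np.bincount(sum_flat, weights=P.ravel(), minlength=2 * K - 1)

    def _ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    ca = float(np.sum(np.arange(K) * p_diff))
    ia = float(np.sum(np.arange(2 * K - 1) * p_sum))
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    s_x = math.sqrt(max(float(np.sum((i - mu_x) ** 2 * px)), 0.0))
    s_y = math.sqrt(max(float(np.sum((i - mu_y) ** 2 * py)), 0.0))
    cov = float(np.sum(i[:, None] * i[None, :] * P)) - mu_x * mu_y

    HXY = _ent(P.ravel())
    HX, HY = _ent(px), _ent(py)
    pxy = px[:, None] * py[None, :]
    HXY1 = float(-np.sum(P[nz] * np.log(pxy[nz] + _EPS)))
    pp = pxy[pxy > 0]
    HXY2 = float(-np.sum(pp * np.log(pp)))

    return {
        "energy": float(np.sum(P ** 2)),
        "entropy": HXY,
        "contrast": float(np.sum(diff ** 2 * P)),
        "contrast_inverse_moment": float(np.sum(P / (1.0 + diff ** 2))),
        "contrast_average": ca,
        "contrast_variance": float(np.sum((np.arange(K) - ca) ** 2 * p_diff)),
        "contrast_entropy": _ent(p_diff),
        "intensity_average": ia,
        "intensity_variance": float(np.sum((np.arange(2 * K - 1) - ia) ** 2 * p_sum)),
        "intensity_entropy": _ent(p_sum),
        "correlation": cov / (s_x * s_y) if s_x * s_y > 0 else 0.0,
        "info_measure_1": (HXY - HXY1) / max(HX, HY) if max(HX, HY) > 0 else 0.0,
        "info_measure_2": math.sqrt(max(1.0 - math.exp(-2.0 * (HXY2 - HXY)), 0.0)),
    }


# ---------------------------------------------------------------------------
# cell orientation entropy

def core_features(orientations: np.ndarray, edges: np.ndarray,
                  cfg: FeatureConfig | None = None) -> dict[str, float]:
    """39 CORE statistics over CCG neighborhoods.

    Orientations are binned relative to each neighborhood's central nucleus,
    so rotating every nucleus by the same angle leaves the features unchanged.
    """
    cfg = cfg or FeatureConfig()
    na = {f"core_{st}_{s}": np.nan for st in COOCCURRENCE_STATS for s in CORE_STATS}
    theta = np.asarray(orientations, dtype=float)
    if len(edges) == 0:
        return na
    B = cfg.core_bins
    n = len(theta)
    eu, ev = edges[:, 0], edges[:, 1]
    in_hood = np.zeros(n, dtype=bool)

    per_stat: dict[str, list[float]] = {st: [] for st in COOCCURRENCE_STATS}
    nbr_lists: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        nbr_lists[u].append(int(v))
        nbr_lists[v].append(int(u))
    for c in range(n):
        if not nbr_lists[c]:
            continue
        hood = nbr_lists[c] + [c]
        in_hood[hood] = True
        sub = in_hood[eu] & in_hood[ev]
        in_hood[hood] = False
        if not sub.any():
            continue
        bi = (np.mod(theta[eu[sub]] - theta[c], math.pi) / math.pi * B).astype(int) % B
        bj = (np.mod(theta[ev[sub]] - theta[c], math.pi) / math.pi * B).astype(int) % B
        P = np.zeros((B, B))
        np.add.at(P, (bi, bj), 1.0)
        np.add.at(P, (bj, bi), 1.0)
        stats = cooccurrence_stats(P)
        for st in COOCCURRENCE_STATS:
            per_stat[st].append(stats[st])

    if not per_stat[COOCCURRENCE_STATS[0]]:
        return na
    out: dict[str, float] = {}
    for st in COOCCURRENCE_STATS:
        v = np.array(per_stat[st])
        out[f"core_{st}_mean"] = float(v.mean())
        out[f"core_{st}_sd"] = _sd(v)
        out[f"core_{st}_disorder"] = disorder(v)
    return out


# ---------------------------------------------------------------------------
# Haralick chromatin texture

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_of_mask(levels_img: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric, offset-averaged GLCM restricted to pixels inside ``mask``."""
    P = np.zeros((n_levels, n_levels))
    h, w = levels_img.shape
    for dr, dc in _GLCM_OFFSETS:
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        a = levels_img[r0a:r1a, c0a:c1a]
        b = levels_img[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        ma = mask[r0a:r1a, c0a:c1a] & mask[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        if not ma.any():
            continue
        idx = a[ma].astype(int) * n_levels + b[ma].astype(int)
        counts = np.bincount(idx, minlength=n_levels * n_levels)
        M = counts.reshape(n_levels, n_levels).astype(float)
        P += M + M.T
    return P


def haralick_nuclear(tile: TileRecord, cfg: FeatureConfig | None = None
                     ) -> dict[str, float]:
    """26 chromatin-texture values: 13 GLCM statistics x {mean, SD} over nuclei."""
    cfg = cfg or FeatureConfig()
    lum = luminance(tile.intensity)
    levels = np.clip((lum / 256.0 * cfg.glcm_levels).astype(int), 0, cfg.glcm_levels - 1)
    per_nucleus: list[dict[str, float]] = []
    for label, sl in enumerate(ndimage.find_objects(tile.nuclei_mask), start=1):
        if sl is None:
            continue
        mask = tile.nuclei_mask[sl] == label
        if mask.sum() < cfg.min_texture_area_px:
            continue
        P = glcm_of_mask(levels[sl], mask, cfg.glcm_levels)
        if P.sum() == 0:
            continue
        per_nucleus.append(cooccurrence_stats(P / P.sum()))
    out: dict[str, float] = {}
    for st in COOCCURRENCE_STATS:
        if per_nucleus:
            v = np.array([p[st] for p in per_nucleus])
            out[f"haralick_{st}_mean"] = float(v.mean())
            out[f"haralick_{st}_sd"] = _sd(v)
        else:
            out[f"haralick_{st}_mean"] = np.nan
            out[f"haralick_{st}_sd"] = np.nan
    return out


# ---------------------------------------------------------------------------
# assembled tile vector

def nuclear_tile_vector(tile: TileRecord, cfg: FeatureConfig | None = None
                        ) -> dict[str, float]:
    """The 242 nuclear tile descriptors in catalog order (NaN = family NA)."""
    cfg = cfg or FeatureConfig()
    desc = describe_nuclei(tile, cfg)
    out = shape_tile_features(desc)
    centroids = np.array([d.centroid for d in desc]).reshape(-1, 2)
    out.update(architecture_features(centroids, tile.shape, cfg))
    if len(desc) >= 2:
        edges = ccg_edges(centroids, cfg)
        out.update(ccg_features(centroids, cfg, edges=edges))
        out.update(core_features(np.array([d.orientation for d in desc]), edges, cfg))
    else:
        out.update({f"ccg_{m}": np.nan for m in CCG_NAMES})
        out.update({f"core_{st}_{s}": np.nan
                    for st in COOCCURRENCE_STATS for s in CORE_STATS})
    out.update(haralick_nuclear(tile, cfg))
    return out
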