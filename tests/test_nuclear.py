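"""Nuclear features: analytic shapes, graph oracles, invariances."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ibris.catalog import CCG_NAMES, COOCCURRENCE_STATS
from ibris.config import FeatureConfig
from ibris.nuclear import (architecture_features, ccg_edges, ccg_features,
                           cooccurrence_stats, core_features, describe_nuclei,
                           glcm_of_mask, haralick_nuclear, nuclear_tile_vector)

from conftest import draw_ellipse_mask, make_tile


# ---------------------------------------------------------------------------
# shape

def test_disc_shape_descriptors():
    mask = draw_ellipse_mask(64, 32, 32, 10, 10, 0.0)
    desc = describe_nuclei(make_tile(mask))
    assert len(desc) == 1
    v = desc[0].values
    assert v["circularity"] == pytest.approx(1.0, abs=0.05)
    assert v["eccentricity"] < 0.15
    assert v["area"] == pytest.approx(math.pi * 100, rel=0.05)
    assert v["solidity"] > 0.95
    assert v["elongation"] == pytest.approx(1.0, abs=0.1)


@pytest.mark.parametrize("angle", [0.3, 1.1, 2.4])
def test_two_to_one_ellipse_elongation_and_orientation(angle):
    mask = draw_ellipse_mask(96, 48, 48, 24, 12, angle)
    desc = describe_nuclei(make_tile(mask))
    v = desc[0].values
    assert v["elongation"] == pytest.approx(2.0, rel=0.06)
    drawn = angle % math.pi
    diff = abs(desc[0].orientation - drawn) % math.pi
    assert min(diff, math.pi - diff) < 0.08


def test_empty_mask_gives_empty_list():
    assert describe_nuclei(make_tile(np.zeros((32, 32), dtype=int))) == []


def test_tiny_labels_discarded():
    mask = np.zeros((32, 32), dtype=np.int32)
    mask[5, 5] = 1  # single pixel, below the 3-px floor
    mask[10:20, 10:20] = 2
    desc = describe_nuclei(make_tile(mask))
    assert [d.label for d in desc] == [2]


# ---------------------------------------------------------------------------
# architecture

def _mst_total_by_brute_force(pts):
    """Minimum over all spanning trees (edge subsets of size n-1)."""
    n = len(pts)
    edges = list(itertools.combinations(range(n), 2))
    w = {e: np.linalg.norm(pts[e[0]] - pts[e[1]]) for e in edges}
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = min(best, sum(w[e] for e in subset))
    return best


def test_mst_matches_exhaustive_spanning_tree_oracle():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 100, size=(5, 2))
    feats = architecture_features(pts, (128, 128))
    total = feats["arch_mst_edge_mean"] * 4  # n-1 edges
    oracle = _mst_total_by_brute_force(pts * FeatureConfig().microns_per_px)
    assert total == pytest.approx(oracle, rel=1e-9)


def test_square_lattice_mst_has_zero_disorder():
    xs, ys = np.meshgrid(np.arange(5) * 20.0, np.arange(5) * 20.0)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    feats = architecture_features(pts, (128, 128))
    assert feats["arch_mst_edge_sd"] == pytest.approx(0.0, abs=1e-9)
    assert feats["arch_mst_edge_disorder"] == pytest.approx(0.0, abs=1e-9)


def test_unit_square_delaunay_against_exhaustive_oracle():
    """Any triangulation of 4 cocircular points: 2 triangles, areas sum to 1."""
    pts_um = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    pts_px = pts_um / FeatureConfig().microns_per_px
    feats = architecture_features(pts_px, (8, 8))
    assert feats["arch_delaunay_area_mean"] == pytest.approx(0.5, rel=1e-9)
    assert feats["arch_delaunay_area_mean"] * 2 == pytest.approx(1.0, rel=1e-9)
    # the five edges: four unit sides plus one sqrt(2) diagonal
    assert feats["arch_delaunay_side_mean"] == pytest.approx(
        (4 * 1.0 + math.sqrt(2)) / 5, rel=1e-9)


def test_architecture_needs_four_points():
    feats = architecture_features(np.array([[0, 0], [5, 5], [9, 1]]), (32, 32))
    assert all(np.isnan(v) for v in feats.values())


def test_architecture_scaling_metamorphic():
    rng = np.random.default_rng(8)
    pts = rng.uniform(10, 90, size=(12, 2))
    f1 = architecture_features(pts, (100, 100))
    f2 = architecture_features(pts * 2, (200, 200))
    for k in ("arch_mst_edge_mean", "arch_delaunay_side_mean", "arch_knn3_mean"):
        assert f2[k] == pytest.approx(2 * f1[k], rel=1e-9)
    assert f2["arch_delaunay_area_mean"] == pytest.approx(
        4 * f1["arch_delaunay_area_mean"], rel=1e-9)
    assert f2["arch_density_value"] == pytest.approx(f1["arch_density_value"] / 4,
                                                     rel=1e-9)


# ---------------------------------------------------------------------------
# cell cluster graph

def _ccg_oracle(pts_px, cfg):
    """Independent adjacency-matrix evaluation of all 26 CCG metrics."""
    pts = pts_px * cfg.microns_per_px
    n = len(pts)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(pts[i] - pts[j])
            if d > 0 and d ** (-cfg.ccg_alpha) > cfg.ccg_r:
                G.add_edge(i, j)
    deg = np.array([G.degree(v) for v in range(n)], dtype=float)
    comps = list(nx.connected_components(G))
    giant = max(comps, key=len)
    sizes = np.array([len(c) for c in comps], dtype=float)
    ecc = []
    for comp in comps:
        sub = G.subgraph(comp)
        ecc.extend(nx.eccentricity(sub).values())
    ecc = np.array(ecc, dtype=float)
    sub_g = G.subgraph(giant)
    pl = [d for u, targets in nx.all_pairs_shortest_path_length(sub_g)
          for v, d in targets.items() if u < v]
    elen = np.array([np.linalg.norm(pts[u] - pts[v]) for u, v in G.edges()])
    A = nx.to_numpy_array(G, nodelist=range(n))
    Lg = nx.laplacian_matrix(sub_g).toarray()
    try:
        assort = nx.degree_assortativity_coefficient(G)
        if not np.isfinite(assort):
            assort = 0.0
    except (ValueError, ZeroDivisionError):
        assort = 0.0

    def dis(x):
        m, s = x.mean(), x.std()
        return s / (m + s) if m + s else 0.0

    return {
        "ccg_node_count": n,
        "ccg_edge_count": G.number_of_edges(),
        "ccg_degree_mean": deg.mean(),
        "ccg_degree_sd": deg.std(),
        "ccg_component_count": len(comps),
        "ccg_giant_fraction": len(giant) / n,
        "ccg_isolated_fraction": float(np.mean(deg == 0)),
        "ccg_eccentricity_mean": ecc.mean(),
        "ccg_eccentricity_sd": ecc.std(),
        "ccg_diameter": nx.diameter(sub_g),
        "ccg_radius": nx.radius(sub_g),
        "ccg_clustering_mean": nx.average_clustering(G),
        "ccg_transitivity": nx.transitivity(G),
        "ccg_path_length_mean": np.mean(pl) if pl else 0.0,
        "ccg_path_length_sd": np.std(pl) if pl else 0.0,
        "ccg_assortativity": assort,
        "ccg_component_size_mean": sizes.mean(),
        "ccg_component_size_disorder": dis(sizes),
        "ccg_triangle_count": sum(nx.triangles(G).values()) / 3,
        "ccg_edge_length_mean": elen.mean(),
        "ccg_edge_length_sd": elen.std(),
        "ccg_edge_length_disorder": dis(elen),
        "ccg_kcore_max": max(nx.core_number(G).values()),
        "ccg_spectral_radius": float(np.linalg.eigvalsh(A).max()),
        "ccg_algebraic_connectivity": float(np.sort(np.linalg.eigvalsh(Lg))[1])
        if len(giant) >= 2 else 0.0,
        "ccg_betweenness_mean": float(np.mean(list(
            nx.betweenness_centrality(G).values()))),
    }


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ccg_matches_independent_graph_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 150, size=(8, 2))
    cfg = FeatureConfig()
    feats = ccg_features(pts, cfg)
    oracle = _ccg_oracle(pts, cfg)
    for name in CCG_NAMES:
        assert feats[f"ccg_{name}"] == pytest.approx(oracle[f"ccg_{name}"], abs=1e-8), name


def test_ccg_without_edges():
    cfg = FeatureConfig(ccg_r=10.0)  # d^-0.5 > 10 means d < 0.01 um: no edges
    pts = np.array([[0, 0], [200, 0], [0, 200], [200, 200]], dtype=float)
    feats = ccg_features(pts, cfg)
    assert feats["ccg_edge_count"] == 0
    assert feats["ccg_isolated_fraction"] == 1.0
    assert feats["ccg_clustering_mean"] == 0.0


def test_ccg_triangle_of_close_points():
    pts = np.array([[0, 0], [8, 0], [4, 7]], dtype=float)
    feats = ccg_features(pts, FeatureConfig())
    assert feats["ccg_triangle_count"] == 1
    assert feats["ccg_clustering_mean"] == 1.0
    assert feats["ccg_edge_count"] == 3


def test_ccg_identical_points_error():
    with pytest.raises(ValueError, match="degenerate"):
        ccg_features(np.zeros((5, 2)), FeatureConfig())


# ---------------------------------------------------------------------------
# CORE

def test_core_identical_orientations():
    pts = np.array([[0, 0], [10, 0], [5, 8], [2, 12]], dtype=float)
    cfg = FeatureConfig()
    edges = ccg_edges(pts, cfg)
    feats = core_features(np.full(4, 0.7), edges, cfg)
    assert feats["core_energy_mean"] == pytest.approx(1.0)
    assert feats["core_entropy_mean"] == pytest.approx(0.0)


def test_core_entropy_matches_direct_tally():
    """Uniformly spread orientations on a complete graph vs a by-hand tally."""
    n = 18
    cfg = FeatureConfig()
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 30, size=(n, 2))  # tight cluster: complete CCG
    theta = (np.arange(n) + 0.5) * math.pi / n
    edges = ccg_edges(pts, cfg)
    assert len(edges) == n * (n - 1) // 2
    feats = core_features(theta, edges, cfg)

    # oracle for one neighborhood (the full graph, relative to center c)
    B = cfg.core_bins
    ents = []
    for c in range(n):
        P = np.zeros((B, B))
        for u in range(n):
            for v in range(u + 1, n):
                bi = int(((theta[u] - theta[c]) % math.pi) / math.pi * B) % B
                bj = int(((theta[v] - theta[c]) % math.pi) / math.pi * B) % B
                P[bi, bj] += 1
                P[bj, bi] += 1
        p = P.ravel() / P.sum()
        p = p[p > 0]
        ents.append(-np.sum(p * np.log(p)))
    assert feats["core_entropy_mean"] == pytest.approx(np.mean(ents), abs=1e-10)


def test_core_two_cliques_zero_contrast():
    """Two distant cliques, internally uniform orientations: zero contrast."""
    a = np.array([[0, 0], [10, 0], [5, 8]], dtype=float)
    b = a + 400.0  # far beyond the edge threshold
    pts = np.vstack([a, b])
    theta = np.array([0.2] * 3 + [0.2 + math.pi / 2] * 3)
    cfg = FeatureConfig()
    edges = ccg_edges(pts, cfg)
    assert len(edges) == 6  # two K3s
    feats = core_features(theta, edges, cfg)
    assert feats["core_contrast_mean"] == pytest.approx(0.0)
    assert feats["core_contrast_sd"] == pytest.approx(0.0)


def test_core_invariant_to_global_rotation():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 120, size=(12, 2))
    theta = rng.uniform(0, math.pi, size=12)
    cfg = FeatureConfig()
    edges = ccg_edges(pts, cfg)
    f1 = core_features(theta, edges, cfg)
    f2 = core_features((theta + 0.9) % math.pi, edges, cfg)
    for k, v in f1.items():
        assert f2[k] == pytest.approx(v, abs=1e-9), k


def test_core_no_edges_is_family_na():
    feats = core_features(np.array([0.1, 0.2]), np.empty((0, 2), dtype=int))
    assert all(np.isnan(v) for v in feats.values())


# ---------------------------------------------------------------------------
# Haralick

def test_constant_intensity_nuclei_texture():
    mask = np.zeros((32, 32), dtype=np.int32)
    mask[4:16, 4:16] = 1
    img = np.full((32, 32, 3), 120, dtype=np.uint8)
    feats = haralick_nuclear(make_tile(mask, intensity=img))
    assert feats["haralick_energy_mean"] == pytest.approx(1.0)
    assert feats["haralick_entropy_mean"] == pytest.approx(0.0)
    assert feats["haralick_contrast_mean"] == pytest.approx(0.0)


def test_checkerboard_contrast_matches_pairwise_count_oracle():
    cfg = FeatureConfig()
    mask = np.zeros((16, 16), dtype=np.int32)
    mask[2:14, 2:14] = 1
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:16, 0:16]
    img[(yy + xx) % 2 == 0] = 40
    img[(yy + xx) % 2 == 1] = 200
    tile = make_tile(mask, intensity=img)
    feats = haralick_nuclear(tile, cfg)

    # oracle: explicit pair enumeration over the 4 offsets, symmetric
    from ibris.nuclear import luminance

    lv = np.clip((luminance(img) / 256 * cfg.glcm_levels).astype(int), 0,
                 cfg.glcm_levels - 1)
    inside = mask == 1
    pairs = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        for r in range(16):
            for c in range(16):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < 16 and 0 <= c2 < 16 and inside[r, c] and inside[r2, c2]:
                    pairs.append((lv[r, c], lv[r2, c2]))
                    pairs.append((lv[r2, c2], lv[r, c]))
    contrast = np.mean([(a - b) ** 2 for a, b in pairs])
    assert feats["haralick_contrast_mean"] == pytest.approx(contrast, rel=1e-9)


def test_two_nucleus_sd_is_population_sd():
    mask = np.zeros((32, 64), dtype=np.int32)
    mask[4:16, 4:16] = 1
    mask[4:16, 40:52] = 2
    img = np.full((32, 64, 3), 100, dtype=np.uint8)
    rng = np.random.default_rng(0)
    img[4:16, 40:52] = rng.integers(0, 255, size=(12, 12, 3))
    feats = haralick_nuclear(make_tile(mask, intensity=img))
    # per-nucleus energies a, b -> tile sd = |a - b| / 2 (population SD)
    mask_a = np.zeros_like(mask)
    mask_a[4:16, 4:16] = 1
    mask_b = np.zeros_like(mask)
    mask_b[4:16, 40:52] = 1
    fa = haralick_nuclear(make_tile(mask_a, intensity=img))["haralick_energy_mean"]
    fb = haralick_nuclear(make_tile(mask_b, intensity=img))["haralick_energy_mean"]
    assert feats["haralick_energy_sd"] == pytest.approx(abs(fa - fb) / 2, rel=1e-9)


def test_glcm_excludes_pixels_outside_mask():
    lv = np.array([[1, 2], [3, 4]])
    mask = np.array([[True, True], [False, False]])
    P = glcm_of_mask(lv, mask, 8)
    assert P.sum() == 2  # the single horizontal pair, symmetric
    assert P[1, 2] == 1 and P[2, 1] == 1


def test_cooccurrence_stats_on_known_matrix():
    P = np.array([[0.5, 0.0], [0.0, 0.5]])
    s = cooccurrence_stats(P)
    assert s["energy"] == pytest.approx(0.5)
    assert s["entropy"] == pytest.approx(math.log(2))
    assert s["contrast"] == pytest.approx(0.0)
    assert s["correlation"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# assembled tile vector

def test_tile_vector_has_242_entries(small_cohort):
    vec = nuclear_tile_vector(small_cohort[0].tiles[0])
    assert len(vec) == 242
    counts = {"shape": 0, "arch": 0, "ccg": 0, "core": 0, "haralick": 0}
    for k in vec:
        counts[k.split("_")[0]] += 1
    assert counts == {"shape": 100, "arch": 51, "ccg": 26, "core": 39, "haralick": 26}


def test_tile_vector_translation_invariance():
    rng = np.random.default_rng(2)
    side = 96
    mask = np.zeros((side, side), dtype=np.int32)
    # nuclei confined to one quadrant so a small shift crosses no quadrant line
    for i in range(8):
        cx, cy = rng.uniform(12, 38, size=2)
        draw_ellipse_mask(side, cx, cy, 5, 3, rng.uniform(0, math.pi), label=i + 1,
                          mask=mask)
    img = np.full((side, side, 3), 230, dtype=np.uint8)
    img[mask > 0] = (100, 80, 160)
    shifted_mask = np.roll(np.roll(mask, 5, axis=0), 5, axis=1)
    shifted_img = np.roll(np.roll(img, 5, axis=0), 5, axis=1)
    v1 = nuclear_tile_vector(make_tile(mask, intensity=img))
    v2 = nuclear_tile_vector(make_tile(shifted_mask, intensity=shifted_img))
    for k, val in v1.items():
        assert v2[k] == pytest.approx(val, abs=1e-9), k


def test_tile_vector_three_nuclei_flags_architecture_na():
    mask = np.zeros((64, 64), dtype=np.int32)
    for i, (cx, cy) in enumerate([(12, 12), (40, 14), (25, 45)]):
        draw_ellipse_mask(64, cx, cy, 5, 3, 0.4 * i, label=i + 1, mask=mask)
    vec = nuclear_tile_vector(make_tile(mask))
    shape_vals = [v for k, v in vec.items() if k.startswith("shape_")]
    arch_vals = [v for k, v in vec.items() if k.startswith("arch_")]
    assert all(np.isfinite(v) for v in shape_vals)
    assert all(np.isnan(v) for v in arch_vals)
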