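"""Synthetic phantom cohorts: labeled tiles plus survival outcomes.

The generator emulates the inputs the prognostic pipeline consumes — tumor
tiles with nuclei label masks, mitosis point lists, tubule and epithelium
masks — together with disease-free-survival outcomes whose hazard is tied to
planted per-patient image phenotypes.  Nuclei are rendered as hard-core
ellipses (minimum center spacing equal to the mean minor axis), mitoses as a
Poisson point process over the epithelium, and tubules as annular rings whose
rim nuclei are flagged.  Survival times follow an exponential (optionally
Weibull) proportional-hazards model with log-hazard
``sum_k planted_effect[k] * u_k`` over standard-normal patient latents
``u_k``; censoring is independent, calibrated so the realized censored
fraction approximates ``censor_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.draw import ellipse as draw_ellipse

from .datatypes import PatientCase, TileRecord

#: latent phenotype axes a planted effect may act on
PHENOTYPE_KEYS = ("mitotic", "nuclear_disorder", "tubule")

#: lognormal link slope from the mitotic latent to the per-tile Poisson mean
MITOTIC_LINK_SLOPE = 0.6


class PackingError(ValueError):
    """Raised when the hard-core constraint cannot accommodate the density."""


@dataclass
class PhantomConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a breast-cancer DFS cohort: mostly censored follow-up
    (~80%), median survival on the 100-month scale, 2000-px tiles at
    0.25 um/px.  Tests scale ``tile_side_px`` and ``nuclei_density`` down.
    """

    n_patients: int = 100
    tiles_per_patient: int = 2
    tile_side_px: int = 2000
    nuclei_density: int = 1400  # nuclei per tile
    nucleus_radius_px: float = 14.0  # mean equivalent radius (~3.5 um at 0.25 um/px)
    pleomorphism_level: float = 0.5  # in [0,1]; scales axis/orientation variance
    mitosis_rate_per_tile: float = 4.0  # Poisson mean at phenotype latent 0
    tubule_fraction: float = 0.3  # target fraction of nuclei on tubule rims
    planted_effect: dict = field(default_factory=dict)  # phenotype -> log-hazard coeff
    baseline_hazard_scale: float = 0.005  # events per month at latent 0
    dfs_distribution: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    censor_rate: float = 0.8
    odx_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_side_px < 64:
            raise ValueError("tile_side_px must be >= 64")
        for name in ("nuclei_density", "mitosis_rate_per_tile", "baseline_hazard_scale",
                     "nucleus_radius_px", "tiles_per_patient", "n_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.tubule_fraction <= 1.0:
            raise ValueError("tubule_fraction must be in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 <= self.pleomorphism_level <= 1.0:
            raise ValueError("pleomorphism_level must be in [0, 1]")
        if self.dfs_distribution not in ("exponential", "weibull"):
            raise ValueError("dfs_distribution must be 'exponential' or 'weibull'")
        unknown = set(self.planted_effect) - set(PHENOTYPE_KEYS)
        if unknown:
            raise ValueError(
                f"planted_effect names unknown phenotype keys {sorted(unknown)}; "
                f"known keys: {PHENOTYPE_KEYS}"
            )


def _hard_core_sample(rng: np.random.Generator, n: int, side: int, dmin: float,
                      existing: np.ndarray | None = None, margin: float = 2.0,
                      max_tries_factor: int = 60) -> np.ndarray:
    """Dart-throwing with a cell-grid occupancy check; returns (m, 2) (x, y)."""
    cell = max(dmin, 1e-9)
    ncell = int(math.ceil(side / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []

    def _try_add(x: float, y: float) -> bool:
        ci, cj = int(x / cell), int(y / cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    px, py = pts[k]
                    if (px - x) ** 2 + (py - y) ** 2 < dmin * dmin:
                        return False
        grid.setdefault((ci, cj), []).append(len(pts))
        pts.append((x, y))
        return True

    if existing is not None:
        for x, y in existing:
            ci, cj = int(x / cell), int(y / cell)
            grid.setdefault((ci, cj), []).append(len(pts))
            pts.append((float(x), float(y)))
    n_existing = len(pts)

    lo, hi = margin, side - 1 - margin
    accepted = 0
    tries = 0
    max_tries = max_tries_factor * max(n, 1)
    while accepted < n and tries < max_tries:
        cand = rng.uniform(lo, hi, size=(min(2 * (n - accepted), 512), 2))
        for x, y in cand:
            tries += 1
            if _try_add(x, y):
                accepted += 1
                if accepted == n:
                    break
            if tries >= max_tries:
                break
    if accepted < n:
        raise PackingError(
            f"could not place {n} centers with hard-core distance {dmin:.1f} px in a "
            f"{side}x{side} tile; nuclei_density is the limiting parameter"
        )
    return np.array(pts[n_existing:], dtype=float)


def simulate_tile(cfg: PhantomConfig, patient_phenotype: dict,
                  rng: np.random.Generator, tile_id: str = "t0",
                  origin: tuple[int, int] = (0, 0)) -> TileRecord:
    """Render one synthetic tumor tile for a patient phenotype.

    ``patient_phenotype`` supplies the per-patient latent levels:
    ``mitotic_intensity`` (Poisson mean per tile), ``nuclear_disorder`` in
    [0,1] and ``tubule_fraction`` in [0,1].
    """
    side = cfg.tile_side_px
    n = int(cfg.nuclei_density)
    R = cfg.nucleus_radius_px
    b_mean = 0.75 * R  # mean minor semi-axis
    dmin = 2.0 * b_mean  # hard-core distance = mean minor axis length

    if n * dmin * dmin > 0.6 * side * side:
        raise PackingError(
            f"nuclei_density={n} infeasible for hard-core distance {dmin:.1f} px in a "
            f"{side}x{side} tile; nuclei_density is the limiting parameter"
        )

    disorder = float(np.clip(patient_phenotype.get("nuclear_disorder",
                                                   cfg.pleomorphism_level), 0.0, 1.0))
    tub_frac = float(np.clip(patient_phenotype.get("tubule_fraction",
                                                   cfg.tubule_fraction), 0.0, 1.0))
    mito_mean = float(max(patient_phenotype.get("mitotic_intensity",
                                                cfg.mitosis_rate_per_tile), 0.0))

    # --- tubule rings and their rim nuclei ---
    ring_r = 3.5 * R
    per_ring = 8
    n_tub = int(round(tub_frac * n))
    n_rings = int(math.ceil(n_tub / per_ring)) if n_tub > 0 else 0
    centers_tub = np.empty((0, 2))
    ring_centers = np.empty((0, 2))
    if n_rings > 0:
        ring_margin = ring_r + 2.5 * R
        try:
            ring_centers = _hard_core_sample(
                rng, n_rings, side, dmin=2 * ring_margin, margin=ring_margin)
        except PackingError:
            # target fraction not reachable on a small tile: place what fits
            ring_centers = _hard_core_sample(
                rng, max(1, n_rings // 2), side, dmin=2 * ring_margin, margin=ring_margin)
        rim = []
        remaining = n_tub
        for cx, cy in ring_centers:
            m = min(per_ring, remaining)
            ang = rng.uniform(0, 2 * np.pi) + np.arange(m) * (2 * np.pi / per_ring)
            ang += rng.normal(0, 0.06, size=m)
            rad = ring_r + rng.normal(0, 0.15 * R, size=m)
            rim.append(np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang), ang]))
            remaining -= m
        rim_arr = np.concatenate(rim) if rim else np.empty((0, 3))
        centers_tub = rim_arr[:, :2]
        rim_angles = rim_arr[:, 2]
    else:
        rim_angles = np.empty(0)

    n_free = n - len(centers_tub)
    centers_free = _hard_core_sample(rng, n_free, side, dmin, existing=centers_tub,
                                     margin=2.0)
    centers = np.vstack([centers_tub, centers_free])
    tubule_flag = np.zeros(len(centers), dtype=bool)
    tubule_flag[: len(centers_tub)] = True

    # --- per-nucleus geometry ---
    m = len(centers)
    theta0 = rng.uniform(0, np.pi)
    sigma_th = 0.15 + 1.4 * disorder
    theta = np.mod(theta0 + rng.normal(0, sigma_th, size=m), np.pi)
    # rim nuclei align tangentially to their ring
    if len(rim_angles):
        theta[: len(rim_angles)] = np.mod(rim_angles + np.pi / 2
                                          + rng.normal(0, 0.1, len(rim_angles)), np.pi)
    b = np.clip(rng.normal(b_mean, 0.18 * R * (0.4 + disorder), size=m),
                0.35 * R, 1.0 * R)
    elong = np.clip(rng.normal(1.6, 0.45 * disorder + 0.05, size=m), 1.05, 3.0)
    a = b * elong

    # --- rasters ---
    nuclei_mask = np.zeros((side, side), dtype=np.int32)
    label = 0
    keep = []
    for i in range(m):
        x, y = centers[i]
        rr, cc = draw_ellipse(y, x, b[i], a[i], shape=(side, side), rotation=theta[i])
        free = nuclei_mask[rr, cc] == 0
        if free.sum() < 3:
            continue
        label += 1
        nuclei_mask[rr[free], cc[free]] = label
        keep.append(i)
    tubule_flag = tubule_flag[keep]

    # epithelium = dilated neighborhood of the nuclei
    dist = ndimage.distance_transform_edt(nuclei_mask == 0)
    epithelium = dist < 2.2 * R

    tubule_mask = np.zeros((side, side), dtype=bool)
    band = 1.5 * R
    for cx, cy in ring_centers:
        r0 = int(max(0, cy - ring_r - band - 1))
        r1 = int(min(side, cy + ring_r + band + 2))
        c0 = int(max(0, cx - ring_r - band - 1))
        c1 = int(min(side, cx + ring_r + band + 2))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(yy - cy, xx - cx)
        tubule_mask[r0:r1, c0:c1] |= np.abs(d - ring_r) <= band

    # mitoses: Poisson count, uniform over epithelium pixels
    k = rng.poisson(mito_mean)
    if k > 0:
        ey, ex = np.nonzero(epithelium)
        idx = rng.integers(0, len(ex), size=k)
        mitoses = np.column_stack([ex[idx].astype(float), ey[idx].astype(float)])
    else:
        mitoses = np.empty((0, 2))

    # H&E-like rendering: pale eosin background, basophilic (blue-purple) nuclei
    img = np.empty((side, side, 3), dtype=float)
    bg = np.array([235.0, 205.0, 225.0])
    img[:] = bg + rng.normal(0, 3.0, size=(side, side, 3))
    inside = nuclei_mask > 0
    base = np.array([95.0, 75.0, 155.0])
    jitter = rng.normal(0, 12.0, size=(label + 1, 3))
    jitter[0] = 0.0
    per_nuc = base + jitter[nuclei_mask[inside]]
    texture = rng.normal(0, 14.0, size=(inside.sum(), 3))
    img[inside] = per_nuc + texture
    img = np.clip(img, 0, 255).astype(np.uint8)

    return TileRecord(
        tile_id=tile_id,
        origin=origin,
        intensity=img,
        nuclei_mask=nuclei_mask,
        mitosis_points=mitoses,
        tubule_mask=tubule_mask,
        epithelium_mask=epithelium,
    )


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _tile_rng(seed: int, index: int, t: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index, 17 + t)))


def _draw_survival(cfg: PhantomConfig, lp: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Proportional-hazards failure times plus independent calibrated censoring."""
    rate = cfg.baseline_hazard_scale * np.exp(lp)
    e = rng.exponential(1.0, size=len(lp))
    if cfg.dfs_distribution == "exponential":
        t_fail = e / rate
    else:
        t_fail = (e / rate) ** (1.0 / cfg.weibull_shape)
    if cfg.censor_rate == 0:
        return t_fail, np.ones(len(lp), dtype=int)

    def realized(log_mu: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(log_mu) * t_fail))) - cfg.censor_rate

    lo, hi = -20.0, 20.0
    log_mu = optimize.brentq(realized, lo, hi)
    c = rng.exponential(1.0 / np.exp(log_mu), size=len(lp))
    event = (t_fail <= c).astype(int)
    time = np.minimum(t_fail, c)
    return time, event


_RACE = (("white", 0.63), ("black", 0.09), ("south_asian", 0.26), ("other", 0.02))
_PR = (("pos", 0.85), ("neg", 0.14), ("unknown", 0.01))
_HER2 = (("neg", 0.78), ("pos", 0.08), ("unknown", 0.14))
_CHEMO = (("yes", 0.60), ("no", 0.37), ("unknown", 0.03))


def _choice(rng: np.random.Generator, table) -> str:
    labels, probs = zip(*table)
    return str(rng.choice(labels, p=np.array(probs) / sum(probs)))


def simulate_cohort(cfg: PhantomConfig) -> list[PatientCase]:
    """Generate a full phantom cohort; deterministic given ``cfg`` (incl. seed).

    Patient-level draws use counter-based substreams keyed by patient index,
    so changing ``tiles_per_patient`` does not reshuffle other patients.
    """
    n = cfg.n_patients
    latents = np.empty((n, 3))  # columns follow PHENOTYPE_KEYS
    for i in range(n):
        rng = _patient_rng(cfg.seed, i)
        latents[i] = rng.normal(0, 1, size=3)

    lp = np.zeros(n)
    for j, key in enumerate(PHENOTYPE_KEYS):
        lp += cfg.planted_effect.get(key, 0.0) * latents[:, j]

    surv_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                            spawn_key=(999983,)))
    time, event = _draw_survival(cfg, lp, surv_rng)

    # ODx: noisy monotone function of the latent hazard (or of the latents
    # under a null cohort) so subgroup analyses are exercisable
    if np.ptp(lp) > 0:
        s = (lp - lp.mean()) / (lp.std() + 1e-12)
    else:
        s = (latents[:, 0] + latents[:, 1]) / np.sqrt(2)

    cases: list[PatientCase] = []
    for i in range(n):
        rng = _patient_rng(cfg.seed, i)
        rng.normal(0, 1, size=3)  # consume the latent draws, keep stream aligned
        u_mit, u_nuc, u_tub = latents[i]
        phenotype = {
            "mitotic": u_mit,
            "nuclear_disorder": u_nuc,
            "tubule": u_tub,
            "mitotic_intensity": cfg.mitosis_rate_per_tile * math.exp(MITOTIC_LINK_SLOPE * u_mit),
            "nuclear_disorder_level": float(np.clip(cfg.pleomorphism_level + 0.2 * u_nuc,
                                                    0.02, 1.0)),
            "tubule_fraction": float(np.clip(cfg.tubule_fraction + 0.15 * u_tub, 0.0, 0.9)),
            "log_hazard": float(lp[i]),
        }
        age = float(np.clip(rng.normal(57.0, 10.5), 30.0, 88.0))
        race = _choice(rng, _RACE)
        pr = _choice(rng, _PR)
        her2 = _choice(rng, _HER2)
        chemo = _choice(rng, _CHEMO)
        size_mm = float(np.clip(rng.lognormal(math.log(18.0), 0.45), 4.0, 80.0))
        g_latent = 0.6 * u_nuc + 0.6 * u_mit + 0.8 * rng.normal()
        # grade frequencies ~18/55/27% via fixed normal cutoffs of the latent
        sd_g = math.sqrt(0.36 + 0.36 + 0.64)
        grade = 1 + int(g_latent > sd_g * -0.9154) + int(g_latent > sd_g * 0.6128)
        odx_val = rng.normal()
        odx: int | None = int(np.clip(round(17.0 + 6.0 * s[i] + 5.0 * odx_val), 0, 60))
        if cfg.odx_missing_rate > 0 and rng.uniform() < cfg.odx_missing_rate:
            odx = None

        tiles = []
        grid_w = max(1, int(math.ceil(math.sqrt(cfg.tiles_per_patient))))
        for t in range(cfg.tiles_per_patient):
            trng = _tile_rng(cfg.seed, i, t)
            origin = ((t // grid_w) * cfg.tile_side_px, (t % grid_w) * cfg.tile_side_px)
            tiles.append(simulate_tile(cfg, phenotype, trng,
                                       tile_id=f"p{i:04d}_t{t:02d}", origin=origin))

        cases.append(PatientCase(
            patient_id=f"p{i:04d}",
            tiles=tiles,
            dfs_time=float(time[i]),
            event=int(event[i]),
            age=age,
            tumor_size_mm=size_mm,
            grade=grade,
            pr_status=pr,
            her2_status=her2,
            race=race,
            chemotherapy=chemo,
            odx_score=odx,
            phenotype=phenotype,
        ))
    return cases
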