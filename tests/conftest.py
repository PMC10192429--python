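import numpy as np
import pytest

from ibris import PhantomConfig, extract_features, simulate_cohort
from ibris.config import FeatureConfig
from ibris.datatypes import TileRecord


def make_tile(nuclei_mask, intensity=None, mitoses=None, tubule=None, epithelium=None,
              tile_id="t0", origin=(0, 0)):
    """Assemble a TileRecord from a label mask with sensible defaults."""
    nuclei_mask = np.asarray(nuclei_mask, dtype=np.int32)
    h, w = nuclei_mask.shape
    if intensity is None:
        intensity = np.full((h, w, 3), 230, dtype=np.uint8)
        intensity[nuclei_mask > 0] = (100, 80, 160)
    if tubule is None:
        tubule = np.zeros((h, w), dtype=bool)
    if epithelium is None:
        epithelium = nuclei_mask > 0
    if mitoses is None:
        mitoses = np.empty((0, 2))
    return TileRecord(tile_id=tile_id, origin=origin, intensity=intensity,
                      nuclei_mask=nuclei_mask, mitosis_points=mitoses,
                      tubule_mask=tubule, epithelium_mask=epithelium)


def draw_ellipse_mask(side, cx, cy, a, b, theta, label=1, mask=None):
    from skimage.draw import ellipse

    if mask is None:
        mask = np.zeros((side, side), dtype=np.int32)
    rr, cc = ellipse(cy, cx, b, a, shape=mask.shape, rotation=theta)
    mask[rr, cc] = label
    return mask


@pytest.fixture(scope="session")
def small_cohort():
    cfg = PhantomConfig(n_patients=8, tiles_per_patient=2, tile_side_px=128,
                        nuclei_density=30, nucleus_radius_px=5.0,
                        planted_effect={"mitotic": 1.0}, censor_rate=0.25, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_features(small_cohort)


@pytest.fixture(scope="session")
def feature_cfg():
    return FeatureConfig()
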