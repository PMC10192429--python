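"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class TileRecord:
    """One tumor tile: RGB raster plus the segmentation/detection products.

    Rasters are indexed ``(row, col)``; point lists are 0-based ``(x, y)``
    with ``x`` the column coordinate.
    """

    tile_id: str
    origin: tuple[int, int]  # (row, col) pixel offset within the parent image
    intensity: np.ndarray  # H x W x 3 uint8
    nuclei_mask: np.ndarray  # H x W integer labels, 0 = background
    mitosis_points: np.ndarray  # (n, 2) float, columns (x, y)
    tubule_mask: np.ndarray  # H x W bool
    epithelium_mask: np.ndarray  # H x W bool

    def __post_init__(self) -> None:
        self.mitosis_points = np.asarray(self.mitosis_points, dtype=float).reshape(-1, 2)
        h, w = self.nuclei_mask.shape
        for name in ("tubule_mask", "epithelium_mask"):
            m = getattr(self, name)
            if m.shape != (h, w):
                raise ValueError(f"{self.tile_id}: {name} shape {m.shape} != {(h, w)}")
        if self.intensity.shape[:2] != (h, w):
            raise ValueError(
                f"{self.tile_id}: intensity shape {self.intensity.shape[:2]} != {(h, w)}"
            )
        if len(self.mitosis_points):
            x, y = self.mitosis_points[:, 0], self.mitosis_points[:, 1]
            if (x < 0).any() or (x > w - 1).any() or (y < 0).any() or (y > h - 1).any():
                raise ValueError(f"{self.tile_id}: mitosis point outside tile bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_mask.shape


@dataclass
class PatientCase:
    """A patient: tiles, disease-free-survival outcome and clinical covariates."""

    patient_id: str
    tiles: list[TileRecord]
    dfs_time: float  # months
    event: int  # 1 = recurrence/death, 0 = censored
    age: float = np.nan
    tumor_size_mm: float = np.nan
    grade: int | None = None  # 1, 2, 3 or None (unknown)
    pr_status: str = "unknown"  # pos | neg | unknown
    her2_status: str = "unknown"
    race: str = "unknown"
    chemotherapy: str = "unknown"  # yes | no | unknown
    odx_score: int | None = None
    phenotype: dict = field(default_factory=dict)  # latent generator state, if synthetic

    def __post_init__(self) -> None:
        if not self.dfs_time > 0:
            raise ValueError(f"{self.patient_id}: dfs_time must be > 0, got {self.dfs_time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1, got {self.event}")
        if not self.tiles:
            raise ValueError(f"{self.patient_id}: at least one tile required")


@dataclass
class SurvivalOutcome:
    time: float
    event: int


def cohort_outcome_frame(cohort: Sequence[PatientCase]) -> pd.DataFrame:
    """Patient-level manifest frame (id, outcome, covariates) for a cohort."""
    rows = []
    for c in cohort:
        rows.append(
            {
                "patient_id": c.patient_id,
                "dfs_time": c.dfs_time,
                "event": c.event,
                "age": c.age,
                "tumor_size_mm": c.tumor_size_mm,
                "grade": c.grade if c.grade is not None else "",
                "pr_status": c.pr_status,
                "her2_status": c.her2_status,
                "race": c.race,
                "chemotherapy": c.chemotherapy,
                "odx_score": c.odx_score if c.odx_score is not None else "",
            }
        )
    return pd.DataFrame(rows)


class FeatureMatrix:
    """Patients x features matrix in frozen catalog column order."""

    def __init__(self, patient_ids: Sequence[str], feature_names: Sequence[str],
                 values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(patient_ids), len(feature_names)):
            raise ValueError(
                f"values shape {values.shape} != ({len(patient_ids)}, {len(feature_names)})"
            )
        if len(set(patient_ids)) != len(patient_ids):
            raise ValueError("duplicate patient id in feature matrix")
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("duplicate feature name in feature matrix")
        self.patient_ids = list(patient_ids)
        self.feature_names = list(feature_names)
        self.values = values

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids, name="patient_id"),
                            columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.patient_ids)
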