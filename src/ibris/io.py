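"""On-disk cohort artifacts: manifests, masks, point lists, matrices, models.

Layout of a cohort directory::

    manifest.csv                  one row per patient (outcome + covariates)
    tiles.csv                     one row per tile (patient, origin, file names)
    tiles/<tile_id>_image.png     RGB raster
    tiles/<tile_id>_nuclei.png    16-bit label mask
    tiles/<tile_id>_tubule.png    binary mask (0/255)
    tiles/<tile_id>_epithelium.png
    mitoses.csv                   tile_id, x, y (0-based, x = column)

Readers validate and reject malformed inputs rather than coercing; missing
categorical values round-trip as the "unknown" level and a missing ODx score
as an empty field.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, default_catalog
from .datatypes import FeatureMatrix, PatientCase, TileRecord, cohort_outcome_frame
from .model import RiskModel

_MANIFEST_COLS = ["patient_id", "dfs_time", "event", "age", "tumor_size_mm", "grade",
                  "pr_status", "her2_status", "race", "chemotherapy", "odx_score"]


def write_cohort(cohort: list[PatientCase], dir_path) -> None:
    root = Path(dir_path)
    (root / "tiles").mkdir(parents=True, exist_ok=True)
    cohort_outcome_frame(cohort).to_csv(root / "manifest.csv", index=False)
    tile_rows, mito_rows = [], []
    for case in cohort:
        for t in case.tiles:
            stem = t.tile_id
            iio.imwrite(root / "tiles" / f"{stem}_image.png", t.intensity)
            iio.imwrite(root / "tiles" / f"{stem}_nuclei.png",
                        t.nuclei_mask.astype(np.uint16))
            iio.imwrite(root / "tiles" / f"{stem}_tubule.png",
                        (t.tubule_mask.astype(np.uint8) * 255))
            iio.imwrite(root / "tiles" / f"{stem}_epithelium.png",
                        (t.epithelium_mask.astype(np.uint8) * 255))
            tile_rows.append({"patient_id": case.patient_id, "tile_id": stem,
                              "origin_row": t.origin[0], "origin_col": t.origin[1]})
            for x, y in t.mitosis_points:
                mito_rows.append({"tile_id": stem, "x": x, "y": y})
    pd.DataFrame(tile_rows).to_csv(root / "tiles.csv", index=False)
    pd.DataFrame(mito_rows, columns=["tile_id", "x", "y"]).to_csv(
        root / "mitoses.csv", index=False)


def _parse_optional_int(v) -> int | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    return int(float(v))


def read_cohort(dir_path) -> list[PatientCase]:
    """Load and validate a cohort directory written by :func:`write_cohort`."""
    root = Path(dir_path)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"patient_id": str},
                           keep_default_na=False, na_values=[])
    tiles_df = pd.read_csv(root / "tiles.csv", dtype={"patient_id": str, "tile_id": str})
    mito_path = root / "mitoses.csv"
    mito = (pd.read_csv(mito_path, dtype={"tile_id": str}) if mito_path.exists()
            else pd.DataFrame(columns=["tile_id", "x", "y"]))
    mito_by_tile = {k: g[["x", "y"]].to_numpy(float) for k, g in mito.groupby("tile_id")}

    if manifest["patient_id"].duplicated().any():
        dup = manifest.loc[manifest["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient id {dup!r} in manifest")

    cases = []
    for idx, row in manifest.iterrows():
        dfs_time = float(row["dfs_time"])
        if not dfs_time > 0:
            raise ValueError(f"manifest row {idx} ({row['patient_id']}): "
                             f"non-positive dfs_time {dfs_time}")
        event = int(float(row["event"]))
        if event not in (0, 1):
            raise ValueError(f"manifest row {idx} ({row['patient_id']}): "
                             f"event must be 0 or 1, got {row['event']}")
        tiles = []
        for _, trow in tiles_df[tiles_df["patient_id"] == row["patient_id"]].iterrows():
            stem = trow["tile_id"]
            paths = {kind: root / "tiles" / f"{stem}_{kind}.png"
                     for kind in ("image", "nuclei", "tubule", "epithelium")}
            for kind, p in paths.items():
                if not p.exists():
                    raise FileNotFoundError(f"tile {stem}: missing {kind} mask file {p}")
            img = iio.imread(paths["image"])
            nuclei = iio.imread(paths["nuclei"]).astype(np.int32)
            tub = iio.imread(paths["tubule"]) > 0
            epi = iio.imread(paths["epithelium"]) > 0
            tiles.append(TileRecord(
                tile_id=stem,
                origin=(int(trow["origin_row"]), int(trow["origin_col"])),
                intensity=img, nuclei_mask=nuclei,
                mitosis_points=mito_by_tile.get(stem, np.empty((0, 2))),
                tubule_mask=tub, epithelium_mask=epi))
        grade = _parse_optional_int(row.get("grade"))

        def _cat(v: str) -> str:
            v = str(v).strip()
            return v if v else "unknown"

        cases.append(PatientCase(
            patient_id=str(row["patient_id"]), tiles=tiles, dfs_time=dfs_time,
            event=event,
            age=float(row["age"]) if str(row.get("age", "")).strip() else np.nan,
            tumor_size_mm=(float(row["tumor_size_mm"])
                           if str(row.get("tumor_size_mm", "")).strip() else np.nan),
            grade=grade, pr_status=_cat(row.get("pr_status", "")),
            her2_status=_cat(row.get("her2_status", "")),
            race=_cat(row.get("race", "")),
            chemotherapy=_cat(row.get("chemotherapy", "")),
            odx_score=_parse_optional_int(row.get("odx_score"))))
    return cases


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    fm.to_dataframe().to_csv(path, float_format="%.17g")


def read_feature_matrix(path, catalog: FeatureCatalog | None = None) -> FeatureMatrix:
    """Read a feature CSV; validates against the catalog column order."""
    catalog = catalog or default_catalog()
    df = pd.read_csv(path, index_col="patient_id", dtype={"patient_id": str},
                     float_precision="round_trip")
    if list(df.columns) != catalog.names:
        raise ValueError(
            f"feature columns do not match the {len(catalog)}-name catalog "
            f"(file has {len(df.columns)} feature columns)")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate patient id {df.index[df.index.duplicated()][0]!r}")
    return FeatureMatrix.from_dataframe(df)


def save_model(model: RiskModel, path) -> None:
    """Lock a fitted model down as auditable JSON."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model(path, catalog: FeatureCatalog | None = None) -> RiskModel:
    """Load a locked model; refuses a catalog version mismatch."""
    catalog = catalog or default_catalog()
    with open(path) as fh:
        d = json.load(fh)
    if d.get("catalog_hash") != catalog.version_hash():
        raise ValueError(
            f"model catalog hash {d.get('catalog_hash')!r} does not match the current "
            f"catalog {catalog.version_hash()!r}; refusing to score")
    return RiskModel.from_dict(d)
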