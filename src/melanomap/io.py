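"""Readers and writers for the pipeline's on-disk interfaces.

Images are 24-bit RGB PNG; ROI masks single-band 8-bit PNG (0/255); ranges
GeoJSON (one feature per species, property ``species_id``); tabular outputs
CSV with a provenance header comment (config hash + seed) so every file
records the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry.base import BaseGeometry

from .lightness import SpecimenImage


def write_specimen_png(image: SpecimenImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)


def read_specimen_png(image_path: str | Path, mask_path: str | Path, *,
                      species_id: str, side: str, sex: str = "unknown",
                      morph_id: str = "m0",
                      family: str | None = None) -> SpecimenImage:
    pixels = np.asarray(Image.open(image_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L")) > 0
    return SpecimenImage(pixels=pixels, roi_mask=mask, species_id=species_id,
                         side=side, sex=sex, morph_id=morph_id, family=family)


def write_ranges_geojson(ranges: dict[str, BaseGeometry | None],
                         path: str | Path, crs: str = "") -> None:
    features = []
    for sid in sorted(ranges):
        geom = ranges[sid]
        features.append({
            "type": "Feature",
            "properties": {"species_id": sid, "empty": geom is None},
            "geometry": None if geom is None
            else json.loads(shapely.to_geojson(geom))})
    doc = {"type": "FeatureCollection", "features": features}
    if crs:
        doc["crs"] = {"type": "name", "properties": {"name": crs}}
    Path(path).write_text(json.dumps(doc))


def read_ranges_geojson(path: str | Path) -> dict[str, BaseGeometry | None]:
    doc = json.loads(Path(path).read_text())
    out: dict[str, BaseGeometry | None] = {}
    for feat in doc["features"]:
        sid = feat["properties"]["species_id"]
        geom = feat.get("geometry")
        out[sid] = None if geom is None else shapely.geometry.shape(geom)
    return out


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *,
                run_hash: str = "", seed: int | None = None) -> None:
    """CSV with a provenance header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# melanomap run_hash={run_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
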