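"""File formats.

Stain rasters are single-channel 16-bit TIFF with a JSON description
carrying pixel size and stain label; PET volumes are NIfTI-1 with the
frame schedule in a sidecar JSON; ROI polygons are GeoJSON in pixel
coordinates (x = column, y = row); tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .ihc_morphometry import StainImage

__all__ = [
    "write_stain_image",
    "read_stain_image",
    "save_volume",
    "load_volume",
    "write_frame_schedule",
    "read_frame_schedule",
    "write_rois",
    "read_rois",
    "write_ground_truth",
]


def write_stain_image(path, image: StainImage) -> None:
    """Write a stain raster as 16-bit TIFF (values clipped to uint16 range)."""
    data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    meta = {"pixel_size_um": image.pixel_size, "stain": image.stain}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stain_image(path) -> StainImage:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (ValueError, TypeError):
                meta = {}
    return StainImage(
        pixels=data,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        stain=meta.get("stain", "AT8"),
    )


def save_volume(path, data: np.ndarray, voxel_size_mm: float | tuple = 1.0) -> None:
    """Save a 3-D or 4-D volume as NIfTI-1."""
    if np.isscalar(voxel_size_mm):
        zooms = (float(voxel_size_mm),) * 3
    else:
        zooms = tuple(float(v) for v in voxel_size_mm)
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def write_frame_schedule(path, frame_durations_s) -> None:
    with open(path, "w") as fh:
        json.dump({"frame_durations_s": list(map(float, frame_durations_s)), "units": "s"}, fh)


def read_frame_schedule(path) -> list[float]:
    with open(path) as fh:
        return list(json.load(fh)["frame_durations_s"])


def write_rois(path, rois: list[tuple[object, Polygon, dict]]) -> None:
    """Write ROI polygons as GeoJSON; each feature carries id and properties."""
    features = [
        {"type": "Feature", "id": rid, "geometry": mapping(poly), "properties": props or {}}
        for rid, poly, props in rois
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_rois(path) -> list[tuple[object, Polygon, dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for i, feat in enumerate(fc["features"]):
        rid = feat.get("id", feat.get("properties", {}).get("id", i))
        out.append((rid, shape(feat["geometry"]), feat.get("properties", {}) or {}))
    return out


def write_ground_truth(path, truth) -> None:
    """Persist planted-object ground truth (objects only, not rasters) as JSON."""
    payload = {
        "pixel_size_um": truth.pixel_size,
        "background": truth.background,
        "positive_fraction": truth.positive_fraction,
        "objects": [
            {
                "label": o.label,
                "centroid_row": o.centroid[0],
                "centroid_col": o.centroid[1],
                "area_um2": o.area_um2,
                "intensity": o.intensity,
            }
            for o in truth.objects
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
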