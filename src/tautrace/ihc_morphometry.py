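"""Morphometric quantification of AT8-positive objects in stain images.

Segments supra-threshold connected components, computes shape/intensity
descriptors, calibrates per-channel interval rules from labeled exemplars,
classifies objects into the two analysis channels (dense neuronal /
oligodendroglial ``NFT/CB`` vs astrocytic / fragment ``TA/TF``), and
quantifies per-ROI occupancy and colocalization.

Conventions (fixed so counts are reproducible):

* connected components use 8-connectivity;
* coordinates are 0-based row-major with the origin at the top-left pixel;
  a pixel ``(row, col)`` has center ``(x=col, y=row)`` in ROI space, and a
  pixel belongs to a polygon ROI iff its center falls inside the polygon;
* perimeter is the classical weighted contour-length estimator
  (:func:`skimage.measure.perimeter`, 4-neighbourhood); for a solid
  axis-aligned ``h x w`` rectangle it equals ``2*(h-1) + 2*(w-1)`` pixels;
  it is floored at the equivalent-circle perimeter, which only affects
  few-pixel specks where the contour estimator collapses;
* ellipse axes come from second central moments
  (:class:`skimage.measure.regionprops`).

Dimensionless descriptors: circularity ``4*pi*A/P**2``, roundness
``4*A/(pi*major**2)``, compactness ``sqrt(4*A/pi)/major``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "CHANNELS",
    "CLASS_TO_CHANNEL",
    "FEATURE_NAMES",
    "StainImage",
    "TauObject",
    "ClassRuleSet",
    "SubfieldRecord",
    "segment_objects",
    "compute_features",
    "calibrate_rules",
    "classify_objects",
    "quantify_subfield",
    "colocalization_area",
    "channel_masks",
    "roi_pixel_mask",
]

CHANNELS = ("NFT/CB", "TA/TF")
UNASSIGNED = "unassigned"

#: object classes -> merged analysis channel
CLASS_TO_CHANNEL = {"NFT": "NFT/CB", "CB": "NFT/CB", "TA": "TA/TF", "TF": "TA/TF"}

FEATURE_NAMES = (
    "area",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "perimeter",
    "mean_intensity",
    "circularity",
    "roundness",
    "compactness",
)


@dataclass
class StainImage:
    """2-D stain-intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels:
        Non-negative intensity array (a.u.), shape ``(rows, cols)``.
    pixel_size:
        Physical edge length of one pixel in µm.
    stain:
        Stain label, one of ``AT8 | GFAP | MAP2 | ARG``.
    """

    pixels: np.ndarray
    pixel_size: float
    stain: str = "AT8"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("StainImage.pixels must be 2-D")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TauObject:
    """One segmented AT8-positive connected component.

    ``coords`` holds (row, col) pixel indices into the source image;
    ``features`` maps every name in :data:`FEATURE_NAMES` to its value
    (areas in µm², lengths in µm, intensity in a.u.).
    """

    coords: np.ndarray
    features: dict[str, float]
    channel: str = UNASSIGNED
    label: int = 0

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.coords.mean(axis=0))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def _features_from_props(props, pixel_size: float) -> dict[str, float]:
    ps = float(pixel_size)
    area = props.area * ps**2
    eqd = math.sqrt(4.0 * area / math.pi)
    major = props.axis_major_length * ps
    minor = props.axis_minor_length * ps
    if major <= 0.0:  # degenerate (single pixel / collinear): fall back
        major = minor = eqd
    # contour estimator underestimates badly below a few px; floor at the
    # equivalent-circle perimeter so circularity stays in (0, 1] + tolerance
    perim = max(props.perimeter * ps, math.pi * eqd)
    circularity = 4.0 * math.pi * area / perim**2
    return {
        "area": area,
        "equivalent_diameter": eqd,
        "major_axis": major,
        "minor_axis": minor,
        "perimeter": perim,
        "mean_intensity": float(props.intensity_mean),
        "circularity": circularity,
        "roundness": 4.0 * area / (math.pi * major**2),
        "compactness": eqd / major,
    }


def compute_features(
    mask: np.ndarray, pixels: np.ndarray, pixel_size: float
) -> dict[str, float]:
    """Descriptor vector of a single object.

    ``mask`` must be a non-empty boolean array of the same shape as
    ``pixels`` containing one object (all True pixels are treated as a
    single region).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(pixels).shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise ValueError("empty object mask")
    props = regionprops(mask.astype(np.uint8), intensity_image=np.asarray(pixels, float))[0]
    return _features_from_props(props, pixel_size)


def segment_objects(
    image: StainImage,
    intensity_threshold: float | None = None,
    min_area: float = 0.0,
) -> list[TauObject]:
    """Segment supra-threshold 8-connected components into unclassified objects.

    ``intensity_threshold`` defaults to Otsu's threshold on the image
    histogram (overridable by a fixed value, which is how the analysis is
    meant to be run section-to-section).  Components with area (µm²)
    below ``min_area`` are dropped.  A blank image yields an empty list.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    px = image.pixels
    if intensity_threshold is None:
        if px.min() == px.max():
            return []
        intensity_threshold = float(threshold_otsu(px))
    else:
        intensity_threshold = float(intensity_threshold)
        if not np.isfinite(intensity_threshold):
            raise ValueError("intensity_threshold must be finite")
        if not (px.min() <= intensity_threshold <= px.max()):
            raise ValueError(
                f"intensity_threshold {intensity_threshold} outside intensity "
                f"range [{px.min()}, {px.max()}]"
            )
    mask = px > intensity_threshold
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    out: list[TauObject] = []
    for props in regionprops(labels, intensity_image=px):
        feats = _features_from_props(props, image.pixel_size)
        if feats["area"] < min_area:
            continue
        out.append(TauObject(coords=np.asarray(props.coords), features=feats, label=props.label))
    return out


@dataclass
class ClassRuleSet:
    """Per-channel inclusive feature intervals plus an intensity threshold.

    Calibrated from manually selected exemplars; an object belongs to a
    channel iff every feature falls inside that channel's interval.
    """

    intervals: dict[str, dict[str, tuple[float, float]]]
    intensity_threshold: dict[str, float]
    provenance: dict[str, list] = field(default_factory=dict)
    features: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        for channel, table in self.intervals.items():
            for name, (lo, hi) in table.items():
                if lo > hi:
                    raise ValueError(f"interval min > max for {channel}/{name}")

    def matches(self, features: Mapping[str, float], channel: str) -> bool:
        table = self.intervals[channel]
        return all(table[f][0] <= features[f] <= table[f][1] for f in self.features)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "intervals": {
                ch: {f: list(iv) for f, iv in tab.items()} for ch, tab in self.intervals.items()
            },
            "intensity_threshold": dict(self.intensity_threshold),
            "provenance": {ch: list(v) for ch, v in self.provenance.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ClassRuleSet":
        return cls(
            intervals={
                ch: {f: tuple(iv) for f, iv in tab.items()} for ch, tab in d["intervals"].items()
            },
            intensity_threshold=dict(d["intensity_threshold"]),
            provenance={ch: list(v) for ch, v in d.get("provenance", {}).items()},
            features=tuple(d["features"]),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "ClassRuleSet":
        try:
            d = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def calibrate_rules(
    exemplars: Sequence[TauObject],
    labels: Sequence[str],
    expansion: float = 0.2,
    features: Sequence[str] = FEATURE_NAMES,
    exemplar_ids: Sequence | None = None,
) -> ClassRuleSet:
    """Build interval rules from labeled exemplar objects.

    NFT and CB exemplars are pooled into the ``NFT/CB`` channel and TA/TF
    into ``TA/TF``.  Each per-feature interval is the exemplar [min, max]
    widened by ``expansion * (max - min)`` on both sides.  The per-channel
    intensity threshold (used only to break ties between channels) is the
    widened lower bound of the mean-intensity interval.
    """
    if len(exemplars) != len(labels):
        raise ValueError("exemplars and labels length mismatch")
    if expansion < 0:
        raise ValueError("expansion must be >= 0")
    if exemplar_ids is None:
        exemplar_ids = list(range(len(exemplars)))

    by_channel: dict[str, list[int]] = {ch: [] for ch in CHANNELS}
    for i, lab in enumerate(labels):
        if lab in CLASS_TO_CHANNEL:
            by_channel[CLASS_TO_CHANNEL[lab]].append(i)
        elif lab in CHANNELS:
            by_channel[lab].append(i)
        else:
            raise ValueError(f"unknown exemplar label {lab!r}")
    for ch in CHANNELS:
        if not by_channel[ch]:
            raise ValueError(f"no exemplars for channel {ch!r}")

    intervals: dict[str, dict[str, tuple[float, float]]] = {}
    intensity_threshold: dict[str, float] = {}
    provenance: dict[str, list] = {}
    for ch, idx in by_channel.items():
        table = {}
        for f in features:
            vals = np.array([exemplars[i].features[f] for i in idx], dtype=float)
            lo, hi = float(vals.min()), float(vals.max())
            pad = expansion * (hi - lo)
            table[f] = (lo - pad, hi + pad)
        intervals[ch] = table
        intensity_threshold[ch] = table["mean_intensity"][0]
        provenance[ch] = [exemplar_ids[i] for i in idx]

    return ClassRuleSet(
        intervals=intervals,
        intensity_threshold=intensity_threshold,
        provenance=provenance,
        features=tuple(features),
    )


def classify_objects(objects: Iterable[TauObject], rules: ClassRuleSet) -> list[TauObject]:
    """Assign each object to a channel (in place; returns the list).

    An object is assigned to a channel iff all of its features fall inside
    that channel's intervals.  If both channels match, the tie is broken
    toward ``NFT/CB`` (the high-density channel) when the object's mean
    intensity is at or above the NFT/CB intensity threshold, else toward
    ``TA/TF``.  Objects matching no channel stay ``unassigned``.
    """
    out = list(objects)
    for obj in out:
        hits = [ch for ch in CHANNELS if rules.matches(obj.features, ch)]
        if len(hits) == 1:
            obj.channel = hits[0]
        elif len(hits) == 2:
            thr = rules.intensity_threshold["NFT/CB"]
            obj.channel = "NFT/CB" if obj.features["mean_intensity"] >= thr else "TA/TF"
        else:
            obj.channel = UNASSIGNED
    return out


def channel_masks(
    objects: Iterable[TauObject], shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Boolean per-channel masks from classified objects (disjoint by construction)."""
    masks = {ch: np.zeros(shape, dtype=bool) for ch in CHANNELS}
    for obj in objects:
        if obj.channel in masks:
            masks[obj.channel][obj.coords[:, 0], obj.coords[:, 1]] = True
    return masks


def roi_pixel_mask(roi: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers (x=col, y=row) fall inside the polygon."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = shapely.contains_xy(roi, cols.ravel().astype(float), rows.ravel().astype(float))
    return inside.reshape(shape)


@dataclass
class SubfieldRecord:
    """Per-ROI occupancy record: one subfield of one section.

    ``area_pct`` and ``mean_intensity`` are per-channel; a channel with no
    positive pixels inside the ROI reports 0.0 area-% and missing (NaN)
    intensity.
    """

    subfield_id: object
    area_pct: dict[str, float]
    mean_intensity: dict[str, float]
    total_area_pct: float
    n_roi_pixels: int
    region_label: str | None = None

    def as_row(self) -> dict:
        row = {"subfield_id": self.subfield_id, "region_label": self.region_label}
        for ch in self.area_pct:
            key = ch.replace("/", "").replace(" ", "").lower()
            row[f"{key}_area_pct"] = self.area_pct[ch]
            row[f"{key}_mean_intensity"] = self.mean_intensity[ch]
        row["total_area_pct"] = self.total_area_pct
        row["n_roi_pixels"] = self.n_roi_pixels
        return row


def quantify_subfield(
    image: StainImage,
    masks: Mapping[str, np.ndarray],
    roi: Polygon,
    subfield_id: object = None,
    region_label: str | None = None,
    total_mask: np.ndarray | None = None,
) -> SubfieldRecord:
    """Per-channel AT8 area-% and mean intensity inside one ROI polygon.

    ``masks`` maps channel name to a boolean positivity mask co-registered
    with ``image``.  ``total_mask`` defaults to the union of the channel
    masks.  Raises if the ROI contains no pixel centers of the image.
    """
    roi_px = roi_pixel_mask(roi, image.shape)
    n_roi = int(roi_px.sum())
    if n_roi == 0:
        raise ValueError("ROI lies fully outside the image")
    for ch, m in masks.items():
        if m.shape != image.shape:
            raise ValueError(f"mask geometry mismatch for channel {ch!r}")
    if total_mask is None:
        total_mask = np.zeros(image.shape, dtype=bool)
        for m in masks.values():
            total_mask |= m

    area_pct, mean_int = {}, {}
    for ch, m in masks.items():
        pos = m & roi_px
        n_pos = int(pos.sum())
        area_pct[ch] = 100.0 * n_pos / n_roi
        mean_int[ch] = float(image.pixels[pos].mean()) if n_pos else float("nan")
    total_pct = 100.0 * int((total_mask & roi_px).sum()) / n_roi
    return SubfieldRecord(
        subfield_id=subfield_id,
        area_pct=area_pct,
        mean_intensity=mean_int,
        total_area_pct=total_pct,
        n_roi_pixels=n_roi,
        region_label=region_label,
    )


def colocalization_area(
    signal: StainImage,
    mask_image: StainImage,
    signal_threshold: float,
    mask_threshold: float | None = None,
    mode: str = "mask",
) -> float:
    """AT8-in-structure colocalization, in percent.

    ``mode='mask'`` returns ``100 * |signal+ ∩ mask+| / |mask+|`` (AT8
    area inside GFAP/MAP2-positive structures).  ``mode='frame'`` returns
    the signal's supra-threshold area as % of the entire scanning frame.
    Returns NaN when the structure mask is empty in mask mode.
    """
    if signal.shape != mask_image.shape:
        raise ValueError("images are not co-registered (shape mismatch)")
    sig = signal.pixels > signal_threshold
    if mode == "frame":
        return 100.0 * sig.sum() / sig.size
    if mode != "mask":
        raise ValueError("mode must be 'mask' or 'frame'")
    if mask_threshold is None:
        raise ValueError("mask_threshold required in mask mode")
    struct = mask_image.pixels > mask_threshold
    n_struct = struct.sum()
    if n_struct == 0:
        return float("nan")
    return 100.0 * (sig & struct).sum() / n_struct
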