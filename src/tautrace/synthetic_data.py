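"""Seeded generators for every input the analysis modules consume.

Each generator attaches ground truth so recovery can be tested.  A single
integer seed fans out to per-stage child generators via
:mod:`tautrace._seeds` (``SeedSequence.spawn``), so identical seeds give
bit-identical outputs.

Object morphology defaults are stated conventions, not reconstructions
of real tissue: NFT/CB are rendered as filled high-intensity ellipses
(axis ratio 1-2), TA as low-intensity stellate (radial-arm) shapes, TF
as <= 5-px specks.  Noise is additive Gaussian for stain/ARG/PET rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from ._seeds import child_rngs
from .ihc_morphometry import CLASS_TO_CHANNEL, StainImage
from .kinetics import (
    MOUSE_FRAME_DURATIONS_S,
    InputFunction,
    TimeActivityCurve,
)
from .scrad import F18_HALF_LIFE_MIN, BrainCellCensus, CellPelletRecord

__all__ = [
    "OBJECT_CLASSES",
    "PlantedObject",
    "IHCGroundTruth",
    "gen_ihc_section",
    "DEFAULT_COUPLING",
    "gen_autorad_section",
    "KineticParams",
    "InputShape",
    "gen_dynamic_pet",
    "DynamicPETVolume",
    "gen_dynamic_pet_volume",
    "ScradCohort",
    "gen_scrad_cohort",
    "CorticalSlabTruth",
    "gen_cortical_slab",
    "gaussian_boundary_profile",
]

OBJECT_CLASSES = ("NFT", "CB", "TA", "TF")
_CLASS_IDS = {c: i + 1 for i, c in enumerate(OBJECT_CLASSES)}


# ---------------------------------------------------------------------------
# IHC sections
# ---------------------------------------------------------------------------

@dataclass
class PlantedObject:
    """Ground truth for one planted AT8-positive object."""

    label: str  # NFT | CB | TA | TF
    centroid: tuple[float, float]  # (row, col) px
    area_um2: float  # painted area
    intensity: float  # nominal mean intensity a.u.

    @property
    def channel(self) -> str:
        return CLASS_TO_CHANNEL[self.label]


@dataclass
class IHCGroundTruth:
    """Planted objects plus the exact positivity rasters."""

    objects: list[PlantedObject]
    label_mask: np.ndarray  # 0 background, 1..4 = NFT/CB/TA/TF
    object_map: np.ndarray  # 0 background, i+1 = objects[i]
    pixel_size: float
    background: float

    @property
    def positive_fraction(self) -> float:
        return float((self.label_mask > 0).mean())

    def class_mask(self, name: str) -> np.ndarray:
        return self.label_mask == _CLASS_IDS[name]

    def channel_mask(self, channel: str) -> np.ndarray:
        out = np.zeros(self.label_mask.shape, dtype=bool)
        for cls, ch in CLASS_TO_CHANNEL.items():
            if ch == channel:
                out |= self.class_mask(cls)
        return out

    def positive_fraction_in(self, roi_mask: np.ndarray, channel: str | None = None) -> float:
        """Positive-pixel fraction inside an ROI mask (per channel if given)."""
        pos = self.label_mask > 0 if channel is None else self.channel_mask(channel)
        n = roi_mask.sum()
        if n == 0:
            raise ValueError("empty ROI mask")
        return float((pos & roi_mask).sum() / n)


def _render_nft_cb(rng: np.random.Generator, cls: str, ps: float) -> tuple[np.ndarray, np.ndarray]:
    """Compact filled ellipse; returns (rows, cols) relative to (0, 0) center."""
    r_um = rng.uniform(4.5, 7.0) if cls == "NFT" else rng.uniform(2.5, 4.0)
    ratio = rng.uniform(1.0, 2.0)
    a = r_um * math.sqrt(ratio) / ps  # semi-axes in px, area preserved
    b = r_um / math.sqrt(ratio) / ps
    rot = rng.uniform(0.0, math.pi)
    rr, cc = draw_ellipse(0, 0, a, b, rotation=rot)
    return rr, cc


def _render_ta(rng: np.random.Generator, ps: float) -> tuple[np.ndarray, np.ndarray]:
    """Stellate shape: small core disk plus 5-8 tapered radial arms."""
    size = 64
    canvas = np.zeros((size, size), dtype=bool)
    c = size // 2
    core_r = rng.uniform(1.5, 2.5) / ps
    rr, cc = draw_ellipse(c, c, core_r, core_r)
    canvas[rr, cc] = True
    n_arms = int(rng.integers(5, 9))
    base = rng.uniform(0, 2 * math.pi)
    for k in range(n_arms):
        ang = base + 2 * math.pi * k / n_arms + rng.normal(0, 0.15)
        length = rng.uniform(7.0, 12.0) / ps
        half_w = rng.uniform(0.5, 0.8) / ps
        tip = (c + length * math.sin(ang), c + length * math.cos(ang))
        # triangle from the core out to the tip, tapering to a point
        perp = (math.cos(ang), -math.sin(ang))
        p0 = (c + half_w * perp[0], c + half_w * perp[1])
        p1 = (c - half_w * perp[0], c - half_w * perp[1])
        rr, cc = draw_polygon([p0[0], p1[0], tip[0]], [p0[1], p1[1], tip[1]], shape=canvas.shape)
        canvas[rr, cc] = True
        # a drawn center line keeps thin arms 8-connected after rasterization
        rr, cc = draw_line(c, c, int(round(tip[0])), int(round(tip[1])))
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        canvas[rr[keep], cc[keep]] = True
    rows, cols = np.nonzero(canvas)
    return rows - c, cols - c


_TF_OFFSETS = np.array([(0, 0), (0, 1), (1, 0), (0, -1), (-1, 0)])


def _render_tf(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """<= 5-px speck."""
    n = int(rng.integers(1, 6))
    off = _TF_OFFSETS[:n]
    return off[:, 0], off[:, 1]


_INTENSITY_RANGES = {
    "NFT": (160.0, 200.0),
    "CB": (150.0, 190.0),
    "TA": (60.0, 100.0),
    "TF": (50.0, 90.0),
}


def gen_ihc_section(
    counts: Mapping[str, int] | None = None,
    densities: Mapping[str, float] | None = None,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.5,
    background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    margin_px: int = 2,
    max_attempts: int = 500,
) -> tuple[StainImage, IHCGroundTruth]:
    """Generate one AT8 stain section with ground truth.

    Exactly one of ``counts`` (exact objects per class, e.g. to plant
    exemplars) or ``densities`` (expected objects per mm², Poisson counts)
    may be given; both ``None`` means an empty section.  Objects are
    placed without overlap (rejection sampling with a ``margin_px``
    clearance) and lie fully inside the image.
    """
    if shape[0] < 256 or shape[1] < 256:
        raise ValueError("image dims must be at least 256x256 px")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if counts is not None and densities is not None:
        raise ValueError("give counts or densities, not both")

    rng_counts, rng_morph, rng_noise = child_rngs(seed, 3)

    if counts is None:
        counts = {}
        if densities is not None:
            area_mm2 = shape[0] * shape[1] * (pixel_size * 1e-3) ** 2
            for cls, dens in densities.items():
                if cls not in _CLASS_IDS:
                    raise ValueError(f"unknown class {cls!r}")
                if dens < 0:
                    raise ValueError("densities must be >= 0")
                counts[cls] = int(rng_counts.poisson(dens * area_mm2))
    else:
        for cls, n in counts.items():
            if cls not in _CLASS_IDS:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")

    pixels = np.full(shape, float(background))
    label_mask = np.zeros(shape, dtype=np.int8)
    object_map = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    objects: list[PlantedObject] = []

    # occupancy = painted pixels dilated by margin_px (Chebyshev), so distinct
    # objects stay 8-disconnected without blocking whole bounding boxes
    pad = np.arange(-margin_px, margin_px + 1)
    dil_r, dil_c = np.meshgrid(pad, pad, indexing="ij")
    dil_r, dil_c = dil_r.ravel(), dil_c.ravel()

    order = [cls for cls in OBJECT_CLASSES for _ in range(counts.get(cls, 0))]
    for cls in order:
        placed = False
        for _ in range(max_attempts):
            if cls in ("NFT", "CB"):
                rr, cc = _render_nft_cb(rng_morph, cls, pixel_size)
            elif cls == "TA":
                rr, cc = _render_ta(rng_morph, pixel_size)
            else:
                rr, cc = _render_tf(rng_morph)
            h0, h1 = rr.min(), rr.max()
            w0, w1 = cc.min(), cc.max()
            lo_r, hi_r = margin_px - h0, shape[0] - margin_px - h1
            lo_c, hi_c = margin_px - w0, shape[1] - margin_px - w1
            if hi_r <= lo_r or hi_c <= lo_c:
                continue
            r0 = int(rng_morph.integers(lo_r, hi_r))
            c0 = int(rng_morph.integers(lo_c, hi_c))
            R, C = rr + r0, cc + c0
            if occupied[R, C].any():
                continue
            intensity = float(rng_morph.uniform(*_INTENSITY_RANGES[cls]))
            pixels[R, C] = background + intensity
            label_mask[R, C] = _CLASS_IDS[cls]
            object_map[R, C] = len(objects) + 1
            occupied[
                np.clip(R[:, None] + dil_r, 0, shape[0] - 1),
                np.clip(C[:, None] + dil_c, 0, shape[1] - 1),
            ] = True
            objects.append(
                PlantedObject(
                    label=cls,
                    centroid=(float(R.mean()), float(C.mean())),
                    area_um2=len(R) * pixel_size**2,
                    intensity=background + intensity,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {cls} object after {max_attempts} attempts; "
                "the section is too crowded for the requested counts/densities"
            )

    if noise_sd > 0:
        pixels = pixels + rng_noise.normal(0.0, noise_sd, size=shape)
        pixels = np.clip(pixels, 0.0, None)

    image = StainImage(pixels=pixels, pixel_size=pixel_size, stain="AT8")
    truth = IHCGroundTruth(
        objects=objects,
        label_mask=label_mask,
        object_map=object_map,
        pixel_size=pixel_size,
        background=float(background),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Autoradiography
# ---------------------------------------------------------------------------

#: per-class gains: ARG responds strongly to dense NFT/CB, weakly to TA/TF
DEFAULT_COUPLING = {"NFT": 2.0, "CB": 2.0, "TA": 0.3, "TF": 0.3}


def gen_autorad_section(
    truth: IHCGroundTruth,
    coupling: Mapping[str, float] | None = None,
    background: float = 1.0,
    noise_sd: float = 0.05,
    smooth_sigma: float = 0.0,
    seed: int = 0,
) -> StainImage:
    """Autoradiography raster coupled to planted class densities.

    Pixelwise: ``background + sum_class gain * class_mask`` (optionally
    Gaussian-smoothed) plus additive Gaussian noise.  Shares the IHC
    raster geometry so subfield ROIs transfer unchanged.
    """
    coupling = dict(DEFAULT_COUPLING if coupling is None else coupling)
    for cls, g in coupling.items():
        if cls not in _CLASS_IDS:
            raise ValueError(f"unknown class {cls!r}")
        if g < 0:
            raise ValueError("gains must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")

    arg = np.full(truth.label_mask.shape, float(background))
    for cls, g in coupling.items():
        if g > 0:
            arg += g * truth.class_mask(cls)
    if smooth_sigma > 0:
        arg = background + gaussian_filter(arg - background, smooth_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        arg = arg + rng.normal(0.0, noise_sd, size=arg.shape)
    return StainImage(pixels=np.clip(arg, 0.0, None), pixel_size=truth.pixel_size, stain="ARG")


# ---------------------------------------------------------------------------
# Dynamic PET
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """One-tissue-compartment parameters; VT = K1/k2."""

    K1: float  # ml/cm3/min
    k2: float  # 1/min

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError("K1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")

    @property
    def vt(self) -> float:
        return self.K1 / self.k2


@dataclass(frozen=True)
class InputShape:
    """Blood input curve: bi-exponential bolus with a configurable peak.

    ``peak_time == 0`` degenerates to a mono-exponential
    ``peak_amplitude * exp(-washout * t)``.
    """

    peak_time_min: float = 1.0
    peak_amplitude: float = 50.0  # kBq/ml
    washout_per_min: float = 0.08

    def __post_init__(self) -> None:
        if self.peak_time_min < 0 or self.peak_amplitude < 0 or self.washout_per_min <= 0:
            raise ValueError("invalid input-curve shape parameters")

    def _rise_rate(self) -> float:
        # mu > lambda with peak at t* = ln(mu/lam)/(mu - lam)
        from scipy.optimize import brentq

        lam, tp = self.washout_per_min, self.peak_time_min
        f = lambda mu: math.log(mu / lam) / (mu - lam) - tp
        return brentq(f, lam * 1.0000001, 1e4)

    def concentration(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lam = self.washout_per_min
        if self.peak_time_min == 0:
            return self.peak_amplitude * np.exp(-lam * t)
        mu = self._rise_rate()
        raw = np.exp(-lam * t) - np.exp(-mu * t)
        peak = math.exp(-lam * self.peak_time_min) - math.exp(-mu * self.peak_time_min)
        return self.peak_amplitude * raw / peak


def _tissue_response(
    params: KineticParams, input_shape: InputShape, t_grid: np.ndarray
) -> np.ndarray:
    """Numeric one-tissue-compartment response on a fine time grid.

    Trapezoidal exponential-integrator recursion for
    ``C_T' = K1*Cp - k2*C_T`` (O(dt^2) accurate).
    """
    cp = input_shape.concentration(t_grid)
    dt = np.diff(t_grid)
    e = np.exp(-params.k2 * dt)
    ct = np.zeros_like(t_grid)
    for i in range(len(dt)):
        ct[i + 1] = e[i] * (ct[i] + 0.5 * dt[i] * params.K1 * cp[i]) + 0.5 * dt[i] * params.K1 * cp[i + 1]
    return ct


def gen_dynamic_pet(
    params: Mapping[str, KineticParams],
    input_shape: InputShape | None = None,
    frame_durations_s: Sequence[float] = MOUSE_FRAME_DURATIONS_S,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_dt_min: float = 0.005,
) -> tuple[dict[str, TimeActivityCurve], InputFunction]:
    """Per-region tissue TACs plus the blood input curve.

    Tissue activity is the one-tissue-compartment response
    ``K1 * exp(-k2 t) (x) Cp(t)`` evaluated at frame mid-times (numeric
    convolution on a fine grid); Gaussian noise of absolute sd
    ``noise_sd`` is added per frame.
    """
    if len(frame_durations_s) == 0:
        raise ValueError("empty frame schedule")
    input_shape = input_shape or InputShape()
    d = np.asarray(frame_durations_s, dtype=float) / 60.0
    end = np.cumsum(d)
    mids = end - d / 2.0
    t_grid = np.arange(0.0, end[-1] + grid_dt_min, grid_dt_min)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tacs: dict[str, TimeActivityCurve] = {}
    for region, p in params.items():
        ct_grid = _tissue_response(p, input_shape, t_grid)
        ct = np.interp(mids, t_grid, ct_grid)
        if noise_sd > 0:
            ct = np.clip(ct + rng.normal(0.0, noise_sd, size=ct.shape), 0.0, None)
        tacs[region] = TimeActivityCurve.from_durations(frame_durations_s, ct)
    cp = input_shape.concentration(mids)
    input_fn = InputFunction.from_durations(frame_durations_s, cp, source="left ventricle")
    return tacs, input_fn


@dataclass
class DynamicPETVolume:
    """4-D labeled phantom: regional kinetics plus a planted blood sphere."""

    data: np.ndarray  # (x, y, z, t)
    masks: dict[str, np.ndarray]
    frame_durations_s: tuple[float, ...]
    tacs: dict[str, TimeActivityCurve]
    input_fn: InputFunction
    voxel_size_mm: float = 1.0


def gen_dynamic_pet_volume(
    params: Mapping[str, KineticParams],
    input_shape: InputShape | None = None,
    frame_durations_s: Sequence[float] = MOUSE_FRAME_DURATIONS_S,
    shape: tuple[int, int, int] = (16, 16, 8),
    blood_center: Sequence[float] | None = None,
    blood_diameter_mm: float = 5.0,
    voxel_size_mm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DynamicPETVolume:
    """Voxel phantom: region blocks carry their TAC, a sphere carries the input.

    Regions split the volume into equal slabs along x; the blood sphere is
    centered at ``blood_center`` (defaults to the volume center).
    """
    from .kinetics import sphere_mask

    tacs, input_fn = gen_dynamic_pet(
        params, input_shape, frame_durations_s, noise_sd=0.0, seed=seed
    )
    n_frames = len(input_fn.activity)
    data = np.zeros(shape + (n_frames,))
    masks: dict[str, np.ndarray] = {}
    regions = list(tacs)
    edges = np.linspace(0, shape[0], len(regions) + 1).astype(int)
    for (region, tac), lo, hi in zip(tacs.items(), edges[:-1], edges[1:]):
        m = np.zeros(shape, dtype=bool)
        m[lo:hi] = True
        masks[region] = m
        data[m] = tac.activity

    if blood_center is None:
        blood_center = [s / 2.0 for s in shape]
    blood = sphere_mask(shape, blood_center, blood_diameter_mm, voxel_size_mm)
    data[blood] = input_fn.activity
    masks["blood"] = blood
    for region in regions:
        masks[region] &= ~blood

    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        data = np.clip(data + rng.normal(0.0, noise_sd, size=data.shape), 0.0, None)
    return DynamicPETVolume(
        data=data,
        masks=masks,
        frame_durations_s=tuple(frame_durations_s),
        tacs=tacs,
        input_fn=input_fn,
        voxel_size_mm=voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# scRadiotracing cohorts
# ---------------------------------------------------------------------------

@dataclass
class ScradCohort:
    """Per-mouse ground truth plus the pellet-level measurement table."""

    mice: pd.DataFrame = field(repr=False)
    pellets: pd.DataFrame = field(repr=False)
    census: BrainCellCensus = field(default_factory=BrainCellCensus)

    def pellet_records(self) -> list[CellPelletRecord]:
        cols = [f.name for f in CellPelletRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        return [
            CellPelletRecord(**{k: row[k] for k in cols if k in row})
            for row in self.pellets.to_dict("records")
        ]


def gen_scrad_cohort(
    n_tg: int = 5,
    n_wt: int = 5,
    effect: float = 1.89,
    noise_sd: float = 0.0,
    neuron_astro_ratio_tg: float = 27.0,
    neuron_astro_ratio_wt: float = 5.0,
    wt_neuron_uptake_bq: float = 1.6e-4,
    seed: int = 0,
    census: BrainCellCensus | None = None,
) -> ScradCohort:
    """Synthetic scRadiotracing cohort.

    TG neuron uptake is drawn around ``effect * wt_neuron_uptake_bq``
    (default effect 1.89-fold); astrocyte uptake follows the per-genotype
    neuron/astrocyte ratios (defaults 27x TG, 5x WT).  Defaults put the
    TG per-animal cellular activity in the 7.7-36.5 kBq range.  The PET
    increment of every mouse is the census-weighted sum of its uptakes
    plus relative Gaussian noise ``noise_sd``; at ``noise_sd == 0`` the
    extrapolation identity holds exactly per mouse.
    """
    if n_tg < 1 or n_wt < 1:
        raise ValueError("need at least one mouse per arm")
    if effect <= 0:
        raise ValueError("fold-change must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    census = census or BrainCellCensus()
    rng_u, rng_meta, rng_noise = child_rngs(seed, 3)

    rows_mice, rows_pellets = [], []
    for genotype, n in (("TG", n_tg), ("WT", n_wt)):
        mean_u = wt_neuron_uptake_bq * (effect if genotype == "TG" else 1.0)
        ratio = neuron_astro_ratio_tg if genotype == "TG" else neuron_astro_ratio_wt
        for i in range(n):
            mouse_id = f"{genotype}{i + 1:02d}"
            u_n = float(rng_u.uniform(0.55, 1.45) * mean_u)
            u_a = float(rng_u.uniform(0.7, 1.3) * u_n / ratio)
            truth_increment = census.n_neuron * u_n + census.n_astrocyte * u_a
            pet_increment = truth_increment
            if noise_sd > 0:
                pet_increment = truth_increment * (1.0 + float(rng_noise.normal(0.0, noise_sd)))
            dose = float(np.clip(rng_meta.normal(12.7, 2.1), 6.0, 20.0))
            weight = float(rng_meta.uniform(18.0, 30.0))
            rows_mice.append(
                {
                    "mouse_id": mouse_id,
                    "genotype": genotype,
                    "bq_per_neuron": u_n,
                    "bq_per_astrocyte": u_a,
                    "injected_dose_mbq": dose,
                    "body_weight_g": weight,
                    "pet_increment_bq": pet_increment,
                }
            )
            for cell_type, u in (("neuron", u_n), ("astrocyte", u_a)):
                count = int(rng_meta.integers(2e5, 8e5) if cell_type == "neuron" else rng_meta.integers(1e5, 5e5))
                dt = float(rng_meta.uniform(360.0, 420.0))  # 6-7 h procedure
                measured = u * count * 2.0 ** (-dt / F18_HALF_LIFE_MIN)
                if noise_sd > 0:
                    measured = max(0.0, measured * (1.0 + float(rng_noise.normal(0.0, noise_sd))))
                # counter background well below even decayed astrocyte pellets,
                # so default cohorts clear the 2-fold QC threshold
                background = float(rng_meta.uniform(0.02, 0.08))
                if cell_type == "neuron":
                    purity = float(rng_meta.uniform(0.87, 0.97))
                    total = int(round(count / purity))
                    contaminants = total - count
                    cd11b = int(rng_meta.integers(0, contaminants + 1))
                    acsa2 = contaminants - cd11b
                else:
                    purity = float(rng_meta.uniform(0.87, 0.97))
                    total = int(round(count / purity))
                    cd11b = int(rng_meta.integers(0, total - count + 1))
                    acsa2 = count
                rows_pellets.append(
                    {
                        "mouse_id": mouse_id,
                        "genotype": genotype,
                        "cell_type": cell_type,
                        "cell_count": count,
                        "measured_bq": measured,
                        "time_offset_min": dt,
                        "background_bq": background,
                        "injected_dose_mbq": dose,
                        "body_weight_g": weight,
                        "total_cells": total,
                        "cd11b_pos": cd11b,
                        "acsa2_pos": acsa2,
                    }
                )
    return ScradCohort(
        mice=pd.DataFrame(rows_mice), pellets=pd.DataFrame(rows_pellets), census=census
    )


# ---------------------------------------------------------------------------
# Cortical slab
# ---------------------------------------------------------------------------

def gaussian_boundary_profile(
    baseline: float = 1.0, amplitude: float = 0.8, width_mm: float = 0.8
) -> Callable[[np.ndarray], np.ndarray]:
    """Depth profile peaking at the GM/WM boundary (signed distance 0 mm)."""

    def profile(d_mm: np.ndarray) -> np.ndarray:
        return baseline + amplitude * np.exp(-np.asarray(d_mm, float) ** 2 / (2 * width_mm**2))

    return profile


@dataclass
class CorticalSlabTruth:
    """Labeled slab volume with boundary maps and a depth-dependent PET signal."""

    labels: np.ndarray  # 0 CSF, 1 GM, 2 WM
    pet: np.ndarray
    z_csf_map: np.ndarray  # GM/CSF boundary depth per (x, y) column, voxel units
    z_wm_map: np.ndarray  # GM/WM boundary depth per column, voxel units
    parcel_map: np.ndarray  # (x, y) int 1..R
    voxel_size_mm: float
    profile: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_map.max())


def gen_cortical_slab(
    shape: tuple[int, int, int] = (48, 48, 40),
    voxel_size_mm: float = 0.5,
    csf_margin_mm: float = 3.0,
    cortex_thickness_mm: float = 3.0,
    curvature_amp_mm: float = 0.0,
    profile: Callable[[np.ndarray], np.ndarray] | None = None,
    n_parcels: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CorticalSlabTruth:
    """Flat (optionally gently curved) cortical slab with a depth profile.

    The z axis is depth: CSF above the GM/CSF boundary, GM between the
    boundaries, WM below.  The PET volume equals
    ``profile(signed distance to the GM/WM boundary in mm)`` plus noise
    (positive distance = into WM).  The parcel map partitions the (x, y)
    cortical sheet into ``n_parcels`` contiguous stripes (default 200).
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    nx, ny, nz = shape
    if profile is None:
        profile = gaussian_boundary_profile()

    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    wave = 0.0
    if curvature_amp_mm > 0:
        wave = (curvature_amp_mm / voxel_size_mm) * np.sin(2 * np.pi * x / nx) * np.cos(
            2 * np.pi * y / ny
        )
    z_csf = csf_margin_mm / voxel_size_mm + wave
    z_wm = z_csf + cortex_thickness_mm / voxel_size_mm
    z_csf = np.broadcast_to(np.asarray(z_csf, float), (nx, ny)).copy()
    z_wm = np.broadcast_to(np.asarray(z_wm, float), (nx, ny)).copy()

    if cortex_thickness_mm < voxel_size_mm:
        raise ValueError("cortical thickness below voxel size")
    if np.any(z_wm >= nz - 1) or np.any(z_csf <= 0):
        raise ValueError("degenerate slab: boundaries leave the volume")

    z = np.arange(nz)[None, None, :]
    labels = np.full(shape, 1, dtype=np.int8)
    labels[z.repeat(nx, 0).repeat(ny, 1) < z_csf[..., None]] = 0
    labels[z.repeat(nx, 0).repeat(ny, 1) >= z_wm[..., None]] = 2
    if not (labels == 1).any():
        raise ValueError("degenerate slab: no gray matter")

    depth_mm = (z - z_wm[..., None]) * voxel_size_mm  # signed, + into WM
    pet = profile(depth_mm)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        pet = pet + rng.normal(0.0, noise_sd, size=pet.shape)

    col_idx = (np.arange(nx)[:, None] * ny + np.arange(ny)[None, :]).astype(np.int64)
    parcel_map = (col_idx * n_parcels // (nx * ny) + 1).astype(np.int32)

    return CorticalSlabTruth(
        labels=labels,
        pet=np.asarray(pet, float),
        z_csf_map=z_csf,
        z_wm_map=z_wm,
        parcel_map=parcel_map,
        voxel_size_mm=voxel_size_mm,
        profile=profile,
    )
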