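"""Layered cortical-surface sampling of PET volumes.

Five sampling surfaces span the cortical ribbon: the GM/CSF boundary,
two intermediate depths (defaults 25% and 75% of cortical depth, i.e.
GM-toward-CSF and GM-toward-WM), the GM/WM boundary, and a surface
offset into the white matter (default +1 mm, about one PET voxel).
Surfaces are depth maps over the (x, y) cortical sheet; sampling is
trilinear at surface vertices (one per sheet column), averaged per
parcel.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates

from .kinetics import cohens_d
from .synthetic_data import CorticalSlabTruth

__all__ = [
    "LAYER_NAMES",
    "LayerSurfaces",
    "LayerComparison",
    "EffectSizeResult",
    "build_layer_surfaces",
    "surfaces_from_labels",
    "sample_layer_suvr",
    "compare_layers",
    "layer_effect_sizes",
]

LAYER_NAMES = ("gm_csf", "gm_toward_csf", "gm_toward_wm", "gm_wm", "below_gm_wm")


@dataclass
class LayerSurfaces:
    """Five depth maps (z in voxel coordinates) over the cortical sheet."""

    zmaps: np.ndarray  # (5, nx, ny)
    names: tuple[str, ...] = LAYER_NAMES
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.zmaps.shape[0] != len(self.names):
            raise ValueError("one depth map per layer required")
        diffs = np.diff(self.zmaps, axis=0)
        if np.any(diffs < -1e-9):
            raise ValueError("layer surfaces cross (depths must be non-decreasing)")


def build_layer_surfaces(
    slab: CorticalSlabTruth,
    offsets_mm: Sequence[float] | None = None,
    csf_fractions: tuple[float, float] = (0.25, 0.75),
    wm_offset_mm: float = 1.0,
) -> LayerSurfaces:
    """Construct the five sampling surfaces for a cortical slab.

    Default placement: GM/CSF boundary, ``csf_fractions`` of cortical
    depth, GM/WM boundary, and ``wm_offset_mm`` below it.  If
    ``offsets_mm`` is given, it is interpreted as five signed physical
    distances from the GM/WM boundary (negative toward CSF, positive
    into WM) and must be non-decreasing so surfaces never cross.
    """
    vox = slab.voxel_size_mm
    thickness = slab.z_wm_map - slab.z_csf_map  # voxel units
    if np.any(thickness * vox < vox):
        raise ValueError("cortical thickness below voxel size somewhere in the slab")

    if offsets_mm is None:
        f1, f2 = csf_fractions
        zmaps = np.stack(
            [
                slab.z_csf_map,
                slab.z_csf_map + f1 * thickness,
                slab.z_csf_map + f2 * thickness,
                slab.z_wm_map,
                slab.z_wm_map + wm_offset_mm / vox,
            ]
        )
    else:
        offsets = np.asarray(list(offsets_mm), dtype=float)
        if offsets.shape != (5,):
            raise ValueError("offsets_mm must contain exactly 5 values")
        if np.any(np.diff(offsets) < 0):
            raise ValueError("offsets must be non-decreasing (surfaces must not cross)")
        zmaps = np.stack([slab.z_wm_map + o / vox for o in offsets])

    nz = slab.labels.shape[2]
    if zmaps.min() < 0 or zmaps.max() > nz - 1:
        raise ValueError("a layer surface leaves the volume")
    return LayerSurfaces(zmaps=zmaps, voxel_size_mm=vox)


def surfaces_from_labels(
    labels: np.ndarray, voxel_size_mm: float = 1.0, **kwargs
) -> LayerSurfaces:
    """Build surfaces from a 0/1/2 (CSF/GM/WM) label volume.

    Boundary depths are recovered per (x, y) column as the first GM voxel
    (GM/CSF) and the first WM voxel (GM/WM); used by the CLI where only
    the label volume is on disk.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be 3-D")
    gm = labels == 1
    wm = labels == 2
    if not gm.any():
        raise ValueError("degenerate slab: no gray matter")
    nz = labels.shape[2]
    z = np.arange(nz)
    z_csf = np.where(gm.any(axis=2), gm.argmax(axis=2).astype(float), np.nan)
    first_wm = np.where(wm.any(axis=2), wm.argmax(axis=2).astype(float), np.nan)
    if np.isnan(z_csf).any() or np.isnan(first_wm).any():
        raise ValueError("every sheet column must contain GM and WM")
    slab = CorticalSlabTruth(
        labels=labels,
        pet=np.zeros_like(labels, dtype=float),
        z_csf_map=z_csf,
        z_wm_map=first_wm,
        parcel_map=np.ones(labels.shape[:2], dtype=np.int32),
        voxel_size_mm=voxel_size_mm,
        profile=None,
    )
    return build_layer_surfaces(slab, **kwargs)


def sample_layer_suvr(
    pet: np.ndarray,
    surfaces: LayerSurfaces,
    parcel_map: np.ndarray,
    subject_id: object = "s0",
    group: str | None = None,
) -> pd.DataFrame:
    """Sample a PET volume on the five surfaces, averaged per parcel.

    Returns a tidy frame with columns ``subject, group, parcel, layer,
    layer_index, suvr``; a parcel with no sheet columns yields a missing
    value (cannot occur with the generator's stripe parcellation).
    """
    pet = np.asarray(pet, dtype=float)
    if pet.ndim != 3:
        raise ValueError("pet must be a 3-D volume")
    nx, ny = parcel_map.shape
    if pet.shape[:2] != (nx, ny):
        raise ValueError("pet and parcel map are not co-registered")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    parcels = np.unique(parcel_map)
    flat_parcel = parcel_map.ravel()

    rows = []
    for li, name in enumerate(surfaces.names):
        z = surfaces.zmaps[li]
        vals = map_coordinates(
            pet,
            [xs.ravel().astype(float), ys.ravel().astype(float), z.ravel().astype(float)],
            order=1,
            mode="nearest",
        )
        sums = np.bincount(flat_parcel, weights=vals, minlength=parcels.max() + 1)
        cnts = np.bincount(flat_parcel, minlength=parcels.max() + 1)
        for p in parcels:
            suvr = sums[p] / cnts[p] if cnts[p] > 0 else float("nan")
            rows.append(
                {
                    "subject": subject_id,
                    "group": group,
                    "parcel": int(p),
                    "layer": name,
                    "layer_index": li,
                    "suvr": float(suvr),
                }
            )
    return pd.DataFrame(rows)


def _subject_layer_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Subject-level layer means over parcels; raises listing incomplete subjects."""
    wide = (
        profiles.groupby(["subject", "layer"])["suvr"].mean().unstack("layer")
    )
    missing_cols = [l for l in LAYER_NAMES if l not in wide.columns]
    incomplete = wide.index[wide.reindex(columns=LAYER_NAMES).isna().any(axis=1)].tolist()
    if missing_cols or incomplete:
        raise ValueError(f"missing layers for subjects: {incomplete or list(wide.index)}")
    return wide[list(LAYER_NAMES)]


@dataclass
class LayerComparison:
    """Repeated-measures ANOVA across layers plus Tukey-adjusted contrasts."""

    f_statistic: float
    df: tuple[float, float]
    p_value: float
    layer_means: pd.Series = field(repr=False)
    contrasts: pd.DataFrame = field(repr=False)
    epsilon: float | None = None  # Greenhouse-Geisser, if applied


def compare_layers(
    profiles: pd.DataFrame, greenhouse_geisser: bool = False
) -> LayerComparison:
    """One-way repeated-measures ANOVA across the five layers (one group).

    Works on subject-level means over parcels.  Post hoc: all 10 pairwise
    layer contrasts on the layer means, Tukey-adjusted via the
    studentized range with the RM error term.  Sphericity is not tested;
    ``greenhouse_geisser=True`` applies the epsilon-adjusted F test.
    """
    wide = _subject_layer_matrix(profiles)
    data = wide.to_numpy(dtype=float)
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = data.mean()
    layer_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_layer = n * ((layer_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_layer - ss_subj
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    ms_err = ss_err / df2

    epsilon = None
    if ss_layer <= 1e-12 * max(ss_total, 1.0):
        f_stat, p = 0.0, 1.0
    elif ms_err <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_layer / df1) / ms_err
        if greenhouse_geisser:
            epsilon = _gg_epsilon(data)
            p = float(stats.f.sf(f_stat, df1 * epsilon, df2 * epsilon))
        else:
            p = float(stats.f.sf(f_stat, df1, df2))

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = layer_means[j] - layer_means[i]
        if ms_err > 0:
            q = abs(diff) / math.sqrt(ms_err / n)
            p_adj = float(stats.studentized_range.sf(q, k, df2))
        else:
            p_adj = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "layer_a": LAYER_NAMES[i],
                "layer_b": LAYER_NAMES[j],
                "difference": float(diff),
                "p_adj": min(max(p_adj, 0.0), 1.0),
            }
        )
    return LayerComparison(
        f_statistic=float(f_stat),
        df=(df1, df2),
        p_value=float(p),
        layer_means=pd.Series(layer_means, index=list(LAYER_NAMES)),
        contrasts=pd.DataFrame(rows),
        epsilon=epsilon,
    )


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of layers."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


@dataclass
class EffectSizeResult:
    """Per-(parcel, layer) Cohen's d between groups, with a layer summary."""

    table: pd.DataFrame = field(repr=False)
    layer_mean_d: pd.Series = field(repr=False, default=None)
    best_layer: str = ""


def layer_effect_sizes(
    patient_profiles: pd.DataFrame, control_profiles: pd.DataFrame
) -> EffectSizeResult:
    """Cohen's d per (parcel, layer), patients vs controls.

    Uses subject-level values per (parcel, layer).  Cells with zero
    pooled SD are missing.  The summary reports the mean d per layer and
    which layer maximizes it.
    """
    if patient_profiles.empty or control_profiles.empty:
        raise ValueError("both groups must be non-empty")

    def pivot(df: pd.DataFrame) -> pd.DataFrame:
        return df.pivot_table(index=["parcel", "layer"], columns="subject", values="suvr")

    pat = pivot(patient_profiles)
    ctl = pivot(control_profiles)
    rows = []
    for key in pat.index:
        if key not in ctl.index:
            continue
        a = pat.loc[key].dropna().to_numpy(dtype=float)
        b = ctl.loc[key].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            d = float("nan")
        else:
            d = cohens_d(a, b)
        rows.append({"parcel": key[0], "layer": key[1], "cohens_d": d})
    table = pd.DataFrame(rows)
    layer_mean = table.groupby("layer")["cohens_d"].mean().reindex(list(LAYER_NAMES))
    best = str(layer_mean.idxmax()) if layer_mean.notna().any() else ""
    return EffectSizeResult(table=table, layer_mean_d=layer_mean, best_layer=best)
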