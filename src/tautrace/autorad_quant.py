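"""Autoradiography binding ratios and the correlation/regression battery.

Subfield binding ratios (target ROI mean over an AT8-negative white
matter reference mean) are joined with per-channel tau abundance and fed
to pooled Pearson correlations, partial correlations with region
cofactors, two-predictor standardized regression, per-subject
correlation-vs-abundance analysis, and intensity-vs-occupancy contrasts.

Conventions: two-sided p-values throughout; no multiple-testing
correction; undefined correlations propagate as NaN (never 0); pooled
(subfields across subjects) and per-subject modes never mix implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from shapely.geometry import Polygon

from .ihc_morphometry import StainImage, roi_pixel_mask

__all__ = [
    "BindingRatio",
    "CorrelationResult",
    "RegressionResult",
    "binding_ratio",
    "pooled_subfield_correlation",
    "partial_correlation",
    "celltype_regression",
    "per_subject_correlation_vs_abundance",
    "PerSubjectResult",
    "intensity_vs_occupancy",
]

#: canonical column names for joined subfield tables
CHANNEL_COLUMNS = {"NFT/CB": "nftcb_area_pct", "TA/TF": "tatf_area_pct"}


@dataclass
class BindingRatio:
    """Target/reference ROI-mean ratio for one subfield."""

    subfield_id: object
    target_mean: float
    reference_mean: float
    region_label: str | None = None  # e.g. 'cortical' | 'GM/WM boundary'

    def __post_init__(self) -> None:
        if not self.reference_mean > 0:
            raise ValueError("reference mean must be positive")

    @property
    def ratio(self) -> float:
        return self.target_mean / self.reference_mean


@dataclass
class CorrelationResult:
    """Pearson or partial correlation with sample size and p-value."""

    estimate: float
    n: int
    p_value: float
    covariates: tuple[str, ...] = ()
    method: str = "pearson"
    note: str = ""
    normality_p: float | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


@dataclass
class RegressionResult:
    """OLS on z-scored variables: standardized betas with per-coefficient p."""

    predictors: tuple[str, ...]
    beta: dict[str, float]
    p_value: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    r_squared: float
    n: int


def binding_ratio(
    arg: StainImage,
    target_roi: Polygon,
    reference_roi: Polygon,
    subfield_id: object = None,
    region_label: str | None = None,
) -> BindingRatio:
    """Ratio of ROI means on an autoradiography raster.

    ROI membership (pixel centers inside the polygon) is shared with the
    IHC module so subfield definitions transfer exactly.
    """
    t_mask = roi_pixel_mask(target_roi, arg.shape)
    r_mask = roi_pixel_mask(reference_roi, arg.shape)
    if not t_mask.any() or not r_mask.any():
        raise ValueError("ROI lies fully outside the image")
    ref_mean = float(arg.pixels[r_mask].mean())
    if ref_mean <= 0:
        raise ValueError("reference region mean must be positive")
    return BindingRatio(
        subfield_id=subfield_id,
        target_mean=float(arg.pixels[t_mask].mean()),
        reference_mean=ref_mean,
        region_label=region_label,
    )


def _pearson(x: np.ndarray, y: np.ndarray, covariates: tuple[str, ...] = (), method="pearson") -> CorrelationResult:
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(
            estimate=float("nan"), n=n, p_value=float("nan"),
            covariates=covariates, method=method, note="zero variance",
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(estimate=float(r), n=n, p_value=float(p), covariates=covariates, method=method)


def pooled_subfield_correlation(
    records: pd.DataFrame,
    channel: str,
    value_col: str = "binding_ratio",
    abundance_col: str | None = None,
) -> CorrelationResult:
    """Pooled Pearson correlation of channel tau abundance vs binding ratio.

    Pools subfields across subjects (the pooled-n design); n is reported
    alongside r.  Normality of the simple-regression residuals is checked
    with a Kolmogorov-Smirnov test and reported (``normality_p``), not
    enforced.
    """
    col = abundance_col or CHANNEL_COLUMNS.get(channel, channel)
    df = records[[col, value_col]].dropna()
    x = df[col].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    res = _pearson(x, y)
    if res.defined:
        slope, icpt = np.polyfit(x, y, 1)
        resid = y - (slope * x + icpt)
        sd = resid.std(ddof=1)
        if sd > 0:
            res.normality_p = float(stats.kstest((resid - resid.mean()) / sd, "norm").pvalue)
    return res


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> CorrelationResult:
    """Pearson correlation of residuals after removing covariates from both.

    Constant covariate columns are dropped (they carry no information
    beyond the intercept), so a constant covariate reproduces the plain
    Pearson r; remaining rank deficiency raises.  p from the t-transform
    with ``n - 2 - k`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y length mismatch")

    names: tuple[str, ...] = ()
    if covariates is None:
        C = np.empty((n, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            names = tuple(map(str, covariates.columns))
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            names = tuple(f"c{i}" for i in range(C.shape[1]))
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match n")
        keep = C.std(axis=0) > 0
        C = C[:, keep]
        names = tuple(nm for nm, k in zip(names, keep) if k)

    k = C.shape[1]
    if n < 4 and k > 0:
        raise ValueError("need n >= 4 for partial correlation")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(
            estimate=float("nan"), n=n, p_value=float("nan"),
            covariates=names, method="partial", note="zero variance",
        )
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return CorrelationResult(
            estimate=float("nan"), n=n, p_value=float("nan"),
            covariates=names, method="partial", note="zero residual variance",
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough observations for the covariate count")
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * math.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(estimate=r, n=n, p_value=float(p), covariates=names, method="partial")


def celltype_regression(
    records: pd.DataFrame,
    predictors: tuple[str, str] = ("NFT/CB", "TA/TF"),
    value_col: str = "binding_ratio",
) -> RegressionResult:
    """Two-predictor OLS of binding ratio on z-scored channel abundances.

    Predictor order is preserved in the output (neuronal/oligodendroglial
    channel first by default).  Perfectly collinear predictors raise.
    """
    cols = [CHANNEL_COLUMNS.get(p, p) for p in predictors]
    df = records[cols + [value_col]].dropna()
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError("not enough observations for the predictor count")
    X = df[cols].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    if X.shape[1] == 2:
        r12 = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        if abs(r12) >= 1.0 - 1e-12:
            raise ValueError("predictors are perfectly collinear")

    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    ci = model.conf_int(alpha=0.05)
    beta, p_value, conf = {}, {}, {}
    for j, name in enumerate(predictors):
        beta[name] = float(model.params[j + 1])
        p_value[name] = float(model.pvalues[j + 1])
        conf[name] = (float(ci[j + 1, 0]), float(ci[j + 1, 1]))
    return RegressionResult(
        predictors=tuple(predictors),
        beta=beta,
        p_value=p_value,
        conf_int=conf,
        r_squared=float(model.rsquared),
        n=n,
    )


@dataclass
class PerSubjectResult:
    """Within-subject correlations and their relation to overall abundance."""

    table: pd.DataFrame = field(repr=False)
    relation: CorrelationResult | None = None
    sensitivity_threshold: float = float("nan")
    r_cut: float = 0.5


def per_subject_correlation_vs_abundance(
    records: pd.DataFrame,
    channel: str,
    subject_col: str = "subject",
    value_col: str = "binding_ratio",
    abundance_col: str | None = None,
    min_subfields: int = 3,
    r_cut: float = 0.5,
) -> PerSubjectResult:
    """Within-subject r per subject, then r-vs-mean-abundance across subjects.

    Subjects with fewer than ``min_subfields`` subfields or zero variance
    get a missing (NaN) r and are excluded from the across-subject
    relation fit (linear, documented choice).  The sensitivity threshold
    is the smallest subject mean abundance such that every subject at or
    above it has within-subject r >= ``r_cut`` (the reference working
    point in this analysis is 0.2 area-%).
    """
    col = abundance_col or CHANNEL_COLUMNS.get(channel, channel)
    rows = []
    for subject, grp in records.groupby(subject_col, sort=True):
        grp = grp[[col, value_col]].dropna()
        x = grp[col].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        mean_ab = float(x.mean()) if len(x) else float("nan")
        if len(x) < min_subfields or np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(x, y)[0])
        rows.append(
            {"subject": subject, "mean_abundance": mean_ab, "r": r, "n_subfields": len(x),
             "defined": not math.isnan(r)}
        )
    table = pd.DataFrame(rows)

    ok = table[table["defined"]]
    relation = None
    if len(ok) >= 3:
        relation = _pearson(
            ok["mean_abundance"].to_numpy(float), ok["r"].to_numpy(float), method="pearson"
        )

    threshold = float("nan")
    ranked = ok.sort_values("mean_abundance", ascending=False)
    for _, row in ranked.iterrows():
        if row["r"] >= r_cut:
            threshold = float(row["mean_abundance"])
        else:
            break
    return PerSubjectResult(table=table, relation=relation, sensitivity_threshold=threshold, r_cut=r_cut)


def intensity_vs_occupancy(
    records: pd.DataFrame,
    intensity_col: str = "at8_mean_intensity",
    occupancy_col: str = "total_area_pct",
    value_col: str = "binding_ratio",
) -> dict[str, CorrelationResult]:
    """Side-by-side r(intensity, ratio) and r(occupancy, ratio) for one subject."""
    df = records[[intensity_col, occupancy_col, value_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 subfields")
    y = df[value_col].to_numpy(dtype=float)
    return {
        "intensity": _pearson(df[intensity_col].to_numpy(float), y),
        "occupancy": _pearson(df[occupancy_col].to_numpy(float), y),
    }
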