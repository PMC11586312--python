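"""Single-cell radiotracing arithmetic.

Decay correction to injection time, per-cell uptake, %ID*BW
normalization, signal-to-background QC, pellet purity, and the
cell-census extrapolation linking cell-level radioactivity to the PET
signal increment over the wild-type mean.

Activities are stored in Bq internally; injected doses are accepted in
MBq at the interface and converted.  Background activity is used only
for thresholding (no background subtraction is applied to pellet
activity); override by subtracting upstream if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "F18_HALF_LIFE_MIN",
    "BrainCellCensus",
    "CellPelletRecord",
    "QCResult",
    "PurityResult",
    "ExtrapolationResult",
    "decay_correct",
    "per_cell_uptake",
    "normalize_pidbw",
    "qc_signal_to_background",
    "qc_filter",
    "pellet_purity",
    "extrapolate_brain_signal",
]

#: fluorine-18 half-life in minutes
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class BrainCellCensus:
    """Published whole-brain cell numbers used for extrapolation."""

    n_neuron: int = 71_000_000
    n_astrocyte: int = 21_000_000

    def __post_init__(self) -> None:
        if self.n_neuron <= 0 or self.n_astrocyte <= 0:
            raise ValueError("census counts must be positive")


@dataclass
class CellPelletRecord:
    """One enriched cell pellet measured in the gamma counter."""

    mouse_id: str
    genotype: str  # TG | WT
    cell_type: str  # neuron | astrocyte
    cell_count: int
    measured_bq: float
    time_offset_min: float  # injection -> measurement
    background_bq: float
    injected_dose_mbq: float
    body_weight_g: float
    total_cells: int | None = None
    cd11b_pos: int | None = None
    acsa2_pos: int | None = None

    def __post_init__(self) -> None:
        if self.cell_count < 0 or self.measured_bq < 0 or self.time_offset_min < 0:
            raise ValueError("counts, activities and time offsets must be non-negative")


def decay_correct(bq: float, dt_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Activity back-corrected to injection time: ``bq * 2**(dt/half_life)``."""
    if dt_min < 0:
        raise ValueError("time offset must be non-negative")
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return bq * 2.0 ** (dt_min / half_life_min)


def per_cell_uptake(record: CellPelletRecord, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Decay-corrected pellet activity divided by the pellet's cell count (Bq/cell)."""
    if record.cell_count <= 0:
        raise ValueError("cell count must be positive")
    return decay_correct(record.measured_bq, record.time_offset_min, half_life_min) / record.cell_count


def normalize_pidbw(bq_per_cell: float, injected_dose_mbq: float, body_weight_g: float) -> float:
    """Percent injected dose times body weight per cell.

    ``(Bq/cell / injected Bq) * 100 * body weight (g)``; the dose is
    given in MBq.  The formula is the conventional one for this
    normalization (the name alone does not pin it down).
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return bq_per_cell / (injected_dose_mbq * 1e6) * 100.0 * body_weight_g


@dataclass
class QCResult:
    passed: bool
    ratio: float
    reason: str = ""


def qc_signal_to_background(record: CellPelletRecord, min_ratio: float = 2.0) -> QCResult:
    """Pass iff pellet activity is at least ``min_ratio``-fold above background."""
    if record.background_bq <= 0:
        raise ValueError("background activity must be positive")
    ratio = record.measured_bq / record.background_bq
    if ratio >= min_ratio:
        return QCResult(passed=True, ratio=ratio)
    return QCResult(
        passed=False,
        ratio=ratio,
        reason=f"signal-to-background {ratio:.3g} < {min_ratio:g}",
    )


def qc_filter(
    records: Sequence[CellPelletRecord], min_ratio: float = 2.0
) -> tuple[list[CellPelletRecord], pd.DataFrame]:
    """Split records into QC passes and an exclusion log (idempotent)."""
    passed, excluded = [], []
    for rec in records:
        qc = qc_signal_to_background(rec, min_ratio)
        if qc.passed:
            passed.append(rec)
        else:
            excluded.append(
                {"mouse_id": rec.mouse_id, "cell_type": rec.cell_type, "ratio": qc.ratio, "reason": qc.reason}
            )
    return passed, pd.DataFrame(excluded, columns=["mouse_id", "cell_type", "ratio", "reason"])


@dataclass
class PurityResult:
    purity: float
    passed: bool
    threshold: float


def pellet_purity(
    total: int,
    cd11b_pos: int,
    acsa2_pos: int,
    mode: str,
    acceptance_threshold: float = 0.85,
) -> PurityResult:
    """Flow-cytometry pellet purity.

    Neuron mode counts the marker-negative fraction,
    ``(total - cd11b_pos - acsa2_pos) / total``; astrocyte mode counts the
    ACSA-2-positive fraction.  The acceptance flag defaults to 0.85.
    """
    if total <= 0:
        raise ValueError("total cell count must be positive")
    if cd11b_pos < 0 or acsa2_pos < 0:
        raise ValueError("marker counts must be non-negative")
    if mode == "neuron":
        if cd11b_pos + acsa2_pos > total:
            raise ValueError("marker-positive cells exceed total")
        purity = (total - cd11b_pos - acsa2_pos) / total
    elif mode == "astrocyte":
        if acsa2_pos > total:
            raise ValueError("marker-positive cells exceed total")
        purity = acsa2_pos / total
    else:
        raise ValueError("mode must be 'neuron' or 'astrocyte'")
    return PurityResult(purity=purity, passed=purity > acceptance_threshold, threshold=acceptance_threshold)


@dataclass
class ExtrapolationResult:
    """Cell-census extrapolation vs PET increment, per mouse and summed."""

    per_mouse: pd.DataFrame = field(repr=False)
    predicted_sum: float = 0.0
    increment_sum: float = 0.0
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    census: BrainCellCensus = field(default_factory=BrainCellCensus)


def extrapolate_brain_signal(
    uptakes: pd.DataFrame,
    pet_increments: Mapping[str, float] | pd.Series,
    census: BrainCellCensus | None = None,
) -> ExtrapolationResult:
    """Extrapolate whole-brain activity from per-cell uptake and compare with PET.

    ``uptakes`` needs columns ``mouse_id``, ``bq_per_neuron``,
    ``bq_per_astrocyte`` (one row per mouse).  ``pet_increments`` maps
    mouse id to the PET activity increment over the WT cohort mean (Bq).
    The per-mouse prediction is
    ``n_neuron * Bq/neuron + n_astrocyte * Bq/astrocyte``; predictions
    and increments are compared per mouse, as cohort sums, and with a
    paired t test across mice.
    """
    census = census or BrainCellCensus()
    pet = pd.Series(pet_increments, dtype=float)
    mice = list(uptakes["mouse_id"])
    if len(mice) < 2:
        raise ValueError("need at least 2 mice with complete data")
    if set(mice) != set(pet.index):
        raise ValueError("mouse sets of uptakes and PET increments differ")
    if len(set(mice)) != len(mice):
        raise ValueError("duplicate mouse ids in uptake table")

    predicted = (
        census.n_neuron * uptakes["bq_per_neuron"].to_numpy(dtype=float)
        + census.n_astrocyte * uptakes["bq_per_astrocyte"].to_numpy(dtype=float)
    )
    increments = pet.loc[mice].to_numpy(dtype=float)
    residuals = predicted - increments

    scale = max(np.abs(predicted).max(), np.abs(increments).max(), 1.0)
    if np.all(np.abs(residuals) <= 1e-12 * scale):
        t_stat, p_val = 0.0, 1.0  # identical pairs: no detectable difference
    elif residuals.std(ddof=1) <= 1e-12 * scale:
        t_stat, p_val = math.copysign(math.inf, residuals.mean()), 0.0  # constant offset
    else:
        t_stat, p_val = stats.ttest_rel(predicted, increments)

    per_mouse = pd.DataFrame(
        {
            "mouse_id": mice,
            "predicted_bq": predicted,
            "pet_increment_bq": increments,
            "residual_bq": residuals,
        }
    )
    return ExtrapolationResult(
        per_mouse=per_mouse,
        predicted_sum=float(predicted.sum()),
        increment_sum=float(increments.sum()),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        census=census,
    )
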