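"""Per-lysosome -> per-cell -> per-condition aggregation and statistics.

A paired ROI becomes a lysosome measurement: its ratio is inverted through
the calibration curve to a pH, and its size is the 445-channel ROI area
converted to um^2.  Cells are summarized by the unweighted mean over their
lysosomes; conditions by the mean and SEM over cell means (cells weighted
equally, regardless of how many lysosomes they contribute).  A treatment
effect is the difference of condition means, Delta-pH = treated - control,
reported alongside the free-proton fold change 10^(-Delta-pH).  Also here:
the per-lysosome pH ECDF, the pH-size Pearson correlation, and the plain
two-sample t-tests used for condition comparisons.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve
from .roi_pairing import RoiPair

__all__ = [
    "LysosomeMeasurement",
    "CellSummary",
    "ConditionSummary",
    "ShiftResult",
    "measure_lysosomes",
    "assign_pairs_to_cells",
    "summarize",
    "shift",
    "proton_fold",
    "ecdf",
    "ph_size_correlation",
    "two_sample_test",
]


@dataclass(frozen=True)
class LysosomeMeasurement:
    experiment_id: str
    condition: str
    cell_id: int
    lysosome_id: int
    ratio: float
    ph: float
    area_um2: float
    clamped_flag: bool


@dataclass(frozen=True)
class CellSummary:
    cell_id: int
    n_lysosomes: int
    mean_ph: float
    mean_area_um2: float


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_cells: int
    mean_ph: float
    sem_ph: float
    mean_area_um2: float
    sem_area: float
    clamped_fraction: float = 0.0


@dataclass(frozen=True)
class ShiftResult:
    """Treated-minus-control shift; proton_fold = 10^(-delta_ph)."""

    delta_ph: float
    proton_fold: float
    delta_area_um2: float


def proton_fold(delta_ph: float) -> float:
    """Fold change in free [H+] implied by a pH shift: 10^(-delta_ph)."""
    return 10.0 ** (-delta_ph)


def assign_pairs_to_cells(pairs: Sequence[RoiPair], cell_label_mask: np.ndarray) -> dict[int, list[RoiPair]]:
    """Group pairs by the cell whose mask contains the 445 ROI centroid.

    Pairs whose centroid falls outside every cell footprint are dropped.
    Used for multi-cell fields; single-cell images can be grouped directly.
    """
    by_cell: dict[int, list[RoiPair]] = defaultdict(list)
    h, w = cell_label_mask.shape
    for p in pairs:
        r = int(round(p.roi_445.centroid[0]))
        c = int(round(p.roi_445.centroid[1]))
        if 0 <= r < h and 0 <= c < w:
            cell_id = int(cell_label_mask[r, c])
            if cell_id > 0:
                by_cell[cell_id].append(p)
    return dict(by_cell)


def measure_lysosomes(
    pairs_by_cell: Mapping[int, Sequence[RoiPair]],
    curve: CalibrationCurve,
    pixel_size_um: float,
    condition: str = "",
    experiment_id: str = "",
) -> list[LysosomeMeasurement]:
    """One measurement per surviving pair: pH via calibration inversion,
    area as the 445 ROI pixel count times pixel_size_um^2.

    Per-record inversion failures (non-finite ratios) are skipped without
    aborting the batch.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    out: list[LysosomeMeasurement] = []
    lysosome_id = 0
    for cell_id in sorted(pairs_by_cell):
        for pair in pairs_by_cell[cell_id]:
            lysosome_id += 1
            try:
                ph, flagged = curve.invert(pair.ratio)
            except ValueError:
                continue
            out.append(
                LysosomeMeasurement(
                    experiment_id=experiment_id,
                    condition=condition,
                    cell_id=int(cell_id),
                    lysosome_id=lysosome_id,
                    ratio=float(pair.ratio),
                    ph=float(ph),
                    area_um2=float(pair.roi_445.area_px) * pixel_size_um**2,
                    clamped_flag=bool(flagged),
                )
            )
    return out


def summarize(
    measurements: Sequence[LysosomeMeasurement],
    min_lysosomes_per_cell: int = 5,
) -> tuple[list[CellSummary], ConditionSummary]:
    """Cell means, then condition mean +- SEM over cell means.

    Cells with fewer than ``min_lysosomes_per_cell`` measurements are
    excluded.  The condition mean weights cells equally.  SEM is the sd of
    cell means over sqrt(n_cells) and requires >= 2 cells (NaN otherwise).
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    conditions = {m.condition for m in measurements}
    if len(conditions) != 1:
        raise ValueError(f"summarize expects a single condition, got {sorted(conditions)}")
    (condition,) = conditions

    by_cell: dict[int, list[LysosomeMeasurement]] = defaultdict(list)
    for m in measurements:
        by_cell[m.cell_id].append(m)
    cells: list[CellSummary] = []
    for cell_id in sorted(by_cell):
        recs = by_cell[cell_id]
        if len(recs) < min_lysosomes_per_cell:
            continue
        cells.append(
            CellSummary(
                cell_id=cell_id,
                n_lysosomes=len(recs),
                mean_ph=float(np.mean([m.ph for m in recs])),
                mean_area_um2=float(np.mean([m.area_um2 for m in recs])),
            )
        )
    if not cells:
        raise ValueError("no cell meets min_lysosomes_per_cell")
    ph_means = np.array([c.mean_ph for c in cells])
    area_means = np.array([c.mean_area_um2 for c in cells])
    n = len(cells)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    clamped = float(np.mean([m.clamped_flag for m in measurements]))
    summary = ConditionSummary(
        condition=condition,
        n_cells=n,
        mean_ph=float(ph_means.mean()),
        sem_ph=sem(ph_means),
        mean_area_um2=float(area_means.mean()),
        sem_area=sem(area_means),
        clamped_fraction=clamped,
    )
    return cells, summary


def shift(control: ConditionSummary, treated: ConditionSummary) -> ShiftResult:
    """Treatment-induced shift: delta_ph = treated - control (acidification
    is negative), with the implied free-proton fold change."""
    delta_ph = treated.mean_ph - control.mean_ph
    return ShiftResult(
        delta_ph=float(delta_ph),
        proton_fold=proton_fold(delta_ph),
        delta_area_um2=float(treated.mean_area_um2 - control.mean_area_um2),
    )


def ecdf(values: Sequence[float]) -> np.ndarray:
    """Empirical CDF at the sorted unique values: fraction of values <= x.

    Returns an (k, 2) array of (x, fraction); non-decreasing, ending at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf of empty input")
    xs = np.unique(values)
    fractions = np.searchsorted(np.sort(values), xs, side="right") / values.size
    return np.column_stack([xs, fractions])


def ph_size_correlation(measurements: Sequence[LysosomeMeasurement]) -> tuple[float, float]:
    """Pearson correlation between individual-lysosome pH and area (um^2),
    with the two-sided t-distribution p-value."""
    if len(measurements) < 3:
        raise ValueError("need >= 3 measurements")
    ph = np.array([m.ph for m in measurements])
    area = np.array([m.area_um2 for m in measurements])
    if np.std(ph) == 0 or np.std(area) == 0:
        raise ValueError("zero variance in pH or size")
    res = stats.pearsonr(ph, area)
    return float(res.statistic), float(res.pvalue)


def two_sample_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test: Student's pooled-variance by default (Welch by
    flag) for unpaired data, paired t on differences otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise ValueError("paired test needs equal lengths >= 2")
        if np.std(a - b, ddof=1) == 0:
            raise ValueError("degenerate: zero variance of paired differences")
        res = stats.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("unpaired test needs >= 2 samples per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise ValueError("degenerate: zero variance in both groups")
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
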