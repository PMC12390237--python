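"""Waterborne vs dietary source apportionment.

Relative importance is computed per treatment group x day cell from the cell
means of new accumulation (dietary values already daily-equivalent), then
summarized across cells. Cells where noise pushed either route's mean
negative, or the total non-positive, are excluded from summaries with their
flag preserved. A percentile bootstrap (resampling mussels within group x
day, controls included) attaches uncertainty to the summary mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .accounting import NewAccumulation, dietary_scaling_factor
from .core import DIETARY_COL, WATERBORNE_COL, AnalysisConfig, MeasurementTable, Route
from .errors import ConfigurationError, InsufficientDataError, PairingError

__all__ = [
    "ApportionmentCell",
    "ApportionmentSummary",
    "apportion_cell",
    "summarize_apportionment",
    "apportion_table",
    "bootstrap_apportionment",
]


@dataclass(frozen=True)
class ApportionmentCell:
    """Relative importance (percent) of each route in one group x day cell."""

    group: str
    day: int
    frac_waterborne: float
    frac_dietary: float
    excluded: bool


@dataclass(frozen=True)
class ApportionmentSummary:
    """Mean/SD/range of route shares over non-excluded cells, plus their ratio."""

    mean_w: float
    sd_w: float
    range_w: tuple[float, float]
    mean_d: float
    sd_d: float
    range_d: tuple[float, float]
    ratio: float
    n_cells: int
    bootstrap_ci: tuple[float, float] | None = None


def apportion_cell(new_w: NewAccumulation, new_d: NewAccumulation) -> ApportionmentCell:
    """Route shares for one cell from the two routes' mean new accumulation.

    ``frac_waterborne = 100 * mean_w / (mean_w + mean_d)``; the cell is
    excluded (fractions NaN) if either mean is negative or the total is
    non-positive.
    """
    if (new_w.group, new_w.day) != (new_d.group, new_d.day):
        raise PairingError(
            f"cells do not match: ({new_w.group}, {new_w.day}) vs "
            f"({new_d.group}, {new_d.day})"
        )
    if new_w.route is not Route.WATERBORNE or new_d.route is not Route.DIETARY:
        raise PairingError("apportion_cell expects (waterborne, dietary) in that order")
    total = new_w.mean + new_d.mean
    excluded = new_w.mean < 0 or new_d.mean < 0 or total <= 0
    if excluded:
        fw = fd = float("nan")
    else:
        fw = 100.0 * new_w.mean / total
        fd = 100.0 - fw
    return ApportionmentCell(
        group=new_w.group, day=new_w.day, frac_waterborne=fw, frac_dietary=fd,
        excluded=excluded,
    )


def _per_mussel_cell(new_w: NewAccumulation, new_d: NewAccumulation) -> ApportionmentCell:
    """Variant: average per-mussel fractions instead of the fraction of means."""
    w = np.asarray(new_w.values)
    d = np.asarray(new_d.values)
    if w.size != d.size:
        raise PairingError("per-mussel apportionment needs equal cell sizes")
    tot = w + d
    ok = (w >= 0) & (d >= 0) & (tot > 0)
    if not ok.any():
        return ApportionmentCell(new_w.group, new_w.day, float("nan"), float("nan"), True)
    fw = float((100.0 * w[ok] / tot[ok]).mean())
    return ApportionmentCell(new_w.group, new_w.day, fw, 100.0 - fw, False)


def summarize_apportionment(
    cells: Sequence[ApportionmentCell],
    bootstrap_ci: tuple[float, float] | None = None,
) -> ApportionmentSummary:
    """Summarize route shares over the non-excluded cells."""
    kept = [c for c in cells if not c.excluded]
    if not kept:
        raise InsufficientDataError("all apportionment cells are excluded")
    fw = np.array([c.frac_waterborne for c in kept])
    fd = np.array([c.frac_dietary for c in kept])
    sd_w = float(fw.std(ddof=1)) if fw.size > 1 else 0.0
    mean_w, mean_d = float(fw.mean()), float(fd.mean())
    ratio = mean_w / mean_d if mean_d > 0 else float("inf")
    return ApportionmentSummary(
        mean_w=mean_w,
        sd_w=sd_w,
        range_w=(float(fw.min()), float(fw.max())),
        mean_d=mean_d,
        sd_d=sd_w,  # complements: identical spread
        range_d=(float(fd.min()), float(fd.max())),
        ratio=ratio,
        n_cells=len(kept),
        bootstrap_ci=bootstrap_ci,
    )


def apportion_table(
    new_accum: Sequence[NewAccumulation], per_mussel: bool = False
) -> list[ApportionmentCell]:
    """Pair waterborne/dietary cells by (group, day) and apportion each."""
    w_cells = {(c.group, c.day): c for c in new_accum if c.route is Route.WATERBORNE}
    d_cells = {(c.group, c.day): c for c in new_accum if c.route is Route.DIETARY}
    if set(w_cells) != set(d_cells):
        raise PairingError(
            f"unpaired cells: waterborne-only {sorted(set(w_cells) - set(d_cells))}, "
            f"dietary-only {sorted(set(d_cells) - set(w_cells))}"
        )
    fn = _per_mussel_cell if per_mussel else apportion_cell
    return [fn(w_cells[key], d_cells[key]) for key in sorted(w_cells)]


def bootstrap_apportionment(
    table: MeasurementTable,
    config: AnalysisConfig,
    reps: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile bootstrap CI (2.5/97.5) for the summary mean waterborne share.

    Mussels are resampled with replacement within every group x day stratum
    (control strata included, so background uncertainty propagates); the full
    accounting + apportionment is recomputed per replicate. Vectorized over
    replicates, so thousands of reps run in well under a second.
    """
    if reps < 100:
        raise ConfigurationError(f"bootstrap needs reps >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    design = table.design
    S = dietary_scaling_factor(design.feeding_hours_per_day, design.day_hours)

    def cell_rep_means(col: str) -> tuple[np.ndarray, dict[tuple[str, int], np.ndarray]]:
        """(reps,) control-pooled background and per-cell (reps,) treatment means."""
        ctrl_parts = []
        for day in design.sample_days:
            vals = table.group_day(design.control_group, day)[col].to_numpy(float)
            if vals.size:
                idx = rng.integers(0, vals.size, size=(reps, vals.size))
                ctrl_parts.append(vals[idx])
        if not ctrl_parts:
            raise InsufficientDataError("no control rows to bootstrap")
        bg = np.concatenate(ctrl_parts, axis=1).mean(axis=1)
        cells = {}
        for group in design.treatment_groups:
            for day in design.sample_days:
                vals = table.group_day(group, day)[col].to_numpy(float)
                if vals.size == 0:
                    continue
                idx = rng.integers(0, vals.size, size=(reps, vals.size))
                cells[(group, day)] = vals[idx].mean(axis=1)
        return bg, cells

    bg_w, w_cells = cell_rep_means(WATERBORNE_COL)
    bg_d, d_cells = cell_rep_means(DIETARY_COL)

    frac = np.full((reps, len(w_cells)), np.nan)
    for j, key in enumerate(sorted(w_cells)):
        mw = w_cells[key] - bg_w
        md = S * (d_cells[key] - bg_d)
        tot = mw + md
        ok = (mw >= 0) & (md >= 0) & (tot > 0)
        frac[ok, j] = 100.0 * mw[ok] / tot[ok]

    with np.errstate(invalid="ignore"):
        mean_w = np.nanmean(frac, axis=1)
    mean_w = mean_w[~np.isnan(mean_w)]
    if mean_w.size == 0:
        raise InsufficientDataError("every bootstrap replicate had all cells excluded")
    low, high = np.percentile(mean_w, [2.5, 97.5])
    return float(low), float(high)
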