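"""Tracer accounting: backgrounds, feeding-window scaling, new accumulation, QC.

The accounting chain is: estimate the control-group background for each
tracer, subtract it from exposed-group concentrations, and express dietary
values on a daily-equivalent basis by multiplying by the feeding-window
scaling factor (day_hours / feeding_hours). Negative cell means are flagged,
never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ROUTE_COLUMNS,
    AnalysisConfig,
    MeasurementTable,
    Route,
    TracerSpec,
)
from .errors import MissingControlError

__all__ = [
    "BackgroundEstimate",
    "NewAccumulation",
    "estimate_background",
    "dietary_scaling_factor",
    "compute_new_accumulation",
    "tracer_specificity",
    "qc_spike_recovery",
    "background_total_cd",
]


@dataclass(frozen=True)
class BackgroundEstimate:
    """Control-group tracer concentration: mean, SD and per-day breakdown."""

    tracer: str
    mean: float
    sd: float
    n: int
    per_day: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("background estimate needs n >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class NewAccumulation:
    """Per-mussel new accumulation for one group x day x tracer cell.

    Dietary values are already daily-equivalent (scaling applied). The mean
    and SD are derived from ``values``; a cell with negative mean is flagged.
    """

    group: str
    day: int
    tracer: str
    route: Route
    values: tuple[float, ...]
    mean: float = field(init=False)
    sd: float = field(init=False)
    flagged_negative: bool = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty cell {self.group} day {self.day}")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))
        object.__setattr__(self, "mean", float(arr.mean()))
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "flagged_negative", bool(arr.mean() < 0))


def _resolve_column(tracer: TracerSpec | Route | str) -> tuple[str, str, Route]:
    """Map a tracer spec / route to (column, label, route)."""
    if isinstance(tracer, TracerSpec):
        route = tracer.route
        label = tracer.label
    else:
        route = Route(tracer)
        label = route.value
    return ROUTE_COLUMNS[route], label, route


def estimate_background(
    table: MeasurementTable, tracer: TracerSpec | Route | str
) -> BackgroundEstimate:
    """Mean and SD of the control group's tracer concentration.

    Pooled over all sample days (the default downstream), with per-day means
    retained for the time-matched-control option.
    """
    col, label, _ = _resolve_column(tracer)
    rows = table.control_rows()  # raises MissingControlError if absent
    values = rows[col].to_numpy(dtype=float)
    per_day = {
        int(day): float(sub[col].mean()) for day, sub in rows.groupby("day")
    }
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return BackgroundEstimate(
        tracer=label, mean=float(values.mean()), sd=sd, n=int(values.size), per_day=per_day
    )


def dietary_scaling_factor(feeding_hours: float, day_hours: float = 24.0) -> float:
    """Daily-equivalent factor for a limited feeding window: day_hours / feeding_hours.

    A 3 h feeding window in a 24 h day gives 8.
    """
    if feeding_hours <= 0 or day_hours <= 0:
        raise ValueError("hours must be positive")
    if feeding_hours > day_hours:
        raise ValueError(
            f"feeding_hours ({feeding_hours}) cannot exceed day_hours ({day_hours})"
        )
    return day_hours / feeding_hours


def compute_new_accumulation(
    table: MeasurementTable,
    config: AnalysisConfig,
    *,
    time_matched_control: bool = False,
    purity_correction: bool = False,
) -> list[NewAccumulation]:
    """New accumulation for every treatment group x day x tracer.

    Waterborne: ``conc - background_w``. Dietary: ``S * (conc - background_d)``
    with ``S = day_hours / feeding_hours``; the result is daily-equivalent.
    Per-mussel values are retained; cells with negative mean are flagged, not
    clipped.

    ``time_matched_control`` subtracts the control mean of the same sample day
    instead of the pooled mean. ``purity_correction`` divides new accumulation
    by the tracer's spike purity (sensitivity analysis; off by default).
    """
    design = table.design
    S = dietary_scaling_factor(design.feeding_hours_per_day, design.day_hours)
    out: list[NewAccumulation] = []
    for route in (Route.WATERBORNE, Route.DIETARY):
        spec = config.tracer(route)
        col = ROUTE_COLUMNS[route]
        bg = estimate_background(table, spec)
        scale = S if route is Route.DIETARY else 1.0
        if purity_correction:
            scale /= spec.spike_purity
        for group in design.treatment_groups:
            for day in design.sample_days:
                rows = table.group_day(group, day)
                if rows.empty:
                    continue
                b = bg.per_day.get(day, bg.mean) if time_matched_control else bg.mean
                vals = scale * (rows[col].to_numpy(dtype=float) - b)
                out.append(
                    NewAccumulation(
                        group=group, day=day, tracer=spec.label, route=route,
                        values=tuple(vals),
                    )
                )
    return out


def tracer_specificity(
    conc_target_tracer: float, conc_other_tracer: float, threshold: float = 0.99
) -> tuple[float, bool]:
    """Fraction of total tracer signal carried by the target isotope.

    Returns ``(target / (target + other), fraction >= threshold)``.
    """
    if conc_target_tracer < 0 or conc_other_tracer < 0:
        raise ValueError("concentrations must be >= 0")
    total = conc_target_tracer + conc_other_tracer
    if total == 0:
        raise ValueError("specificity undefined: both concentrations are zero")
    fraction = conc_target_tracer / total
    return fraction, fraction >= threshold


def qc_spike_recovery(
    measured: float, certified: float, tolerance: float = 0.10
) -> tuple[float, bool]:
    """Relative deviation of a spike-recovery measurement from the certified value.

    Returns ``(|measured - certified| / certified, deviation < tolerance)``.
    """
    if certified <= 0:
        raise ValueError("certified concentration must be > 0")
    deviation = abs(measured - certified) / certified
    return deviation, deviation < tolerance


def background_total_cd(tracer_conc: float, natural_abundance: float) -> float:
    """Total background Cd implied by one tracer isotope at natural composition.

    ``tracer_conc / natural_abundance`` -- valid only for unexposed tissue
    where the isotope mix is natural.
    """
    if not 0.0 < natural_abundance < 1.0:
        raise ValueError(f"natural_abundance must be in (0, 1), got {natural_abundance}")
    if tracer_conc < 0:
        raise ValueError("tracer concentration must be >= 0")
    return tracer_conc / natural_abundance
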