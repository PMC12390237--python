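"""Influx-rate estimation: linear regression of new accumulation on time.

The influx rate J_in (ug/g/d) for one group x tracer is the OLS slope of
per-mussel new accumulation against exposure day. The default fit keeps a
free intercept (background subtraction should leave it near zero); a
through-origin variant is available. No synthetic (0, 0) point is added.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .accounting import NewAccumulation
from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "InfluxEstimate",
    "InfluxSummary",
    "estimate_influx",
    "summarize_influx",
    "influx_ratio",
    "estimate_group_influxes",
]


@dataclass(frozen=True)
class InfluxEstimate:
    """One group x tracer regression: slope (J_in), its SE and fit diagnostics."""

    group: str
    tracer: str
    j_in: float
    slope_se: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class InfluxSummary:
    """Cross-group summary of influx rates for one tracer (treatment groups only)."""

    tracer: str
    mean_j_in: float
    sd_j_in: float
    min_j_in: float
    max_j_in: float
    per_group: tuple[InfluxEstimate, ...]


def _points(cells: Sequence[NewAccumulation]) -> tuple[np.ndarray, np.ndarray]:
    t, y = [], []
    for cell in cells:
        t.extend([float(cell.day)] * len(cell.values))
        y.extend(cell.values)
    return np.asarray(t), np.asarray(y)


def estimate_influx(
    new_accum: Sequence[NewAccumulation], through_origin: bool = False
) -> InfluxEstimate:
    """OLS of per-mussel new accumulation on exposure day for one group x tracer.

    With a free intercept at least two distinct days are required; through the
    origin one suffices. Raises :class:`InsufficientDataError` /
    :class:`DegenerateDesignError` otherwise.
    """
    if not new_accum:
        raise InsufficientDataError("no new-accumulation cells given")
    groups = {c.group for c in new_accum}
    tracers = {c.tracer for c in new_accum}
    if len(groups) > 1 or len(tracers) > 1:
        raise InsufficientDataError(
            f"estimate_influx expects one group x tracer, got groups={sorted(groups)} "
            f"tracers={sorted(tracers)}"
        )
    t, y = _points(new_accum)
    n = t.size
    distinct = np.unique(t).size

    if through_origin:
        if distinct < 1:
            raise InsufficientDataError("need >= 1 day for a through-origin fit")
        stt = float(t @ t)
        if stt == 0.0:
            raise DegenerateDesignError("all days are zero: slope not identifiable")
        slope = float(t @ y) / stt
        resid = y - slope * t
        dof = n - 1
        se = math.sqrt(float(resid @ resid) / dof / stt) if dof > 0 else float("nan")
        ss_tot = float(y @ y)  # uncentered for a no-intercept model
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        intercept = 0.0
    else:
        if distinct < 2:
            if n >= 2 and distinct == 1:
                raise DegenerateDesignError(
                    "zero variance in exposure day: slope not identifiable"
                )
            raise InsufficientDataError(
                f"need >= 2 distinct days for a free-intercept fit, got {distinct}"
            )
        tbar, ybar = t.mean(), y.mean()
        sxx = float(((t - tbar) ** 2).sum())
        sxy = float(((t - tbar) * (y - ybar)).sum())
        slope = sxy / sxx
        intercept = float(ybar - slope * tbar)
        resid = y - (intercept + slope * t)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - ybar) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = n - 2
        se = math.sqrt(ss_res / dof / sxx) if dof > 0 else float("nan")

    return InfluxEstimate(
        group=new_accum[0].group,
        tracer=new_accum[0].tracer,
        j_in=slope,
        slope_se=se,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        n_points=int(n),
    )


def estimate_group_influxes(
    new_accum: Iterable[NewAccumulation], through_origin: bool = False
) -> list[InfluxEstimate]:
    """Run :func:`estimate_influx` for every (group, tracer) present."""
    by_key: dict[tuple[str, str], list[NewAccumulation]] = {}
    for cell in new_accum:
        by_key.setdefault((cell.group, cell.tracer), []).append(cell)
    return [
        estimate_influx(cells, through_origin=through_origin)
        for (_, _), cells in sorted(by_key.items())
    ]


def summarize_influx(
    estimates: Sequence[InfluxEstimate], tracer: str
) -> InfluxSummary:
    """Mean +/- sample SD and range of group-level slopes for one tracer."""
    sel = tuple(e for e in estimates if e.tracer == tracer)
    if not sel:
        raise InsufficientDataError(f"no influx estimates for tracer {tracer!r}")
    slopes = np.array([e.j_in for e in sel])
    if slopes.size == 1:
        warnings.warn(
            f"single influx estimate for {tracer!r}: SD reported as 0", stacklevel=2
        )
        sd = 0.0
    else:
        sd = float(slopes.std(ddof=1))
    return InfluxSummary(
        tracer=tracer,
        mean_j_in=float(slopes.mean()),
        sd_j_in=sd,
        min_j_in=float(slopes.min()),
        max_j_in=float(slopes.max()),
        per_group=sel,
    )


def influx_ratio(summary_w: InfluxSummary, summary_d: InfluxSummary) -> float:
    """Fold difference of mean influx rates: waterborne / dietary."""
    if summary_d.mean_j_in <= 0:
        raise ValueError(
            f"dietary mean influx must be > 0, got {summary_d.mean_j_in}"
        )
    return summary_w.mean_j_in / summary_d.mean_j_in
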