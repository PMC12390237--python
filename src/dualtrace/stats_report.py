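"""Supporting statistics (ANOVA, t-tests, letter groupings) and report assembly."""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .accounting import (
    NewAccumulation,
    compute_new_accumulation,
    dietary_scaling_factor,
    estimate_background,
)
from .apportionment import (
    ApportionmentCell,
    apportion_table,
    bootstrap_apportionment,
    summarize_apportionment,
)
from .core import AnalysisConfig, MeasurementTable, Route, config_to_dict
from .errors import DependencyError, InsufficientDataError
from .kinetics import estimate_group_influxes, influx_ratio, summarize_influx

__all__ = [
    "GroupComparison",
    "compare_growth",
    "compare_importance",
    "build_report",
    "run_analysis",
    "validate_report",
    "render_markdown",
]

GROWTH_VARIABLES = ("shell_length_cm", "dry_weight_g")

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """One hypothesis test comparing groups (or routes) on a variable."""

    variable: str
    test: str  # "one_way_anova" | "t_test"
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    significant: bool
    scope: str = "across_groups"  # or "across_days" / "paired_routes"
    stratum: str | None = None  # the day (or group) the comparison is within
    letters: Mapping[str, str] | None = None


def _welch_anova(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, p)."""
    k = len(samples)
    n = np.array([s.size for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    var = np.array([s.var(ddof=1) for s in samples])
    if np.any(var == 0):
        var = np.where(var == 0, 1e-300, var)
    w = n / var
    mw = float((w * means).sum() / w.sum())
    a = float((w * (means - mw) ** 2).sum() / (k - 1))
    tmp = float((((1 - w / w.sum()) ** 2) / (n - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * tmp
    f = a / b
    df2 = (k * k - 1.0) / (3.0 * tmp)
    p = float(stats.f.sf(f, k - 1, df2))
    return f, p


def _anova(samples: Sequence[np.ndarray], welch: bool) -> tuple[float, float]:
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # all observations identical: no evidence either way
        return 0.0, 1.0
    if welch:
        return _welch_anova(samples)
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def _tukey_letters(
    values: Mapping[str, np.ndarray], alpha: float = ALPHA
) -> dict[str, str]:
    """Compact letter display from Tukey HSD pairwise tests (insert-absorb)."""
    names = sorted(values, key=lambda g: float(values[g].mean()))
    res = stats.tukey_hsd(*(values[g] for g in names))
    sig_pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if res.pvalue[i, j] < alpha
    ]
    sets: list[set[str]] = [set(names)]
    for a, b in sig_pairs:
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for sub in (s - {a}, s - {b}):
                if sub and not any(sub <= other for other in sets):
                    sets.append(sub)
    sets = [s for s in sets if not any(s < other for other in sets)]
    sets.sort(key=lambda s: min(names.index(g) for g in s))
    letters = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in sorted(s, key=names.index):
            letters[g] += letter
    return letters


def compare_growth(
    table: MeasurementTable,
    welch: bool = False,
    include_letters: bool = True,
    alpha: float = ALPHA,
) -> list[GroupComparison]:
    """One-way ANOVAs of shell length and dry weight.

    Primary comparisons are across groups within each sample day; across-day
    comparisons within each group are also emitted (``scope="across_days"``).
    Tukey HSD compact letter displays are attached unless disabled.
    """
    df = table.data
    out: list[GroupComparison] = []

    def run(variable: str, scope: str, stratum: str, samples: dict[str, np.ndarray]):
        if len(samples) < 2 or any(v.size < 2 for v in samples.values()):
            raise InsufficientDataError(
                f"{variable} {scope} ({stratum}): need >= 2 levels with >= 2 obs each"
            )
        f, p = _anova(list(samples.values()), welch)
        letters = _tukey_letters(samples, alpha) if include_letters else None
        out.append(
            GroupComparison(
                variable=variable,
                test="one_way_anova",
                statistic=f,
                p_value=p,
                groups=tuple(samples),
                significant=bool(p < alpha),
                scope=scope,
                stratum=stratum,
                letters=letters,
            )
        )

    for variable in GROWTH_VARIABLES:
        for day in table.design.sample_days:
            sub = df[df["day"] == day]
            samples = {
                g: s[variable].to_numpy(float)
                for g, s in sub.groupby("group")
                if len(s)
            }
            run(variable, "across_groups", f"day{day}", samples)
        for group in table.design.group_names:
            sub = df[df["group"] == group]
            samples = {
                f"day{d}": s[variable].to_numpy(float)
                for d, s in sub.groupby("day")
                if len(s)
            }
            run(variable, "across_days", group, samples)
    return out


def compare_importance(cells: Sequence[ApportionmentCell]) -> GroupComparison:
    """Paired t-test of waterborne vs dietary relative importance across cells."""
    kept = [c for c in cells if not c.excluded]
    if len(kept) < 2:
        raise InsufficientDataError(
            f"need >= 2 non-excluded cells for a paired t-test, got {len(kept)}"
        )
    fw = np.array([c.frac_waterborne for c in kept])
    fd = np.array([c.frac_dietary for c in kept])
    diff = fw - fd
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            t, p = 0.0, 1.0
        else:  # constant nonzero difference: evidence is overwhelming
            t, p = math.copysign(math.inf, diff.mean()), 0.0
    else:
        t, p = stats.ttest_rel(fw, fd)
    return GroupComparison(
        variable="relative_importance",
        test="t_test",
        statistic=float(t),
        p_value=float(p),
        groups=("waterborne", "dietary"),
        significant=bool(p < ALPHA),
        scope="paired_routes",
        stratum=None,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

REPORT_REQUIRED_KEYS = (
    "config",
    "dietary_scaling_factor",
    "backgrounds",
    "new_accumulation",
    "influx",
    "apportionment",
    "comparisons",
    "flags",
)


def _comparison_to_dict(c: GroupComparison) -> dict:
    d = dataclasses.asdict(c)
    d["groups"] = list(d["groups"])
    if d["letters"] is not None:
        d["letters"] = dict(d["letters"])
    return d


def build_report(
    config: AnalysisConfig,
    backgrounds: Mapping[str, object],
    new_accum: Sequence[NewAccumulation],
    influx_estimates,
    influx_summaries: Mapping[str, object],
    ratio: float,
    cells: Sequence[ApportionmentCell],
    apportionment_summary,
    growth_comparisons: Sequence[GroupComparison],
    importance_comparison: GroupComparison,
    flags: Mapping[str, object],
    timestamp: str | None = None,
) -> dict:
    """Assemble the full JSON-serializable analysis report.

    Every stage output is required; a missing one raises
    :class:`DependencyError`.
    """
    stages = {
        "backgrounds": backgrounds,
        "new_accumulation": new_accum,
        "influx_estimates": influx_estimates,
        "influx_summaries": influx_summaries,
        "apportionment_cells": cells,
        "apportionment_summary": apportionment_summary,
        "growth_comparisons": growth_comparisons,
        "importance_comparison": importance_comparison,
    }
    for name, value in stages.items():
        if value is None:
            raise DependencyError(f"stage output {name!r} is missing")
    report = {
        "config": config_to_dict(config),
        "dietary_scaling_factor": config.dietary_scaling_factor,
        "backgrounds": {
            route: dataclasses.asdict(bg) for route, bg in backgrounds.items()
        },
        "new_accumulation": [
            {
                "group": c.group,
                "day": c.day,
                "tracer": c.tracer,
                "route": c.route.value,
                "mean": c.mean,
                "sd": c.sd,
                "n": len(c.values),
                "flagged_negative": c.flagged_negative,
            }
            for c in new_accum
        ],
        "influx": {
            "estimates": [dataclasses.asdict(e) for e in influx_estimates],
            "summaries": {
                route: {
                    k: v
                    for k, v in dataclasses.asdict(s).items()
                    if k != "per_group"
                }
                for route, s in influx_summaries.items()
            },
            "ratio_waterborne_over_dietary": ratio,
        },
        "apportionment": {
            "cells": [dataclasses.asdict(c) for c in cells],
            "summary": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(apportionment_summary).items()
            },
        },
        "comparisons": {
            "growth": [_comparison_to_dict(c) for c in growth_comparisons],
            "importance": _comparison_to_dict(importance_comparison),
        },
        "flags": dict(flags),
        "timestamp": timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    validate_report(report)
    return report


def validate_report(report: Mapping) -> None:
    """Check the report against its documented schema (required keys)."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise DependencyError(f"report is missing sections: {missing}")


def run_analysis(
    table: MeasurementTable,
    config: AnalysisConfig,
    *,
    bootstrap_reps: int = 0,
    seed: int | None = None,
    through_origin: bool | None = None,
    time_matched_control: bool = False,
    per_mussel: bool = False,
    welch: bool = False,
    timestamp: str | None = None,
) -> dict:
    """Run accounting -> kinetics -> apportionment -> statistics and build the report."""
    through_origin = (
        config.regression_through_origin if through_origin is None else through_origin
    )
    backgrounds = {
        route.value: estimate_background(table, config.tracer(route))
        for route in (Route.WATERBORNE, Route.DIETARY)
    }
    new_accum = compute_new_accumulation(
        table, config, time_matched_control=time_matched_control
    )
    estimates = estimate_group_influxes(new_accum, through_origin=through_origin)
    summaries = {
        route.value: summarize_influx(estimates, config.tracer(route).label)
        for route in (Route.WATERBORNE, Route.DIETARY)
    }
    ratio = influx_ratio(summaries["waterborne"], summaries["dietary"])
    cells = apportion_table(new_accum, per_mussel=per_mussel)
    ci = None
    if bootstrap_reps:
        ci = bootstrap_apportionment(
            table, config, reps=bootstrap_reps,
            seed=config.rng_seed if seed is None else seed,
        )
    app_summary = summarize_apportionment(cells, bootstrap_ci=ci)
    growth = compare_growth(table, welch=welch)
    importance = compare_importance(cells)
    flags = {
        "through_origin": through_origin,
        "time_matched_control": time_matched_control,
        "per_mussel_apportionment": per_mussel,
        "welch_anova": welch,
        "bootstrap_reps": bootstrap_reps,
        "purity_correction": False,
    }
    return build_report(
        config,
        backgrounds,
        new_accum,
        estimates,
        summaries,
        ratio,
        cells,
        app_summary,
        growth,
        importance,
        flags,
        timestamp=timestamp,
    )


def render_markdown(report: Mapping) -> str:
    """Render a report dict to a human-readable Markdown document."""
    validate_report(report)
    lines = ["# Dual-tracer bioaccumulation report", ""]
    lines.append(f"Dietary scaling factor: {report['dietary_scaling_factor']:g}")
    lines.append("")
    lines.append("## Backgrounds (control group)")
    for route, bg in report["backgrounds"].items():
        lines.append(
            f"- {route} ({bg['tracer']}): {bg['mean']:.3f} +/- {bg['sd']:.3f} "
            f"ug/g dw (n={bg['n']})"
        )
    lines.append("")
    lines.append("## Influx rates (J_in, ug/g/d)")
    lines.append("")
    lines.append("| group | tracer | J_in | SE | intercept | R2 | n |")
    lines.append("|---|---|---|---|---|---|---|")
    for e in report["influx"]["estimates"]:
        lines.append(
            f"| {e['group']} | {e['tracer']} | {e['j_in']:.4f} | {e['slope_se']:.4f} "
            f"| {e['intercept']:.4f} | {e['r_squared']:.4f} | {e['n_points']} |"
        )
    lines.append("")
    for route, s in report["influx"]["summaries"].items():
        lines.append(
            f"- {route}: mean {s['mean_j_in']:.3f} +/- {s['sd_j_in']:.3f} "
            f"(range {s['min_j_in']:.3f}-{s['max_j_in']:.3f})"
        )
    lines.append(
        f"- waterborne / dietary fold: "
        f"{report['influx']['ratio_waterborne_over_dietary']:.1f}"
    )
    lines.append("")
    s = report["apportionment"]["summary"]
    lines.append("## Source apportionment (relative importance, %)")
    lines.append(
        f"- waterborne: {s['mean_w']:.1f} +/- {s['sd_w']:.1f} "
        f"(range {s['range_w'][0]:.1f}-{s['range_w'][1]:.1f})"
    )
    lines.append(
        f"- dietary: {s['mean_d']:.1f} +/- {s['sd_d']:.1f} "
        f"(range {s['range_d'][0]:.1f}-{s['range_d'][1]:.1f})"
    )
    lines.append(f"- ratio waterborne/dietary: {s['ratio']:.1f}")
    if s.get("bootstrap_ci"):
        lines.append(
            f"- bootstrap 95% CI for mean waterborne share: "
            f"({s['bootstrap_ci'][0]:.1f}, {s['bootstrap_ci'][1]:.1f})"
        )
    lines.append("")
    imp = report["comparisons"]["importance"]
    lines.append(
        f"Paired t-test (waterborne vs dietary share): t = {imp['statistic']:.2f}, "
        f"p = {imp['p_value']:.2g}, significant = {imp['significant']}"
    )
    lines.append("")
    lines.append("## Growth comparisons")
    n_sig = sum(c["significant"] for c in report["comparisons"]["growth"])
    lines.append(
        f"{len(report['comparisons']['growth'])} ANOVAs run, {n_sig} significant "
        f"at alpha = 0.05."
    )
    lines.append("")
    return "\n".join(lines)


def save_plots(report: Mapping, out_dir) -> list:
    """Write new-accumulation-vs-time plots per tracer (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    records = report["new_accumulation"]
    tracers = sorted({r["tracer"] for r in records})
    for tracer in tracers:
        fig, ax = plt.subplots(figsize=(5, 4))
        sel = [r for r in records if r["tracer"] == tracer]
        for group in sorted({r["group"] for r in sel}):
            pts = sorted((r["day"], r["mean"], r["sd"]) for r in sel if r["group"] == group)
            days = [p[0] for p in pts]
            means = [p[1] for p in pts]
            sds = [p[2] for p in pts]
            ax.errorbar(days, means, yerr=sds, marker="o", capsize=3, label=group)
        ax.set_xlabel("exposure time (d)")
        ax.set_ylabel(f"new accumulation of {tracer} (ug/g dw)")
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"new_accumulation_{tracer}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
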