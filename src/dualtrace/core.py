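"""Domain types, configuration parsing and tidy-table I/O.

Units are fixed throughout the package and never auto-converted:
water concentrations in ug/L, tissue and algal concentrations in ug/g dry
weight, time in days, shell length in cm, dry weight in g.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataValidationError,
    MissingControlError,
    SchemaError,
)

__all__ = [
    "Route",
    "TracerSpec",
    "GroupSpec",
    "ExposureDesign",
    "MeasurementTable",
    "AnalysisConfig",
    "MEASUREMENT_COLUMNS",
    "WATERBORNE_COL",
    "DIETARY_COL",
    "read_measurements",
    "write_measurements",
    "load_config",
]


class Route(str, enum.Enum):
    """Exposure route an isotope tracer labels."""

    WATERBORNE = "waterborne"
    DIETARY = "dietary"


#: Column order of the measurements CSV (the package's main data interface).
MEASUREMENT_COLUMNS = (
    "group",
    "day",
    "tank",
    "mussel_id",
    "cd112_ugg_dw",
    "cd113_ugg_dw",
    "shell_length_cm",
    "dry_weight_g",
)

WATERBORNE_COL = "cd112_ugg_dw"
DIETARY_COL = "cd113_ugg_dw"

#: Tissue-concentration column for each exposure route.
ROUTE_COLUMNS: Mapping[Route, str] = {
    Route.WATERBORNE: WATERBORNE_COL,
    Route.DIETARY: DIETARY_COL,
}


@dataclass(frozen=True)
class TracerSpec:
    """Constants for one stable-isotope tracer.

    Parameters
    ----------
    label
        Isotope name, e.g. ``"Cd112"``.
    route
        Which exposure route this tracer labels.
    natural_abundance
        Fraction of the element naturally occurring as this isotope, in (0, 1).
    spike_purity
        Isotopic enrichment of the purchased spike, in (0, 1].
    """

    label: str
    route: Route
    natural_abundance: float
    spike_purity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if not 0.0 < self.natural_abundance < 1.0:
            raise ConfigurationError(
                f"natural_abundance must be in (0, 1), got {self.natural_abundance}"
            )
        if not 0.0 < self.spike_purity <= 1.0:
            raise ConfigurationError(
                f"spike_purity must be in (0, 1], got {self.spike_purity}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """One exposure group: name plus nominal exposure levels."""

    name: str
    waterborne_conc: float  # ug/L in water
    dietary_conc: float  # ug/g dw in the food algae

    def __post_init__(self) -> None:
        if self.waterborne_conc < 0 or self.dietary_conc < 0:
            raise ConfigurationError(
                f"group {self.name!r}: exposure concentrations must be >= 0"
            )


@dataclass(frozen=True)
class ExposureDesign:
    """Replication structure and schedule of the exposure experiment."""

    groups: tuple[GroupSpec, ...]
    tanks_per_group: int
    mussels_per_tank: int
    sampled_per_group_time: int
    sample_days: tuple[int, ...]
    feeding_hours_per_day: float
    day_hours: float = 24.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "groups",
            tuple(g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups),
        )
        object.__setattr__(self, "sample_days", tuple(int(d) for d in self.sample_days))
        days = self.sample_days
        if not days or any(d <= 0 for d in days) or list(days) != sorted(set(days)):
            raise ConfigurationError(
                f"sample_days must be strictly increasing and positive, got {days}"
            )
        if not 0.0 < self.feeding_hours_per_day <= self.day_hours:
            raise ConfigurationError(
                "feeding_hours_per_day must satisfy 0 < feeding <= day_hours, "
                f"got {self.feeding_hours_per_day} vs {self.day_hours}"
            )
        if min(self.tanks_per_group, self.mussels_per_tank, self.sampled_per_group_time) < 1:
            raise ConfigurationError("replication counts must be >= 1")
        controls = [g for g in self.groups if g.waterborne_conc == 0.0]
        if len(controls) != 1:
            raise ConfigurationError(
                "design must have exactly one control group (waterborne_conc == 0), "
                f"found {len(controls)}"
            )

    @property
    def control_group(self) -> str:
        """Name of the (unique) control group."""
        return next(g.name for g in self.groups if g.waterborne_conc == 0.0)

    @property
    def treatment_groups(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups if g.name != self.control_group)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)


class MeasurementTable:
    """Validated per-mussel tissue tracer concentrations.

    Thin wrapper around a tidy :class:`pandas.DataFrame` with the columns of
    :data:`MEASUREMENT_COLUMNS`, bound to the :class:`ExposureDesign` it was
    collected (or simulated) under.
    """

    def __init__(self, data: pd.DataFrame, design: ExposureDesign):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"measurement table is missing columns: {missing}")
        df = data.loc[:, list(MEASUREMENT_COLUMNS)].reset_index(drop=True)
        df["group"] = df["group"].astype(str)
        df["mussel_id"] = df["mussel_id"].astype(str)
        df["tank"] = df["tank"].astype(str)
        try:
            df["day"] = df["day"].astype(int)
            for col in MEASUREMENT_COLUMNS[4:]:
                df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value in a numeric column: {exc}") from exc
        self._validate(df, design)
        self.data = df
        self.design = design

    @staticmethod
    def _validate(df: pd.DataFrame, design: ExposureDesign) -> None:
        known_groups = set(design.group_names)
        known_days = set(design.sample_days)
        for idx, row in enumerate(df.itertuples(index=False)):
            if row.group not in known_groups:
                raise DataValidationError(
                    f"row {idx}: unknown group {row.group!r} (design groups: {sorted(known_groups)})"
                )
            if row.day not in known_days:
                raise DataValidationError(
                    f"row {idx}: day {row.day} not in sampling schedule {sorted(known_days)}"
                )
        for col in (WATERBORNE_COL, DIETARY_COL, "shell_length_cm", "dry_weight_g"):
            bad = df.index[(df[col] < 0) | df[col].isna()]
            if len(bad):
                raise DataValidationError(
                    f"row {bad[0]}: column {col!r} is negative or missing"
                )
        dup = df.duplicated(subset=["group", "day", "mussel_id"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise DataValidationError(
                "duplicate (group, day, mussel_id) = "
                f"({first['group']}, {first['day']}, {first['mussel_id']})"
            )

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self.design == other.design and self.data.equals(other.data)

    def control_rows(self) -> pd.DataFrame:
        rows = self.data[self.data["group"] == self.design.control_group]
        if rows.empty:
            raise MissingControlError(
                f"no rows for control group {self.design.control_group!r}"
            )
        return rows

    def group_day(self, group: str, day: int) -> pd.DataFrame:
        return self.data[(self.data["group"] == group) & (self.data["day"] == day)]


@dataclass(frozen=True)
class AnalysisConfig:
    """Full description of one dual-tracer analysis.

    ``tracers`` must contain exactly one waterborne and one dietary tracer.
    """

    tracers: tuple[TracerSpec, ...]
    design: ExposureDesign
    regression_through_origin: bool = False
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    qc_tolerance: float = 0.10

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "tracers",
            tuple(t if isinstance(t, TracerSpec) else TracerSpec(**t) for t in self.tracers),
        )
        routes = sorted(t.route.value for t in self.tracers)
        if routes != ["dietary", "waterborne"]:
            raise ConfigurationError(
                "config needs exactly one waterborne and one dietary tracer, "
                f"got routes {routes}"
            )
        if self.bootstrap_reps < 0:
            raise ConfigurationError("bootstrap_reps must be >= 0")
        if not 0.0 < self.qc_tolerance < 1.0:
            raise ConfigurationError("qc_tolerance must be in (0, 1)")

    def tracer(self, route: Route | str) -> TracerSpec:
        """The tracer labelling the given exposure route."""
        route = Route(route)
        return next(t for t in self.tracers if t.route == route)

    @property
    def dietary_scaling_factor(self) -> float:
        """day_hours / feeding_hours: daily-equivalent factor for dietary measurements."""
        return self.design.day_hours / self.design.feeding_hours_per_day


def read_measurements(path: str | Path, design: ExposureDesign) -> MeasurementTable:
    """Read and validate a measurements CSV.

    Raises :class:`SchemaError` for a malformed header and
    :class:`DataValidationError` for rows violating the design invariants.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"group": str, "tank": str, "mussel_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return MeasurementTable(df, design)


def write_measurements(table: MeasurementTable, path: str | Path) -> Path:
    """Write a measurements CSV that round-trips losslessly through
    :func:`read_measurements` (floats serialized with full repr precision)."""
    path = Path(path)
    # shortest round-trip representation: read(write(t)) is bit-exact
    table.data.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def config_from_dict(raw: Mapping) -> AnalysisConfig:
    try:
        design = ExposureDesign(
            groups=tuple(GroupSpec(**g) for g in raw["design"]["groups"]),
            **{k: v for k, v in raw["design"].items() if k != "groups"},
        )
        tracers = tuple(TracerSpec(**t) for t in raw["tracers"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed config: {exc}") from exc
    extra = {
        k: raw[k]
        for k in ("regression_through_origin", "bootstrap_reps", "rng_seed", "qc_tolerance")
        if k in raw
    }
    return AnalysisConfig(tracers=tracers, design=design, **extra)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: config file must be a YAML mapping")
    return config_from_dict(raw)


def config_to_dict(config: AnalysisConfig) -> dict:
    """JSON/YAML-serializable representation of a config (inverse of
    :func:`config_from_dict`)."""
    d = dataclasses.asdict(config)
    for t in d["tracers"]:
        t["route"] = t["route"].value if isinstance(t["route"], Route) else t["route"]
    d["tracers"] = list(d["tracers"])
    d["design"]["groups"] = list(d["design"]["groups"])
    d["design"]["sample_days"] = list(d["design"]["sample_days"])
    return d


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return path
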