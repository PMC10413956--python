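"""Domain types and fix-table CSV input/output.

A *fix* is one recorded animal location at a known minute of a focal
observation.  An *observation* is a single 30-minute focal follow sampled at
1-minute intervals (at most 31 fixes, minute indices 0..30), together with
the animal's covariates (species, sex, snout--vent length, mass).  A
*dataset* is a collection of observations, one per individual animal.

The on-disk format is a single denormalized CSV: one row per fix, with the
observation-level covariates repeated on every row so that partial files
remain self-describing.  Columns::

    observation_id, lizard_id, species, sex, svl_mm, mass_g, t_min,
    x_m, y_m, habitat, plant_species, visible_from_previous,
    air_temp_c, wind_speed_ms

Coordinates are planar meters in an arbitrary local frame.  Absent values
(missing weather, visibility flag at the first fix, plant species in the
open) are written as empty fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "Fix",
    "Observation",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "FIX_COLUMNS",
    "read_fixes_csv",
    "write_fixes_csv",
    "validate_observation",
    "validate_dataset",
]

FIX_COLUMNS = [
    "observation_id",
    "lizard_id",
    "species",
    "sex",
    "svl_mm",
    "mass_g",
    "t_min",
    "x_m",
    "y_m",
    "habitat",
    "plant_species",
    "visible_from_previous",
    "air_temp_c",
    "wind_speed_ms",
]

HABITAT_OPEN = "open"
HABITAT_VEGETATION = "vegetation"

MAX_FIXES = 31  # a full 30-min observation: minutes 0..30 inclusive


class SchemaError(ValueError):
    """The CSV file does not have the documented columns."""


class ValidationError(ValueError):
    """The data violate a structural invariant (named in the message)."""


@dataclass
class Fix:
    """One marker location at minute ``t`` of an observation."""

    t: int
    x: float
    y: float
    habitat: str = HABITAT_OPEN
    plant_species: Optional[str] = None
    visible_from_previous: Optional[bool] = None
    air_temp_c: Optional[float] = None
    wind_speed_ms: Optional[float] = None


@dataclass
class Observation:
    """A focal follow of one individual: ordered fixes plus covariates."""

    observation_id: str
    lizard_id: str
    species: str
    sex: str = "unknown"
    svl_mm: Optional[float] = None
    mass_g: Optional[float] = None
    fixes: list[Fix] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        """True when the follow lasted the full 30 min (31 fixes)."""
        return len(self.fixes) == MAX_FIXES


@dataclass
class Dataset:
    observations: list[Observation] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def species_labels(self) -> list[str]:
        seen: list[str] = []
        for obs in self.observations:
            if obs.species not in seen:
                seen.append(obs.species)
        return seen

    def by_species(self, species: str) -> list[Observation]:
        return [o for o in self.observations if o.species == species]


def _is_absent(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value == ""


def validate_observation(obs: Observation) -> list[str]:
    """Check every structural invariant of one observation.

    Returns a list of human-readable violations (empty when valid); never
    raises, so it can be applied to arbitrarily malformed records.
    """
    v: list[str] = []
    n = len(obs.fixes)
    if n < 2:
        v.append(f"{obs.observation_id}: needs >= 2 fixes, has {n}")
    if n > MAX_FIXES:
        v.append(f"{obs.observation_id}: {n} fixes exceeds maximum {MAX_FIXES}")
    prev_t = None
    for i, fx in enumerate(obs.fixes):
        if not isinstance(fx.t, int) or isinstance(fx.t, bool):
            v.append(f"{obs.observation_id}: fix {i} minute index not an integer")
            continue
        if fx.t < 0 or fx.t > 30:
            v.append(f"{obs.observation_id}: fix {i} minute {fx.t} outside 0..30")
        if prev_t is not None and fx.t <= prev_t:
            v.append(
                f"{obs.observation_id}: fix {i} minute {fx.t} not greater "
                f"than previous minute {prev_t}"
            )
        prev_t = fx.t if isinstance(fx.t, int) else prev_t
        in_veg = fx.habitat == HABITAT_VEGETATION
        has_plant = not _is_absent(fx.plant_species)
        if in_veg and not has_plant:
            v.append(f"{obs.observation_id}: fix {i} in vegetation without plant_species")
        if has_plant and not in_veg:
            v.append(f"{obs.observation_id}: fix {i} has plant_species but habitat=open")
        if fx.habitat not in (HABITAT_OPEN, HABITAT_VEGETATION):
            v.append(f"{obs.observation_id}: fix {i} habitat {fx.habitat!r} unknown")
        if i == 0 and fx.visible_from_previous is not None:
            v.append(f"{obs.observation_id}: fix 0 carries a visibility flag")
    return v


def validate_dataset(ds: Dataset) -> list[str]:
    """Observation invariants plus dataset-level uniqueness rules."""
    v: list[str] = []
    seen_obs: set[str] = set()
    seen_lizard: set[str] = set()
    for obs in ds.observations:
        if obs.observation_id in seen_obs:
            v.append(f"duplicate observation_id {obs.observation_id}")
        seen_obs.add(obs.observation_id)
        # one observation per individual animal
        if obs.lizard_id in seen_lizard:
            v.append(f"lizard_id {obs.lizard_id} appears in more than one observation")
        seen_lizard.add(obs.lizard_id)
        v.extend(validate_observation(obs))
    return v


def _parse_bool(value) -> Optional[bool]:
    if _is_absent(value):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean field value {value!r}")


def _parse_float(value) -> Optional[float]:
    if _is_absent(value):
        return None
    return float(value)


def read_fixes_csv(path) -> Dataset:
    """Read a fix-table CSV into a validated :class:`Dataset`.

    Rows are grouped by ``observation_id`` (first-appearance order); rows
    within an observation must already be ordered by ``t_min`` — an
    out-of-order minute index is a data defect, not something to repair
    silently, and raises :class:`ValidationError` naming the observation.
    A missing column raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, dtype={"observation_id": str, "lizard_id": str},
                     float_precision="round_trip")
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    observations: list[Observation] = []
    for obs_id, grp in df.groupby("observation_id", sort=False):
        first = grp.iloc[0]
        fixes = [
            Fix(
                t=int(row.t_min),
                x=float(row.x_m),
                y=float(row.y_m),
                habitat=str(row.habitat),
                plant_species=None if _is_absent(row.plant_species) else str(row.plant_species),
                visible_from_previous=_parse_bool(row.visible_from_previous),
                air_temp_c=_parse_float(row.air_temp_c),
                wind_speed_ms=_parse_float(row.wind_speed_ms),
            )
            for row in grp.itertuples()
        ]
        observations.append(
            Observation(
                observation_id=str(obs_id),
                lizard_id=str(first["lizard_id"]),
                species=str(first["species"]),
                sex="unknown" if _is_absent(first["sex"]) else str(first["sex"]),
                svl_mm=_parse_float(first["svl_mm"]),
                mass_g=_parse_float(first["mass_g"]),
                fixes=fixes,
            )
        )
    ds = Dataset(observations=observations, provenance={"source": str(path)})
    problems = validate_dataset(ds)
    if problems:
        raise ValidationError("; ".join(problems))
    return ds


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_fixes_csv(dataset: Dataset, path) -> None:
    """Write the dataset in the documented column order.

    Floats are written with ``repr`` so the write→read round trip is exact
    and two writes of the same dataset are byte-identical.
    """
    rows: Iterable[str] = (
        ",".join(
            [
                obs.observation_id,
                obs.lizard_id,
                obs.species,
                obs.sex,
                _fmt(obs.svl_mm),
                _fmt(obs.mass_g),
                str(fx.t),
                _fmt(fx.x),
                _fmt(fx.y),
                fx.habitat,
                _fmt(fx.plant_species),
                _fmt(fx.visible_from_previous),
                _fmt(fx.air_temp_c),
                _fmt(fx.wind_speed_ms),
            ]
        )
        for obs in dataset.observations
        for fx in obs.fixes
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(FIX_COLUMNS) + "\n")
        for line in rows:
            fh.write(line + "\n")
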