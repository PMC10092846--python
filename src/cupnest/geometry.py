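"""Nest-volume geometry.

An open cup nest is approximated as half a spheroid.  From up to four
diameter measurements and two height measurements of the whole nest
(``D1..D4``, ``H1..H2``) and of the inner cup (``d1..d4``, ``h1..h2``),
three volumes are derived:

* full volume   — half-spheroid on the mean outer diameter and height,
* inner volume  — half-spheroid on the mean inner diameter and height,
* outer volume  — full minus inner, i.e. the shell of nest material.

All lengths are centimetres and all volumes cubic centimetres.  Records
reported in millimetres must be converted by the reader before they reach
these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .errors import (
    AmbiguousDimensionError,
    InconsistentDimensionsError,
    InvalidDimensionError,
)

__all__ = [
    "NestDimensions",
    "NestVolumes",
    "MeasurementRecord",
    "half_spheroid_volume",
    "nest_volumes",
    "interpret_dimension_tuple",
    "read_measurements",
    "write_measurements",
    "add_volume_columns",
]

#: inner volume may exceed full volume by this relative fraction before the
#: record is rejected; smaller violations are clamped to equality
#: (digitisation noise in literature records).
INNER_EXCESS_TOLERANCE = 0.005


def _mean(values: Sequence[float] | None) -> Optional[float]:
    vals = [v for v in (values or []) if v is not None]
    if not vals:
        return None
    return sum(vals) / len(vals)


def _check_positive(values: Iterable[float] | None, label: str) -> None:
    for v in values or []:
        if v is None:
            continue
        if not math.isfinite(v) or v <= 0:
            raise InvalidDimensionError(f"{label} must be positive, got {v!r}")


@dataclass
class NestDimensions:
    """Raw linear measurements of one nest (cm).

    Replicate counts below the nominal four diameters / two heights are
    accepted; means are taken over whatever replicates are present.
    """

    outer_diameters: list[float] = field(default_factory=list)
    outer_heights: list[float] = field(default_factory=list)
    inner_diameters: list[float] = field(default_factory=list)
    inner_heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_positive(self.outer_diameters, "outer diameter")
        _check_positive(self.outer_heights, "outer height")
        _check_positive(self.inner_diameters, "inner diameter")
        _check_positive(self.inner_heights, "inner height")
        if len(self.outer_diameters) > 4 or len(self.inner_diameters) > 4:
            raise InvalidDimensionError("at most 4 diameter replicates")
        if len(self.outer_heights) > 2 or len(self.inner_heights) > 2:
            raise InvalidDimensionError("at most 2 height replicates")

    @property
    def mean_outer_diameter(self) -> Optional[float]:
        return _mean(self.outer_diameters)

    @property
    def mean_outer_height(self) -> Optional[float]:
        return _mean(self.outer_heights)

    @property
    def mean_inner_diameter(self) -> Optional[float]:
        return _mean(self.inner_diameters)

    @property
    def mean_inner_height(self) -> Optional[float]:
        return _mean(self.inner_heights)

    @property
    def has_outer_pair(self) -> bool:
        return self.mean_outer_diameter is not None and self.mean_outer_height is not None

    @property
    def has_inner_pair(self) -> bool:
        return self.mean_inner_diameter is not None and self.mean_inner_height is not None

    @property
    def rim_thickness(self) -> Optional[float]:
        """Half the difference of mean outer and inner diameters (cm)."""
        D, d = self.mean_outer_diameter, self.mean_inner_diameter
        if D is None or d is None:
            return None
        return (D - d) / 2.0

    def merge(self, other: "NestDimensions") -> "NestDimensions":
        """Combine two partial dimension fragments (used by tuple interpretation)."""
        return NestDimensions(
            outer_diameters=self.outer_diameters + other.outer_diameters,
            outer_heights=self.outer_heights + other.outer_heights,
            inner_diameters=self.inner_diameters + other.inner_diameters,
            inner_heights=self.inner_heights + other.inner_heights,
        )


@dataclass(frozen=True)
class NestVolumes:
    """Derived volumes (cm^3); components are ``None`` when not measurable."""

    full_volume: Optional[float]
    inner_volume: Optional[float]
    outer_volume: Optional[float]


@dataclass
class MeasurementRecord:
    """One population/site record of raw nest dimensions with its provenance."""

    species_id: str
    source: Literal["museum", "literature"]
    dimensions: NestDimensions
    site_label: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise InvalidDimensionError("species_id must be non-empty")
        if self.source not in ("museum", "literature"):
            raise InvalidDimensionError(
                f"source must be 'museum' or 'literature', got {self.source!r}"
            )


def half_spheroid_volume(mean_diameter: float, mean_height: float) -> float:
    """Volume of half a spheroid with circular cross-section ``mean_diameter``
    and depth ``mean_height``:  (2/3)*pi*(D/2)^2*H.

    Note the asymmetry: the diameter enters squared, the height linearly.
    """
    if mean_diameter < 0 or mean_height < 0:
        raise InvalidDimensionError(
            f"dimensions must be non-negative, got ({mean_diameter}, {mean_height})"
        )
    return (2.0 / 3.0) * math.pi * (mean_diameter / 2.0) ** 2 * mean_height


def nest_volumes(dims: NestDimensions) -> NestVolumes:
    """Full, inner and outer volumes from mean dimensions.

    The outer volume is the full half-spheroid minus the inner cup.  Records
    with only the inner pair (incomplete or cavity-constrained specimens)
    yield an inner volume only; records with only the outer pair yield a
    full volume only.  An inner volume exceeding the full volume by more
    than ``INNER_EXCESS_TOLERANCE`` raises; smaller excesses are clamped.
    """
    if not dims.has_inner_pair and not dims.has_outer_pair:
        raise InvalidDimensionError(
            "need at least the inner (d,h) or outer (D,H) diameter/height pair"
        )
    full = inner = outer = None
    if dims.has_outer_pair:
        full = half_spheroid_volume(dims.mean_outer_diameter, dims.mean_outer_height)
    if dims.has_inner_pair:
        inner = half_spheroid_volume(dims.mean_inner_diameter, dims.mean_inner_height)
    if full is not None and inner is not None:
        if inner > full:
            if inner <= full * (1.0 + INNER_EXCESS_TOLERANCE):
                inner = full
            else:
                raise InconsistentDimensionsError(
                    f"inner volume {inner:.3f} exceeds full volume {full:.3f} "
                    f"by more than {INNER_EXCESS_TOLERANCE:.1%}"
                )
        outer = full - inner
        # re-derive full from the rounded difference so the additivity
        # identity full == inner + outer holds bit-exactly
        full = inner + outer
    return NestVolumes(full_volume=full, inner_volume=inner, outer_volume=outer)


def interpret_dimension_tuple(
    values: Sequence[float],
    separator_style: Literal["by_or_x", "plain"] = "plain",
    qualifier: Literal["none", "internal", "external"] = "none",
    preceded_by_inner_diameter: bool = False,
) -> NestDimensions:
    """Interpret an already-tokenised literature dimension tuple.

    Conventions for handbook records:

    * no qualifier means the values refer to the external portion of the
      nest;
    * two values separated by "by"/"x" are nest length and width, i.e. two
      perpendicular diameters (slots D1 and D3); a third value is the nest
      height;
    * a single plain value is a depth measurement and is taken as external
      height — unless it directly follows a description of the inner cup
      diameter, in which case it is the inner cup height.

    Returns a partial :class:`NestDimensions` holding only the interpreted
    slots; merge fragments with :meth:`NestDimensions.merge`.
    """
    if len(values) == 0:
        raise AmbiguousDimensionError("empty dimension tuple")
    if len(values) > 3:
        raise AmbiguousDimensionError(
            f"cannot interpret a {len(values)}-value dimension tuple"
        )
    _check_positive(values, "literature dimension")
    inner = qualifier == "internal"

    if separator_style == "by_or_x":
        if len(values) == 1:
            raise AmbiguousDimensionError("'by'/'x' tuple needs at least two values")
        diams = list(values[:2])  # length and width -> D1, D3 slots
        height = [values[2]] if len(values) == 3 else []
        if inner:
            return NestDimensions(inner_diameters=diams, inner_heights=height)
        return NestDimensions(outer_diameters=diams, outer_heights=height)

    # plain single value: a depth/height figure
    if len(values) == 1:
        as_inner = inner or (qualifier == "none" and preceded_by_inner_diameter)
        if as_inner:
            return NestDimensions(inner_heights=[values[0]])
        return NestDimensions(outer_heights=[values[0]])

    # plain multi-value: replicate diameter measurements
    if inner:
        return NestDimensions(inner_diameters=list(values))
    return NestDimensions(outer_diameters=list(values))


# ---------------------------------------------------------------------------
# tabular I/O

_DEFAULT_COLUMNS = {
    "species": "species_id",
    "source": "source",
    "site": "site_label",
    "outer_diameters": ["D1", "D2", "D3", "D4"],
    "outer_heights": ["H1", "H2"],
    "inner_diameters": ["d1", "d2", "d3", "d4"],
    "inner_heights": ["h1", "h2"],
}


def _collect(row: pd.Series, cols: list[str]) -> list[float]:
    out = []
    for c in cols:
        if c in row.index and pd.notna(row[c]):
            out.append(float(row[c]))
    return out


def read_measurements(
    path, columns: dict | None = None, unit: Literal["cm", "mm"] = "cm", sep: str | None = None
) -> list[MeasurementRecord]:
    """Read a measurement table (CSV/TSV, one row per record).

    ``columns`` overrides the default column mapping; ``unit='mm'`` converts
    every length to cm at ingest.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    scale = 0.1 if unit == "mm" else 1.0
    records = []
    for _, row in df.iterrows():
        dims = NestDimensions(
            outer_diameters=[v * scale for v in _collect(row, cols["outer_diameters"])],
            outer_heights=[v * scale for v in _collect(row, cols["outer_heights"])],
            inner_diameters=[v * scale for v in _collect(row, cols["inner_diameters"])],
            inner_heights=[v * scale for v in _collect(row, cols["inner_heights"])],
        )
        records.append(
            MeasurementRecord(
                species_id=str(row[cols["species"]]),
                source=str(row[cols["source"]]),
                dimensions=dims,
                site_label=str(row[cols["site"]]) if cols["site"] in row.index else "",
            )
        )
    return records


def _record_row(rec: MeasurementRecord) -> dict:
    d = rec.dimensions
    row: dict = {"species_id": rec.species_id, "source": rec.source, "site_label": rec.site_label}
    for name, vals, width in [
        ("D", d.outer_diameters, 4),
        ("H", d.outer_heights, 2),
        ("d", d.inner_diameters, 4),
        ("h", d.inner_heights, 2),
    ]:
        for i in range(width):
            row[f"{name}{i + 1}"] = vals[i] if i < len(vals) else None
    return row


def write_measurements(records: Sequence[MeasurementRecord], path, sep: str = ",") -> None:
    pd.DataFrame([_record_row(r) for r in records]).to_csv(path, sep=sep, index=False)


def add_volume_columns(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Tabulate records with derived volume and rim-thickness columns appended."""
    rows = []
    for rec in records:
        row = _record_row(rec)
        vol = nest_volumes(rec.dimensions)
        row["full_volume"] = vol.full_volume
        row["inner_volume"] = vol.inner_volume
        row["outer_volume"] = vol.outer_volume
        row["rim_thickness"] = rec.dimensions.rim_thickness
        row["outer_diameter"] = rec.dimensions.mean_outer_diameter
        row["outer_height"] = rec.dimensions.mean_outer_height
        row["inner_diameter"] = rec.dimensions.mean_inner_diameter
        row["inner_height"] = rec.dimensions.mean_inner_height
        rows.append(row)
    return pd.DataFrame(rows)
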