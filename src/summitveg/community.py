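"""Survey record types, validation, and community-matrix construction.

The atomic record is one species' percent cover in one 1-m² quadrat in one
survey year. Absence is encoded by record absence: a cover of 0 is invalid.
Records aggregate into a sites × species :class:`CommunityMatrix` at quadrat,
aspect, or summit resolution, in cover or incidence mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    ParseError,
    ValidationError,
)

ASPECTS = ("N", "E", "S", "W")
SECTIONS = ("upper_5m", "lower_10m")
GROWTH_FORMS = ("shrub", "graminoid", "forb", "other")

#: Default representative percent cover for the five ordinal abundance
#: classes used in summit-area sections. The class bounds are a recording
#: convention, not a measurement; the midpoints below follow a Braun-Blanquet
#: style geometric progression and are user-configurable.
DEFAULT_ABUNDANCE_COVER: Mapping[int, float] = {1: 0.5, 2: 3.0, 3: 15.0, 4: 37.5, 5: 87.5}


@dataclass(frozen=True)
class QuadratObservation:
    """One species' percent cover in one corner quadrat in one survey year."""

    summit_id: str
    aspect: str
    quadrat_index: int
    year: int
    species_id: str
    cover: float

    def key(self) -> tuple:
        return (self.summit_id, self.aspect, self.quadrat_index, self.year, self.species_id)


@dataclass(frozen=True)
class SectionObservation:
    """One species' ordinal abundance class in one summit-area section."""

    summit_id: str
    aspect: str
    section: str
    year: int
    species_id: str
    abundance_class: int

    def key(self) -> tuple:
        return (self.summit_id, self.aspect, self.section, self.year, self.species_id)


@dataclass(frozen=True)
class SpeciesAttribute:
    """Per-species attributes: thermic elevational rank and growth form.

    ``elevational_rank`` follows the thermic-indicator convention: species
    with optima at lower (warmer) elevations carry *higher* ranks, so that a
    positive change of the cover-weighted mean rank indicates
    thermophilization.
    """

    species_id: str
    elevational_rank: int
    growth_form: str


@dataclass(frozen=True)
class Summit:
    """A monitored summit and its elevation in metres above sea level."""

    summit_id: str
    elevation: float


@dataclass
class CommunityMatrix:
    """Sites × species matrix with per-site metadata.

    ``values`` is a DataFrame indexed by site label with one column per
    species; ``sites`` is a metadata DataFrame on the same index carrying
    summit_id, aspect, optional quadrat_index, year and elevation.
    """

    values: pd.DataFrame
    sites: pd.DataFrame
    mode: str = "cover"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sites.index):
            raise ValidationError("values and sites must share the same index")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("site and species labels must be unique")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("matrix values must be finite")
        if (arr < 0).any():
            raise ValidationError("matrix values must be non-negative")
        if self.mode == "incidence" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValidationError("incidence matrices may contain only 0 and 1")

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def incidence(self) -> "CommunityMatrix":
        """Threshold cover at > 0 into a 0/1 incidence matrix."""
        if self.mode == "incidence":
            return self
        return CommunityMatrix((self.values > 0).astype(float), self.sites.copy(), "incidence")

    def to_frame(self) -> pd.DataFrame:
        """Export with site metadata columns first, then species columns."""
        return pd.concat([self.sites, self.values], axis=1)


# ---------------------------------------------------------------------------
# validation


def _check_aspect(aspect: str, where: str) -> None:
    if aspect not in ASPECTS:
        raise ValidationError(f"{where}: aspect {aspect!r} not one of {ASPECTS}")


def validate_observations(observations: Sequence[QuadratObservation]) -> None:
    """Check quadrat-record invariants; raise ValidationError on violation."""
    seen: set[tuple] = set()
    for i, ob in enumerate(observations):
        where = f"observation {i} ({ob.summit_id},{ob.aspect},q{ob.quadrat_index},{ob.year},{ob.species_id})"
        _check_aspect(ob.aspect, where)
        if not 1 <= int(ob.quadrat_index):
            raise ValidationError(f"{where}: quadrat_index must be >= 1")
        if not (0 < ob.cover <= 100):
            raise ValidationError(f"{where}: cover {ob.cover} outside (0, 100]")
        k = ob.key()
        if k in seen:
            raise ValidationError(f"{where}: duplicate record key")
        seen.add(k)


def validate_sections(observations: Sequence[SectionObservation]) -> None:
    seen: set[tuple] = set()
    for i, ob in enumerate(observations):
        where = f"section observation {i} ({ob.summit_id},{ob.aspect},{ob.section},{ob.year},{ob.species_id})"
        _check_aspect(ob.aspect, where)
        if ob.section not in SECTIONS:
            raise ValidationError(f"{where}: section must be one of {SECTIONS}")
        if ob.abundance_class not in (1, 2, 3, 4, 5):
            raise ValidationError(f"{where}: abundance_class {ob.abundance_class} outside 1..5")
        k = ob.key()
        if k in seen:
            raise ValidationError(f"{where}: duplicate record key")
        seen.add(k)


def validate_attributes(
    attributes: Sequence[SpeciesAttribute],
    observations: Sequence[QuadratObservation] | None = None,
) -> None:
    seen: set[str] = set()
    for attr in attributes:
        if attr.species_id in seen:
            raise ValidationError(f"species {attr.species_id!r} has more than one attribute row")
        if attr.elevational_rank < 1:
            raise ValidationError(f"species {attr.species_id!r}: elevational_rank must be >= 1")
        if attr.growth_form not in GROWTH_FORMS:
            raise ValidationError(
                f"species {attr.species_id!r}: growth_form {attr.growth_form!r} not one of {GROWTH_FORMS}"
            )
        seen.add(attr.species_id)
    if observations is not None:
        missing = sorted({ob.species_id for ob in observations} - seen)
        if missing:
            raise ValidationError(f"species without attribute rows: {missing}")


# ---------------------------------------------------------------------------
# delimited-text I/O

_QUADRAT_COLS = ["summit_id", "aspect", "quadrat_index", "year", "species_id", "cover"]
_SECTION_COLS = ["summit_id", "aspect", "section", "year", "species_id", "abundance_class"]


def read_observations(path, schema: Literal["quadrat", "section"] = "quadrat"):
    """Read and validate survey records from a comma-separated file.

    The header must name the schema's fields. Returns a list of
    :class:`QuadratObservation` or :class:`SectionObservation`.
    """
    cols = _QUADRAT_COLS if schema == "quadrat" else _SECTION_COLS
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            if schema == "quadrat":
                rec = QuadratObservation(
                    str(row.summit_id), str(row.aspect), int(row.quadrat_index),
                    int(row.year), str(row.species_id), float(row.cover),
                )
            else:
                rec = SectionObservation(
                    str(row.summit_id), str(row.aspect), str(row.section),
                    int(row.year), str(row.species_id), int(row.abundance_class),
                )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row {i + 2}: {exc}") from exc
        records.append(rec)
    if schema == "quadrat":
        validate_observations(records)
    else:
        validate_sections(records)
    return records


def write_observations(records, path) -> None:
    """Write validated records back to comma-separated text (round-trip safe)."""
    if records and isinstance(records[0], SectionObservation):
        cols = _SECTION_COLS
    else:
        cols = _QUADRAT_COLS
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_attributes(path) -> list[SpeciesAttribute]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("species_id", "elevational_rank", "growth_form") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    attrs = [
        SpeciesAttribute(str(r.species_id), int(r.elevational_rank), str(r.growth_form))
        for r in df.itertuples(index=False)
    ]
    validate_attributes(attrs)
    return attrs


def write_attributes(attributes: Sequence[SpeciesAttribute], path) -> None:
    pd.DataFrame(
        [(a.species_id, a.elevational_rank, a.growth_form) for a in attributes],
        columns=["species_id", "elevational_rank", "growth_form"],
    ).to_csv(path, index=False)


def read_summits(path) -> list[Summit]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("summit_id", "elevation") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    summits = [Summit(str(r.summit_id), float(r.elevation)) for r in df.itertuples(index=False)]
    elevations = [s.elevation for s in summits]
    if sorted(elevations) != elevations or len(set(elevations)) != len(elevations):
        raise ValidationError("summit elevations must be strictly increasing in listed order")
    return summits


def write_summits(summits: Sequence[Summit], path) -> None:
    pd.DataFrame(
        [(s.summit_id, s.elevation) for s in summits], columns=["summit_id", "elevation"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrix construction


def abundance_class_to_cover(abundance_class: int, mapping: Mapping[int, float] | None = None) -> float:
    """Map an ordinal abundance class (1-5) to a representative percent cover."""
    mapping = DEFAULT_ABUNDANCE_COVER if mapping is None else mapping
    if abundance_class not in (1, 2, 3, 4, 5):
        raise DomainError(f"abundance class {abundance_class} outside 1..5")
    vals = [mapping[k] for k in sorted(mapping)]
    if sorted(mapping) != [1, 2, 3, 4, 5] or any(x >= y for x, y in zip(vals, vals[1:])):
        raise DomainError("class-to-cover mapping must cover classes 1..5 and be strictly increasing")
    return float(mapping[abundance_class])


def _site_key(ob: QuadratObservation, grouping: str) -> tuple:
    if grouping == "quadrat":
        return (ob.summit_id, ob.aspect, ob.quadrat_index, ob.year)
    if grouping == "aspect":
        return (ob.summit_id, ob.aspect, ob.year)
    if grouping == "summit":
        return (ob.summit_id, ob.year)
    raise DomainError(f"unknown grouping {grouping!r}")


def _site_label(key: tuple, grouping: str) -> str:
    if grouping == "quadrat":
        return f"{key[0]}:{key[1]}:q{key[2]}:{key[3]}"
    if grouping == "aspect":
        return f"{key[0]}:{key[1]}:{key[2]}"
    return f"{key[0]}:{key[1]}"


def build_matrix(
    observations: Iterable[QuadratObservation],
    grouping: Literal["quadrat", "aspect", "summit"] = "quadrat",
    year_filter: int | None = None,
    mode: Literal["cover", "incidence"] = "cover",
    summits: Sequence[Summit] | None = None,
) -> CommunityMatrix:
    """Aggregate quadrat records into a sites × species community matrix.

    Aggregation to coarser groupings sums cover (aspect/summit covers may
    exceed 100); incidence is the logical OR. Species absent from every
    retained site are dropped. If a summit table is supplied, site metadata
    carries elevation.
    """
    obs = [ob for ob in observations if year_filter is None or ob.year == year_filter]
    if not obs:
        raise EmptyInputError("no observations retained" + (f" for year {year_filter}" if year_filter else ""))
    validate_observations(obs)

    rows = pd.DataFrame(
        {
            "key": [_site_key(ob, grouping) for ob in obs],
            "species_id": [ob.species_id for ob in obs],
            "cover": [ob.cover for ob in obs],
        }
    )
    table = rows.pivot_table(index="key", columns="species_id", values="cover", aggfunc="sum", fill_value=0.0)
    table = table.sort_index(axis=0).sort_index(axis=1)
    keys = list(table.index)
    labels = [_site_label(k, grouping) for k in keys]

    elev = {s.summit_id: s.elevation for s in (summits or [])}
    meta_rows = []
    for k in keys:
        meta = {"summit_id": k[0], "aspect": k[1] if grouping != "summit" else None,
                "quadrat_index": k[2] if grouping == "quadrat" else None,
                "year": k[-1], "elevation": elev.get(k[0], np.nan)}
        meta_rows.append(meta)
    sites = pd.DataFrame(meta_rows, index=labels)
    values = pd.DataFrame(table.to_numpy(dtype=float), index=labels, columns=table.columns)
    values = values.loc[:, values.sum(axis=0) > 0]
    if mode == "incidence":
        values = (values > 0).astype(float)
    return CommunityMatrix(values, sites, mode)
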