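"""Domain types and file I/O for the stand-reconstruction pipeline.

Tabular formats are plain UTF-8 CSV with a mandatory header row and "." as
the decimal mark.  Coordinates are planar meters throughout (local Cartesian
or UTM); the stand spans well under 100 m, so no geodesy is attempted.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd


class FormatError(ValueError):
    """A file does not have the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. duplicate id, dbh <= 0)."""


class StateError(RuntimeError):
    """An operation was called before its prerequisites were established."""


#: Genera treated as hosts of the beetle when the stem table does not carry
#: an explicit ``is_host`` column.  Covers the maple/birch/beech/ash/apple/
#: poplar/willow/elm group commonly listed as suitable for oviposition and
#: larval development.
HOST_GENERA = frozenset(
    {"Acer", "Betula", "Fagus", "Fraxinus", "Malus", "Populus", "Salix", "Ulmus"}
)


class InfestationLevel(enum.IntEnum):
    """Per-tree infestation severity; the integer order is the severity order.

    ``A`` = oviposition pits but no emergence (exit) holes, ``B`` = 1-10 exit
    holes, ``C`` = 11-100 exit holes.  ``NONE`` marks an un-infested tree.
    """

    NONE = 0
    A = 1
    B = 2
    C = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class DamageKind(str, enum.Enum):
    EXIT_HOLE = "exit_hole"
    OVIPOSITION_PIT = "oviposition_pit"


@dataclass
class WoodSectionRecord:
    """One cross-cut wood section through an exit hole or oviposition pit.

    ``rings_over`` is the number of growth rings formed over the damage.  An
    unhealed hole has no rings over it by definition; a healed (or partially
    healed) hole must show at least one ring, otherwise the evidence is
    contradictory.
    """

    damage_kind: DamageKind
    healed: bool
    rings_over: int = 0
    assigned_year: int | None = None

    def __post_init__(self) -> None:
        self.damage_kind = DamageKind(self.damage_kind)
        if self.rings_over < 0:
            raise ValidationError(f"rings_over must be >= 0, got {self.rings_over}")
        if not self.healed and self.rings_over != 0:
            raise ValidationError(
                "an unhealed section cannot have rings formed over the damage "
                f"(rings_over={self.rings_over})"
            )


@dataclass
class TreeRecord:
    """One surveyed stem.

    ``sections`` holds every dated (or datable) wood section from the tree:
    all exit holes, plus the subset of oviposition pits that were sampled for
    ring counting.  ``pit_count`` is the total pit count from the field
    survey, which may exceed the number of sampled pit sections.

    Coordinates may be unset (``None``) when the row carried a bearing and
    distance observation instead; ``survey`` then holds the raw
    ``(control_point_id, bearing_deg, distance_m)`` triple for the survey
    geometry stage to resolve.
    """

    tree_id: str
    genus: str
    species: str = ""
    dbh_cm: float = 0.0
    x_m: float | None = None
    y_m: float | None = None
    is_host: bool | None = None
    pit_count: int = 0
    sections: list[WoodSectionRecord] = field(default_factory=list)
    level: InfestationLevel | None = None
    survey: tuple[str, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.tree_id:
            raise ValidationError("tree_id must be a non-empty string")
        if not (self.dbh_cm > 0):
            raise ValidationError(
                f"tree {self.tree_id!r}: dbh_cm must be positive, got {self.dbh_cm}"
            )
        if self.pit_count < 0:
            raise ValidationError(f"tree {self.tree_id!r}: pit_count must be >= 0")
        if self.is_host is None:
            self.is_host = self.genus in HOST_GENERA
        for c in (self.x_m, self.y_m):
            if c is not None and not math.isfinite(c):
                raise ValidationError(f"tree {self.tree_id!r}: non-finite coordinate")

    @property
    def exit_holes(self) -> list[WoodSectionRecord]:
        return [s for s in self.sections if s.damage_kind is DamageKind.EXIT_HOLE]

    @property
    def pit_sections(self) -> list[WoodSectionRecord]:
        return [s for s in self.sections if s.damage_kind is DamageKind.OVIPOSITION_PIT]

    @property
    def exit_count(self) -> int:
        return len(self.exit_holes)

    @property
    def has_coords(self) -> bool:
        return self.x_m is not None and self.y_m is not None

    @property
    def coords(self) -> tuple[float, float]:
        if not self.has_coords:
            raise StateError(f"tree {self.tree_id!r} has unresolved coordinates")
        return (float(self.x_m), float(self.y_m))


@dataclass
class Stand:
    """A surveyed stand: the tree list plus stand-level metadata.

    ``felling_year`` is the calendar year the stand was felled; unhealed
    damage is dated to this year.  ``meta`` carries free-form provenance
    (e.g. the generator configuration for synthetic stands).
    """

    trees: list[TreeRecord]
    area_m2: float | None = None
    felling_year: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.trees:
            if t.tree_id in seen:
                raise ValidationError(f"duplicate tree_id {t.tree_id!r}")
            seen.add(t.tree_id)
        if self.area_m2 is not None and not (self.area_m2 > 0):
            raise ValidationError(f"area_m2 must be positive, got {self.area_m2}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[TreeRecord]:
        return iter(self.trees)

    def tree(self, tree_id: str) -> TreeRecord:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(tree_id)

    @property
    def ids(self) -> list[str]:
        return [t.tree_id for t in self.trees]

    def infested(self) -> list[TreeRecord]:
        """Trees with any sign of infestation (pits and/or exit holes)."""
        return [t for t in self.trees if t.pit_count > 0 or t.exit_count > 0]


@dataclass(frozen=True)
class WindDay:
    """Direction (degrees clockwise from north, [0, 360)) that the fastest
    5-second gust of the day blew *from*."""

    date: _date
    direction_deg: float

    def __post_init__(self) -> None:
        d = float(self.direction_deg) % 360.0
        object.__setattr__(self, "direction_deg", d)


@dataclass
class WindReadResult:
    """Wind table parse result: the usable records plus a skip report."""

    days: list[WindDay]
    skipped: int = 0
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self) -> Iterator[WindDay]:
        return iter(self.days)


# ---------------------------------------------------------------------------
# exit_hole_spec mini-format
#
# Semicolon-separated tokens, one per wood section:
#   u      unhealed exit hole
#   h<k>   healed / partially healed exit hole with k rings formed over it
#   pu     unhealed (current-season) oviposition pit section
#   ph<k>  healed oviposition pit section with k rings over it
# An empty cell means no sections were taken from the tree.
# ---------------------------------------------------------------------------


def parse_section_spec(spec: str) -> list[WoodSectionRecord]:
    """Parse an ``exit_hole_spec`` cell into wood-section records."""
    records: list[WoodSectionRecord] = []
    if spec is None or (isinstance(spec, float) and math.isnan(spec)):
        return records
    for raw in str(spec).split(";"):
        token = raw.strip().lower()
        if not token:
            continue
        kind = DamageKind.EXIT_HOLE
        if token.startswith("p"):
            kind = DamageKind.OVIPOSITION_PIT
            token = token[1:]
        if token == "u":
            records.append(WoodSectionRecord(kind, healed=False, rings_over=0))
        elif token.startswith("h") and token[1:].isdigit():
            records.append(WoodSectionRecord(kind, healed=True, rings_over=int(token[1:])))
        else:
            raise FormatError(f"unparseable section token {raw.strip()!r}")
    return records


def format_section_spec(sections: Iterable[WoodSectionRecord]) -> str:
    tokens = []
    for s in sections:
        prefix = "p" if s.damage_kind is DamageKind.OVIPOSITION_PIT else ""
        tokens.append(f"{prefix}h{s.rings_over}" if s.healed else f"{prefix}u")
    return ";".join(tokens)


# ---------------------------------------------------------------------------
# Stem table
# ---------------------------------------------------------------------------

_STEM_REQUIRED = ("tree_id", "genus", "dbh_cm")
_XY_COLS = ("x_m", "y_m")
_SURVEY_COLS = ("control_point", "bearing_deg", "distance_m")


def read_stem_table(
    path: str | Path,
    *,
    area_m2: float | None = None,
    felling_year: int | None = None,
) -> Stand:
    """Read a stem-survey CSV into a :class:`Stand`.

    Each row is one stem.  Required columns: ``tree_id``, ``genus``,
    ``dbh_cm``; location either as planar ``x_m``/``y_m`` or as a survey
    triple ``control_point``/``bearing_deg``/``distance_m`` (resolved later
    by :mod:`standspread.survey_geometry`).  Optional columns: ``species``,
    ``is_host``, ``pit_count``, ``exit_hole_spec``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"tree_id": str, "genus": str, "species": str})
    for col in _STEM_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"stem table {path.name} is missing required column {col!r}")
    have_xy = all(c in frame.columns for c in _XY_COLS)
    have_survey = all(c in frame.columns for c in _SURVEY_COLS)
    if not (have_xy or have_survey):
        raise FormatError(
            "stem table needs either x_m/y_m columns or "
            "control_point/bearing_deg/distance_m columns"
        )

    trees: list[TreeRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        tree_id = str(row["tree_id"]).strip()
        if tree_id in seen:
            raise ValidationError(f"duplicate tree_id {tree_id!r} in {path.name}")
        seen.add(tree_id)
        x = y = None
        survey = None
        if have_xy and pd.notna(row.get("x_m")) and pd.notna(row.get("y_m")):
            x, y = float(row["x_m"]), float(row["y_m"])
        elif have_survey and pd.notna(row.get("control_point")):
            survey = (
                str(row["control_point"]).strip(),
                float(row["bearing_deg"]),
                float(row["distance_m"]),
            )
        species = row.get("species", "")
        is_host = None
        if "is_host" in frame.columns and pd.notna(row.get("is_host")):
            is_host = bool(row["is_host"]) if not isinstance(row["is_host"], str) else (
                row["is_host"].strip().lower() in {"1", "true", "yes", "y"}
            )
        pit_count = 0
        if "pit_count" in frame.columns and pd.notna(row.get("pit_count")):
            pit_count = int(row["pit_count"])
        sections = []
        if "exit_hole_spec" in frame.columns:
            sections = parse_section_spec(row.get("exit_hole_spec"))
        trees.append(
            TreeRecord(
                tree_id=tree_id,
                genus=str(row["genus"]).strip(),
                species="" if pd.isna(species) else str(species).strip(),
                dbh_cm=float(row["dbh_cm"]),
                x_m=x,
                y_m=y,
                is_host=is_host,
                pit_count=pit_count,
                sections=sections,
                survey=survey,
            )
        )
    return Stand(trees=trees, area_m2=area_m2, felling_year=felling_year)


def write_stem_table(stand: Stand, path: str | Path) -> None:
    rows = []
    for t in stand:
        rows.append(
            {
                "tree_id": t.tree_id,
                "genus": t.genus,
                "species": t.species,
                "dbh_cm": t.dbh_cm,
                "x_m": t.x_m,
                "y_m": t.y_m,
                "is_host": t.is_host,
                "pit_count": t.pit_count,
                "exit_hole_spec": format_section_spec(t.sections),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Wind table
# ---------------------------------------------------------------------------


def read_wind_table(path: str | Path) -> WindReadResult:
    """Read a daily wind CSV (``date``, ``direction_deg``) into wind days.

    The layout matches a GHCND-style daily extract of the fastest-5-second
    gust direction: ISO-8601 date plus a direction in degrees.  Rows with a
    missing or unparseable direction or date are skipped (not fatal) and
    tallied in the result's skip report.  Directions are normalised into
    [0, 360); duplicate dates after the first are skipped.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("date", "direction_deg"):
        if col not in frame.columns:
            raise FormatError(f"wind table {path.name} is missing required column {col!r}")
    if frame.empty:
        warnings.warn(f"wind table {path.name} contains no rows", stacklevel=2)
        return WindReadResult(days=[])

    days: list[WindDay] = []
    errors: list[str] = []
    seen_dates: set[_date] = set()
    for i, row in frame.iterrows():
        raw_dir = row["direction_deg"]
        if pd.isna(raw_dir):
            errors.append(f"row {i}: missing direction")
            continue
        try:
            direction = float(raw_dir)
        except (TypeError, ValueError):
            errors.append(f"row {i}: unparseable direction {raw_dir!r}")
            continue
        try:
            when = pd.Timestamp(row["date"]).date()
        except (TypeError, ValueError):
            errors.append(f"row {i}: unparseable date {row['date']!r}")
            continue
        if when in seen_dates:
            errors.append(f"row {i}: duplicate date {when.isoformat()}")
            continue
        seen_dates.add(when)
        days.append(WindDay(date=when, direction_deg=direction))
    return WindReadResult(days=days, skipped=len(errors), errors=errors)


def write_wind_table(days: Sequence[WindDay], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in days],
            "direction_deg": [d.direction_deg for d in days],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

_QUANTILE_NOTE = "quantile convention: IQR = Q3 - Q1, linear-interpolation quantiles"


def write_results(
    stand: Stand | None,
    graph,
    rose,
    comparison,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the report bundle: edge CSV, wind-rose CSV, GeoJSON, summary.

    Any of ``graph``, ``rose`` and ``comparison`` may be ``None``; the
    corresponding file is then omitted.  Returns a name -> path mapping of
    the files written.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}

    if graph is not None:
        edge_path = outdir / "edges.csv"
        rows = [
            {
                "source_id": e.source_id,
                "target_id": e.target_id,
                "distance_m": round(e.distance_m, 6),
                "bearing_deg": round(e.bearing_deg, 6),
            }
            for e in graph.edges
        ]
        pd.DataFrame(
            rows, columns=["source_id", "target_id", "distance_m", "bearing_deg"]
        ).to_csv(edge_path, index=False)
        written["edges"] = edge_path

    if rose is not None:
        rose_path = outdir / "wind_rose.csv"
        rose.to_frame().to_csv(rose_path, index=False)
        written["wind_rose"] = rose_path

    if comparison is not None:
        comp_path = outdir / "comparison.json"
        comp_path.write_text(json.dumps(comparison.to_dict(), indent=2) + "\n")
        written["comparison"] = comp_path

    if stand is not None:
        written["geojson"] = _write_geojson(stand, graph, outdir / "features.geojson")

    summary_path = outdir / "summary.txt"
    summary_path.write_text(_summary_text(stand, graph, rose, comparison))
    written["summary"] = summary_path
    return written


def _write_geojson(stand: Stand, graph, path: Path) -> Path:
    features = []
    for t in stand:
        if not t.has_coords:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [t.x_m, t.y_m]},
                "properties": {
                    "tree_id": t.tree_id,
                    "genus": t.genus,
                    "species": t.species,
                    "dbh_cm": t.dbh_cm,
                    "is_host": t.is_host,
                    "pit_count": t.pit_count,
                    "exit_count": t.exit_count,
                    "level": t.level.name if t.level is not None else None,
                },
            }
        )
    if graph is not None:
        for e in graph.edges:
            a = stand.tree(e.source_id)
            b = stand.tree(e.target_id)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[a.x_m, a.y_m], [b.x_m, b.y_m]],
                    },
                    "properties": {
                        "source_id": e.source_id,
                        "target_id": e.target_id,
                        "distance_m": e.distance_m,
                        "bearing_deg": e.bearing_deg,
                    },
                }
            )
    payload = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def _summary_text(stand, graph, rose, comparison) -> str:
    lines = ["stand reconstruction summary", "=" * 28, _QUANTILE_NOTE, ""]
    if stand is not None:
        lines.append(f"trees surveyed: {len(stand)}")
        if stand.area_m2:
            lines.append(f"stand area: {stand.area_m2:.0f} m^2")
        if stand.felling_year:
            lines.append(f"felling year: {stand.felling_year}")
        infested = stand.infested()
        lines.append(f"infested trees: {len(infested)}")
    if graph is not None:
        lines.append(f"dispersal edges: {len(graph.edges)} (root: {graph.root_id})")
    if comparison is not None:
        lines.append(
            "distance comparison: "
            f"KS D = {comparison.ks.statistic_value:.4f}, "
            f"median inferred {comparison.median_inferred:.2f} m "
            f"(IQR {comparison.iqr_inferred:.2f}), "
            f"median potential {comparison.median_potential:.2f} m "
            f"(IQR {comparison.iqr_potential:.2f})"
        )
    if rose is not None:
        lines.append(f"wind records binned: {int(rose.total)}")
    return "\n".join(lines) + "\n"


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Re-read an edge CSV written by :func:`write_results`."""
    frame = pd.read_csv(path, dtype={"source_id": str, "target_id": str})
    for col in ("source_id", "target_id", "distance_m", "bearing_deg"):
        if col not in frame.columns:
            raise FormatError(f"edge table is missing required column {col!r}")
    return frame


def read_wind_rose_table(path: str | Path) -> pd.DataFrame:
    """Re-read a wind-rose CSV written by :func:`write_results`."""
    frame = pd.read_csv(path)
    for col in ("source", "frequency"):
        if col not in frame.columns:
            raise FormatError(f"wind-rose table is missing required column {col!r}")
    return frame
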