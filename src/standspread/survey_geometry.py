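"""Bearing/distance survey resolution and stand geometry.

A stem map is built the way a transit survey records it: one primary control
point (the local origin), a handful of sub-control points shot from the
primary, and every stem shot from one of those points as a bearing (degrees
clockwise from grid north, 0.1 degree resolution) and a taped distance
(0.1 m resolution).  Bearings are grid bearings; any constant magnetic
declination cancels in the relative geometry of a single small survey.
Distances are two-dimensional; elevation is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from standspread.core_io import FormatError, Stand, StateError, ValidationError


@dataclass(frozen=True)
class SurveyObservation:
    """One transit shot: bearing and distance from a control point to a stem."""

    target_id: str
    control_point_id: str
    bearing_deg: float
    distance_m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.bearing_deg < 360.0):
            raise ValidationError(
                f"bearing must be in [0, 360), got {self.bearing_deg}"
            )
        if self.distance_m < 0:
            raise ValidationError(f"distance must be >= 0, got {self.distance_m}")


@dataclass(frozen=True)
class ControlPoint:
    """A survey control point, expressed as an offset from the primary."""

    id: str
    east_m: float = 0.0
    north_m: float = 0.0
    primary: bool = False

    def __post_init__(self) -> None:
        if self.primary and (self.east_m, self.north_m) != (0.0, 0.0):
            raise ValidationError("the primary control point must sit at (0, 0)")
        if not (math.isfinite(self.east_m) and math.isfinite(self.north_m)):
            raise ValidationError(f"control point {self.id!r}: non-finite offset")


@dataclass(frozen=True)
class UtmAnchor:
    """UTM coordinate of the primary control point; local coordinates are
    translated (not reprojected) onto it."""

    easting_m: float
    northing_m: float
    zone: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.easting_m) and math.isfinite(self.northing_m)):
            raise ValidationError("UTM anchor must be finite")


def polar_to_local(
    obs: SurveyObservation, cp: ControlPoint
) -> tuple[float, float]:
    """Convert a bearing/distance shot into (east, north) meters.

    Bearings are measured clockwise from grid north, so
    east = E_cp + d sin(b), north = N_cp + d cos(b).
    """
    if cp.id != obs.control_point_id:
        raise LookupError(
            f"observation of {obs.target_id!r} references control point "
            f"{obs.control_point_id!r}, got {cp.id!r}"
        )
    b = math.radians(obs.bearing_deg)
    east = cp.east_m + obs.distance_m * math.sin(b)
    north = cp.north_m + obs.distance_m * math.cos(b)
    return (east, north)


def local_to_utm(
    local: tuple[float, float], anchor: UtmAnchor
) -> tuple[float, float]:
    """Translate local (east, north) meters onto the UTM anchor."""
    east, north = local
    return (anchor.easting_m + east, anchor.northing_m + north)


def read_control_points(path: str | Path) -> dict[str, ControlPoint]:
    """Read a control-point CSV (id, from_id, bearing_deg, distance_m,
    is_primary) and resolve the network from the primary outward.

    Sub-control points are themselves positioned by :func:`polar_to_local`
    from an already-resolved point, mirroring a two-stage transit survey.
    """
    frame = pd.read_csv(path, dtype={"id": str, "from_id": str})
    for col in ("id", "from_id", "bearing_deg", "distance_m", "is_primary"):
        if col not in frame.columns:
            raise FormatError(f"control-point table is missing column {col!r}")
    rows = frame.to_dict("records")
    primaries = [r for r in rows if bool(r["is_primary"])]
    if len(primaries) != 1:
        raise ValidationError(
            f"exactly one primary control point required, found {len(primaries)}"
        )
    resolved: dict[str, ControlPoint] = {
        str(primaries[0]["id"]): ControlPoint(str(primaries[0]["id"]), 0.0, 0.0, True)
    }
    pending = [r for r in rows if not bool(r["is_primary"])]
    while pending:
        progressed = False
        remaining = []
        for r in pending:
            from_id = str(r["from_id"])
            if from_id in resolved:
                obs = SurveyObservation(
                    target_id=str(r["id"]),
                    control_point_id=from_id,
                    bearing_deg=float(r["bearing_deg"]),
                    distance_m=float(r["distance_m"]),
                )
                east, north = polar_to_local(obs, resolved[from_id])
                resolved[str(r["id"])] = ControlPoint(str(r["id"]), east, north)
                progressed = True
            else:
                remaining.append(r)
        if not progressed:
            unknown = sorted(str(r["id"]) for r in remaining)
            raise LookupError(
                f"control points {unknown} reference unresolved parents"
            )
        pending = remaining
    return resolved


def resolve_stand(stand: Stand, control_points: dict[str, ControlPoint]) -> Stand:
    """Fill planar coordinates for every tree carrying a survey triple.

    Mutates the stand in place and returns it.  An unknown control-point id
    raises a lookup error naming the tree.
    """
    for tree in stand:
        if tree.has_coords or tree.survey is None:
            continue
        cp_id, bearing, distance = tree.survey
        if cp_id not in control_points:
            raise LookupError(
                f"tree {tree.tree_id!r} references unknown control point {cp_id!r}"
            )
        obs = SurveyObservation(
            target_id=tree.tree_id,
            control_point_id=cp_id,
            bearing_deg=float(bearing) % 360.0,
            distance_m=float(distance),
        )
        tree.x_m, tree.y_m = polar_to_local(obs, control_points[cp_id])
    return stand


def coordinate_array(stand: Stand) -> np.ndarray:
    """(n, 2) array of tree coordinates, raising if any are unresolved."""
    coords = np.empty((len(stand), 2), dtype=float)
    for i, tree in enumerate(stand):
        if not tree.has_coords:
            raise StateError(
                f"tree {tree.tree_id!r} has unresolved coordinates; "
                "run survey resolution first"
            )
        coords[i] = (tree.x_m, tree.y_m)
    return coords


def pairwise_distances(stand: Stand) -> pd.DataFrame:
    """Symmetric Euclidean distance table over all tree pairs (zero
    diagonal), indexed by tree id."""
    coords = coordinate_array(stand)
    mat = squareform(pdist(coords)) if len(stand) > 1 else np.zeros((len(stand), len(stand)))
    ids = stand.ids
    return pd.DataFrame(mat, index=ids, columns=ids)
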