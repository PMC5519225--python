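"""Wind-rose analysis over sixteen 22.5-degree direction bins.

Daily fastest-gust *source* directions (where the wind blew from) are binned
into the sixteen compass sectors, anchored at 0 degrees: bin b covers
[22.5*b, 22.5*(b+1)).  A wind-borne disperser leaving a point source travels
*with* the wind, so the expected landing sector (the destination) of each
source bin is the opposite compass point — an 8-bin cyclic shift.  Bins are
ranked 1 (least frequent) to 16 (most frequent); equal frequencies are
broken by compass row order, N first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from standspread.core_io import ValidationError, WindDay

#: Compass sector labels in rose row order, N first, clockwise.
COMPASS_16 = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)

BIN_WIDTH_DEG = 22.5
N_BINS = 16


def sector_interval(index: int) -> tuple[float, float]:
    """Half-open degree interval [lo, hi) covered by sector ``index``."""
    return (BIN_WIDTH_DEG * index, BIN_WIDTH_DEG * (index + 1))


def sector_of(direction_deg: float) -> int:
    """Index of the sector containing a direction in [0, 360)."""
    d = float(direction_deg) % 360.0
    return int(d // BIN_WIDTH_DEG)


@dataclass(frozen=True)
class WindRose:
    """Sixteen-bin directional frequency table.

    ``frequencies[b]`` counts records whose direction fell in sector b of
    :data:`COMPASS_16`.  ``percentages`` (two decimals) and ``ranks``
    (1 = least frequent .. 16 = most frequent) are filled by
    :func:`rank_and_percent`.
    """

    frequencies: tuple = field(default_factory=lambda: (0,) * N_BINS)
    percentages: tuple | None = None
    ranks: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.frequencies) != N_BINS:
            raise ValidationError(f"a wind rose has {N_BINS} bins")
        if any(f < 0 for f in self.frequencies):
            raise ValidationError("bin frequencies must be non-negative")
        object.__setattr__(self, "frequencies", tuple(int(f) for f in self.frequencies))

    @property
    def total(self) -> int:
        return int(sum(self.frequencies))

    @property
    def labels(self) -> tuple:
        return COMPASS_16

    @property
    def destination_labels(self) -> tuple:
        """Opposite compass point of each source sector."""
        return tuple(COMPASS_16[(i + 8) % N_BINS] for i in range(N_BINS))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(N_BINS):
            lo, hi = sector_interval(i)
            rows.append(
                {
                    "row": i + 1,
                    "source": COMPASS_16[i],
                    "degrees": f"{lo:g}-{hi:g}",
                    "destination": self.destination_labels[i],
                    "frequency": self.frequencies[i],
                    "percentage": None if self.percentages is None else self.percentages[i],
                    "rank": None if self.ranks is None else self.ranks[i],
                }
            )
        return pd.DataFrame(rows)


def filter_flight_season(
    days: Sequence[WindDay],
    start_year: int,
    end_year: int,
    months: tuple[int, int] = (6, 10),
) -> list[WindDay]:
    """Keep records inside the assumed flight season (June-October,
    inclusive, by default) and the year range [start_year, end_year]."""
    if start_year > end_year:
        raise ValidationError(f"start_year {start_year} > end_year {end_year}")
    lo, hi = months
    return [
        d
        for d in days
        if lo <= d.date.month <= hi and start_year <= d.date.year <= end_year
    ]


def bin_directions(days: Sequence[WindDay]) -> WindRose:
    """Tally source directions into the sixteen sectors."""
    freq = [0] * N_BINS
    for d in days:
        freq[sector_of(d.direction_deg)] += 1
    return WindRose(frequencies=tuple(freq))


def destination_rose(rose: WindRose) -> WindRose:
    """Rose of expected landing (destination) sectors.

    The destination frequency of sector b is the source frequency of the
    opposite sector (b + 8 mod 16); applying the shift twice restores the
    original rose.  Percentages and ranks are shifted along with the
    frequencies when present.
    """
    shift = lambda seq: None if seq is None else tuple(
        seq[(i + 8) % N_BINS] for i in range(N_BINS)
    )
    return WindRose(
        frequencies=shift(rose.frequencies),
        percentages=shift(rose.percentages),
        ranks=shift(rose.ranks),
    )


def rank_and_percent(rose: WindRose) -> WindRose:
    """Fill percentages (2 decimals) and ranks (ascending by frequency,
    ties broken by compass row order, N first)."""
    freq = np.asarray(rose.frequencies, dtype=float)
    total = freq.sum()
    if total <= 0:
        raise ValidationError("cannot rank an empty wind rose")
    percent = tuple(round(100.0 * f / total, 2) for f in freq)
    order = np.argsort(freq, kind="stable")  # stable: ties keep row order
    ranks = [0] * N_BINS
    for position, bin_index in enumerate(order, start=1):
        ranks[int(bin_index)] = position
    return replace(rose, percentages=percent, ranks=tuple(ranks))


def bearing_between(
    origin: tuple[float, float], target: tuple[float, float]
) -> float:
    """Bearing (degrees clockwise from north, [0, 360)) of the displacement
    from ``origin`` to ``target`` in planar (east, north) coordinates."""
    dx = target[0] - origin[0]
    dy = target[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        raise ValidationError("bearing is undefined for coincident points")
    return math.degrees(math.atan2(dx, dy)) % 360.0


@dataclass(frozen=True)
class OutlierPlacement:
    """Where one outlying infestation sits relative to the wind rose."""

    point: tuple
    bearing_deg: float
    sector: str
    destination_rank: int
    inside_top_k: bool


@dataclass(frozen=True)
class TopBinReport:
    placements: tuple
    k: int
    fraction_inside: float


def outliers_in_top_bins(
    rose: WindRose,
    source: tuple[float, float],
    outliers: Sequence[tuple[float, float]],
    k: int = 4,
) -> TopBinReport:
    """Test whether outlying infestations sit in the top-k destination bins.

    For each outlier, the bearing from the source tree places it in a
    compass sector; that sector's *destination likelihood* is the frequency
    rank of the opposite (source) bin, since wind from sector b+8 carries
    dispersers into sector b.  An outlier is "inside" when that rank is
    among the k largest.  The rose must carry ranks
    (see :func:`rank_and_percent`).
    """
    if not (1 <= k <= N_BINS):
        raise ValidationError(f"k must be in 1..{N_BINS}, got {k}")
    ranked = rose if rose.ranks is not None else rank_and_percent(rose)
    placements = []
    inside_count = 0
    for point in outliers:
        bearing = bearing_between(source, tuple(point))
        sector = sector_of(bearing)
        dest_rank = ranked.ranks[(sector + 8) % N_BINS]
        inside = dest_rank > N_BINS - k
        inside_count += inside
        placements.append(
            OutlierPlacement(
                point=tuple(point),
                bearing_deg=bearing,
                sector=COMPASS_16[sector],
                destination_rank=int(dest_rank),
                inside_top_k=bool(inside),
            )
        )
    fraction = inside_count / len(placements) if placements else float("nan")
    return TopBinReport(placements=tuple(placements), k=k, fraction_inside=fraction)
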