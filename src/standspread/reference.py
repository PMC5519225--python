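"""Reference wind climatology used as the default for synthetic wind series.

Directional frequencies of the daily fastest-5-second gust (direction the
wind blew from), June-October 1998-2014, from the airport weather station
nearest the study stand.  Sixteen 22.5-degree sectors in compass row order
(N first, clockwise); the dominant sector is WSW, so wind-borne dispersers
from a point source are most likely to land toward ENE.
"""

from __future__ import annotations

from standspread.wind import COMPASS_16

#: Daily fastest-gust source-direction counts per compass sector.
FLIGHT_SEASON_GUST_FREQUENCIES: dict[str, int] = dict(
    zip(
        COMPASS_16,
        (110, 99, 117, 118, 20, 36, 68, 113, 149, 245, 289, 372, 351, 319, 113, 146),
    )
)

#: Total number of daily records behind the counts above.
FLIGHT_SEASON_GUST_TOTAL: int = sum(FLIGHT_SEASON_GUST_FREQUENCIES.values())


def gust_frequency_tuple() -> tuple[int, ...]:
    """Frequencies as a 16-tuple in compass row order."""
    return tuple(FLIGHT_SEASON_GUST_FREQUENCIES[label] for label in COMPASS_16)


def gust_probability_tuple() -> tuple[float, ...]:
    """Frequencies normalised to per-day sector probabilities."""
    total = float(FLIGHT_SEASON_GUST_TOTAL)
    return tuple(f / total for f in gust_frequency_tuple())
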