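"""Synthetic stands, establishment histories, and wind records.

Every generator is seed-deterministic and writes its configuration into the
output for provenance.  Defaults emulate the study conditions the pipeline
is built for: a dense ~2,860 m^2 wetland stand of 526 stems, ~94% host
genera with ~81% of stems a single preferred host species, a right-skewed
trunk-diameter distribution, an infestation founded in 2008 and felled in
2013 with a ~2-year development lag, and flight-season (June-October) gust
directions following the reference airport climatology.

The establishment simulator is phenomenological.  Each year it draws a
number of new colonisations whose mean grows geometrically (beetle
populations build up over several generations, so almost all spread happens
in the last two seasons), picks targets near the currently active trees
with probability proportional to dbh^exponent (size-biased host choice),
and attributes each colonisation to the nearest tree with emerging adults —
the strict nearest-active-source transmission rule that the adjacency
inference assumes.  A small fraction of events instead leave the stand as
long-distance dispersers whose travel direction follows the wind-rose
destination distribution.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import asdict, dataclass, field
from datetime import date as _date

import numpy as np

from standspread.core_io import (
    DamageKind,
    Stand,
    TreeRecord,
    ValidationError,
    WindDay,
    WoodSectionRecord,
)
from standspread.reference import gust_probability_tuple
from standspread.wind import BIN_WIDTH_DEG, N_BINS

#: Host genera other than the preferred host used to fill the host fraction.
_OTHER_HOST_GENERA = ("Malus", "Betula", "Fraxinus", "Salix", "Populus", "Ulmus", "Fagus")
#: Non-host genera present as interspersed stems.
_NON_HOST_GENERA = ("Quercus", "Pinus", "Carya", "Cornus", "Ilex", "Viburnum")


class ConfigError(ValidationError):
    """A generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class StandConfig:
    """Stand generator settings.

    ``dbh_lognormal_params`` are (meanlog, sdlog) of the trunk-diameter
    distribution in cm; the defaults give a right-skewed stand with a median
    near 7 cm, so that size-biased infestation shifts the infested median
    into the high teens.  ``spatial_pattern`` is ``"clustered"`` (a
    parent-offspring Thomas-like process mimicking a clumped wetland stand)
    or ``"uniform"`` (the null).
    """

    n_trees: int = 526
    area_m2: float = 2860.0
    host_fraction: float = 0.94
    preferred_host_fraction: float = 0.81
    dbh_lognormal_params: tuple[float, float] = (1.95, 0.8)
    spatial_pattern: str = "clustered"
    aspect_ratio: float = 2.0
    cluster_sigma_m: float = 4.0
    trees_per_cluster: float = 20.0
    preferred_genus: str = "Acer"
    preferred_species: str = "rubrum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ConfigError("n_trees must be positive")
        if not (0.0 <= self.preferred_host_fraction <= self.host_fraction <= 1.0):
            raise ConfigError(
                "need 0 <= preferred_host_fraction <= host_fraction <= 1, got "
                f"{self.preferred_host_fraction} / {self.host_fraction}"
            )
        if self.spatial_pattern not in {"uniform", "clustered"}:
            raise ConfigError(f"unknown spatial_pattern {self.spatial_pattern!r}")
        if self.area_m2 <= 0:
            raise ConfigError("area_m2 must be positive")


@dataclass(frozen=True)
class SpreadConfig:
    """Establishment simulator settings.

    The yearly number of new colonisations is drawn with mean
    ``annual_mean * annual_growth**(year - start_year - lag)`` from the first
    emergence year onward (negative-binomial with size ``dispersion``, or
    Poisson when ``dispersion`` is None).  The growth factor reflects the
    build-up of the beetle population; with the defaults the expected
    cohort sizes over 2008-2013 are 1, 3.7, 13.7, 50.6 new trees plus the
    founders, i.e. ~71 infested stems with almost all colonisations in the
    last two seasons.

    ``size_bias_exponent`` weights host choice by dbh^exponent among the
    ``neighborhood_size`` nearest un-infested preferred hosts of the natal
    tree.  ``long_distance_rate`` is the per-event probability that the
    disperser leaves the stand instead; its landing direction follows the
    destination shift of ``wind_rose_weights`` (source-bin probabilities)
    and its distance is lognormal around ``long_distance_m``.

    Damage accumulates with occupancy: a tree colonised ``c`` with ``k``
    emergence seasons before felling carries ~``exit_base * exit_growth**
    (k-1)`` exit holes, so founders end at C level (tens of holes), trees
    colonised two to three seasons before felling at B (a few holes), and
    later colonisations at A (pits only).
    """

    start_year: int = 2008
    end_year: int = 2013
    development_lag_years: int = 2
    size_bias_exponent: float = 2.0
    annual_mean: float = 1.0
    annual_growth: float = 3.7
    dispersion: float | None = None
    long_distance_rate: float = 0.02
    long_distance_m: float = 1400.0
    wind_rose_weights: tuple[float, ...] = field(default_factory=gust_probability_tuple)
    n_founders: int = 2
    neighborhood_size: int = 40
    annual_schedule: tuple[float, ...] | None = None
    pit_rate_per_year: float = 6.0
    exit_base: float = 2.0
    exit_growth: float = 2.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ConfigError("start_year must not exceed end_year")
        if self.development_lag_years <= 0:
            raise ConfigError("development_lag_years must be positive")
        if self.size_bias_exponent < 0:
            raise ConfigError("size_bias_exponent must be >= 0")
        if not (0.0 <= self.long_distance_rate <= 1.0):
            raise ConfigError("long_distance_rate must be in [0, 1]")
        if self.n_founders < 1:
            raise ConfigError("n_founders must be >= 1")
        weights = tuple(float(w) for w in self.wind_rose_weights)
        if len(weights) != N_BINS or any(w < 0 for w in weights):
            raise ConfigError(f"wind_rose_weights must be {N_BINS} non-negative reals")
        total = sum(weights)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            if total <= 0:
                raise ConfigError("wind_rose_weights must sum to a positive value")
            weights = tuple(w / total for w in weights)
        object.__setattr__(self, "wind_rose_weights", weights)
        if self.annual_schedule is not None:
            sched = tuple(float(m) for m in self.annual_schedule)
            if any(m < 0 for m in sched):
                raise ConfigError("annual_schedule means must be non-negative")
            object.__setattr__(self, "annual_schedule", sched)

    @classmethod
    def strict(cls, seed: int = 0, **overrides) -> "SpreadConfig":
        """Strict nearest-eligible-source spread scenario.

        A single founder seeds a first wave of colonisations in its first
        emergence season; spread then pauses while the population builds
        (the classic reluctance to leave the natal tree), and a mass wave of
        pits-only colonisations follows in the felling season.  Under this
        two-wave timing every colonist's nearest active source coincides
        with the nearest higher-level tree at felling, so the adjacency
        inference is consistent with the generative process.
        """
        defaults = dict(
            n_founders=1,
            long_distance_rate=0.0,
            annual_schedule=(5.0, 0.0, 0.0, 65.0),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class WindConfig:
    """Wind-series generator: one record per flight-season day (June-October)
    in the year range, sector drawn from ``bin_probabilities`` (compass row
    order), direction uniform within the 22.5-degree sector."""

    years: tuple[int, int] = (1998, 2014)
    bin_probabilities: tuple[float, ...] = field(default_factory=gust_probability_tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[0] > self.years[1]:
            raise ConfigError("year range must be ordered")
        probs = tuple(float(p) for p in self.bin_probabilities)
        if len(probs) != N_BINS or any(p < 0 for p in probs):
            raise ConfigError(f"bin_probabilities must be {N_BINS} non-negative reals")
        total = sum(probs)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            if total <= 0:
                raise ConfigError("bin_probabilities must sum to a positive value")
            probs = tuple(p / total for p in probs)
        object.__setattr__(self, "bin_probabilities", probs)


@dataclass(frozen=True)
class OutlierEvent:
    """A long-distance dispersal event landing outside the stand."""

    year: int
    source_id: str
    bearing_deg: float
    distance_m: float
    x_m: float
    y_m: float


@dataclass
class TruthRecord:
    """Ground truth of a simulated establishment: the source tree, every
    transmission edge (source id, target id), per-tree colonisation years,
    and any long-distance events."""

    root_id: str
    founder_ids: list[str]
    edges: list[tuple[str, str]]
    colonization_year: dict[str, int]
    outliers: list[OutlierEvent] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "root_id": self.root_id,
            "founder_ids": list(self.founder_ids),
            "edges": [list(e) for e in self.edges],
            "colonization_year": dict(self.colonization_year),
            "outliers": [asdict(o) for o in self.outliers],
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# Stand generation
# ---------------------------------------------------------------------------


def _place_stems(cfg: StandConfig, rng: np.random.Generator) -> np.ndarray:
    width = math.sqrt(cfg.area_m2 * cfg.aspect_ratio)
    height = cfg.area_m2 / width
    n = cfg.n_trees
    if cfg.spatial_pattern == "uniform":
        return np.column_stack(
            [rng.uniform(0, width, n), rng.uniform(0, height, n)]
        )
    n_parents = max(1, round(n / cfg.trees_per_cluster))
    parents = np.column_stack(
        [rng.uniform(0, width, n_parents), rng.uniform(0, height, n_parents)]
    )
    assignment = rng.integers(0, n_parents, n)
    coords = np.empty((n, 2))
    for i in range(n):
        for _ in range(100):  # rejection sampling into the rectangle
            p = parents[assignment[i]] + rng.normal(0.0, cfg.cluster_sigma_m, 2)
            if 0 <= p[0] <= width and 0 <= p[1] <= height:
                coords[i] = p
                break
        else:
            coords[i] = np.clip(p, [0, 0], [width, height])
    return coords


def generate_stand(cfg: StandConfig) -> Stand:
    """Generate a stem-mapped stand per the configuration."""
    rng = np.random.default_rng(cfg.seed)
    coords = _place_stems(cfg, rng)
    meanlog, sdlog = cfg.dbh_lognormal_params
    dbh = np.maximum(0.5, np.round(rng.lognormal(meanlog, sdlog, cfg.n_trees), 1))
    mix = rng.random(cfg.n_trees)
    width = int(math.ceil(math.log10(cfg.n_trees + 1)))
    trees = []
    for i in range(cfg.n_trees):
        if mix[i] < cfg.preferred_host_fraction:
            genus, species, host = cfg.preferred_genus, cfg.preferred_species, True
        elif mix[i] < cfg.host_fraction:
            genus = _OTHER_HOST_GENERA[rng.integers(0, len(_OTHER_HOST_GENERA))]
            species, host = "", True
        else:
            genus = _NON_HOST_GENERA[rng.integers(0, len(_NON_HOST_GENERA))]
            species, host = "", False
        trees.append(
            TreeRecord(
                tree_id=f"T{i + 1:0{width}d}",
                genus=genus,
                species=species,
                dbh_cm=float(dbh[i]),
                x_m=float(coords[i, 0]),
                y_m=float(coords[i, 1]),
                is_host=host,
            )
        )
    return Stand(
        trees=trees,
        area_m2=cfg.area_m2,
        meta={"stand_config": asdict(cfg)},
    )


# ---------------------------------------------------------------------------
# Establishment simulation
# ---------------------------------------------------------------------------


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None or not math.isfinite(dispersion):
        return int(rng.poisson(mean))
    # negative binomial with mean m and size k: var = m + m^2/k
    k = float(dispersion)
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def simulate_establishment(stand: Stand, cfg: SpreadConfig) -> tuple[Stand, TruthRecord]:
    """Run the establishment process over a stand, in place.

    Fills pit counts, wood sections (all exit holes plus the sampled
    first-season pit section per infested tree), and the stand felling year;
    returns the stand together with the :class:`TruthRecord`.  Trees are
    conserved and only preferred hosts are ever infested.
    """
    stand_cfg = stand.meta.get("stand_config", {})
    taxon = (
        stand_cfg.get("preferred_genus", "Acer"),
        stand_cfg.get("preferred_species", "rubrum"),
    )
    preferred = [t for t in stand if t.is_host and (t.genus, t.species) == taxon]
    if not preferred:  # fall back to any host carrying a full species name
        preferred = [t for t in stand if t.is_host and t.species]
    if not preferred:
        raise ConfigError("the stand contains no preferred host trees")
    for t in stand:
        if not t.has_coords:
            raise ValidationError(f"tree {t.tree_id!r} has unresolved coordinates")

    rng = np.random.default_rng(cfg.seed)
    ids = stand.ids
    index = {tid: i for i, tid in enumerate(ids)}
    coords = np.array([[t.x_m, t.y_m] for t in stand])
    dbh = np.array([t.dbh_cm for t in stand])
    preferred_idx = np.array([index[t.tree_id] for t in preferred])

    lag = cfg.development_lag_years
    felling = cfg.end_year
    colonized: dict[int, int] = {}  # tree index -> colonisation year
    edges: list[tuple[str, str]] = []
    outliers: list[OutlierEvent] = []

    founder_pool = preferred_idx.copy()
    founders = rng.choice(founder_pool, size=min(cfg.n_founders, founder_pool.size), replace=False)
    for f in founders:
        colonized[int(f)] = cfg.start_year

    def emerged_at(year: int) -> list[int]:
        return [i for i, c in colonized.items() if c <= year - lag]

    for year in range(cfg.start_year + lag, felling + 1):
        emerged = emerged_at(year)
        if not emerged:
            continue
        step = year - cfg.start_year - lag
        if cfg.annual_schedule is not None:
            mean = cfg.annual_schedule[step] if step < len(cfg.annual_schedule) else 0.0
        else:
            mean = cfg.annual_mean * cfg.annual_growth**step
        n_events = _draw_count(rng, mean, cfg.dispersion)
        # emergence activity grows with occupancy age; weight sources by it
        activity = np.array(
            [cfg.exit_growth ** (year - lag - colonized[i]) for i in emerged], dtype=float
        )
        activity /= activity.sum()
        for _ in range(n_events):
            natal = int(rng.choice(emerged, p=activity))
            if rng.random() < cfg.long_distance_rate:
                dest_bin = (
                    int(rng.choice(N_BINS, p=np.asarray(cfg.wind_rose_weights))) + 8
                ) % N_BINS
                bearing = (dest_bin + rng.random()) * BIN_WIDTH_DEG
                distance = cfg.long_distance_m * rng.lognormal(0.0, 0.3)
                b = math.radians(bearing)
                outliers.append(
                    OutlierEvent(
                        year=year,
                        source_id=ids[natal],
                        bearing_deg=bearing,
                        distance_m=distance,
                        x_m=coords[natal, 0] + distance * math.sin(b),
                        y_m=coords[natal, 1] + distance * math.cos(b),
                    )
                )
                continue
            open_hosts = np.array(
                [i for i in preferred_idx if i not in colonized], dtype=int
            )
            if open_hosts.size == 0:
                break
            d = np.hypot(
                coords[open_hosts, 0] - coords[natal, 0],
                coords[open_hosts, 1] - coords[natal, 1],
            )
            nearest = open_hosts[np.argsort(d, kind="stable")[: cfg.neighborhood_size]]
            weights = dbh[nearest] ** cfg.size_bias_exponent
            weights = weights / weights.sum()
            target = int(rng.choice(nearest, p=weights))
            # strict nearest-active-source transmission: the colonist is
            # attributed to the nearest tree with emerging adults
            emerged_arr = np.array(emerged, dtype=int)
            dists = np.hypot(
                coords[emerged_arr, 0] - coords[target, 0],
                coords[emerged_arr, 1] - coords[target, 1],
            )
            source = int(emerged_arr[int(np.argmin(dists))])
            colonized[target] = year
            edges.append((ids[source], ids[target]))

    # --- damage bookkeeping ---------------------------------------------
    for i, c in colonized.items():
        tree = stand.trees[i]
        seasons = (felling - lag) - c + 1  # emergence seasons before felling
        occupancy = felling - c + 1
        tree.pit_count = max(1, int(rng.poisson(cfg.pit_rate_per_year * occupancy)))
        sections: list[WoodSectionRecord] = []
        first_rings = felling - c
        sections.append(
            WoodSectionRecord(
                DamageKind.OVIPOSITION_PIT,
                healed=first_rings > 0,
                rings_over=first_rings,
            )
        )
        if seasons > 0:
            n_exits = max(1, int(rng.poisson(cfg.exit_base * cfg.exit_growth ** (seasons - 1))))
            first_emergence = c + lag
            years = [first_emergence]
            if n_exits > 1 and felling >= first_emergence:
                span = np.arange(first_emergence, felling + 1)
                w = cfg.exit_growth ** (span - first_emergence)
                years.extend(
                    int(y) for y in rng.choice(span, size=n_exits - 1, p=w / w.sum())
                )
            for y in years:
                rings = felling - y
                sections.append(
                    WoodSectionRecord(
                        DamageKind.EXIT_HOLE,
                        healed=rings > 0,
                        rings_over=rings,
                    )
                )
        tree.sections = sections

    stand.felling_year = felling
    stand.meta["spread_config"] = _spread_config_dict(cfg)
    truth = TruthRecord(
        root_id=ids[int(founders[0])],
        founder_ids=[ids[int(f)] for f in founders],
        edges=edges,
        colonization_year={ids[i]: c for i, c in colonized.items()},
        outliers=outliers,
        config=_spread_config_dict(cfg),
    )
    return stand, truth


def _spread_config_dict(cfg: SpreadConfig) -> dict:
    d = asdict(cfg)
    d["wind_rose_weights"] = list(d["wind_rose_weights"])
    return d


# ---------------------------------------------------------------------------
# Wind series
# ---------------------------------------------------------------------------

_FLIGHT_MONTHS = (6, 7, 8, 9, 10)


def generate_wind_series(cfg: WindConfig) -> list[WindDay]:
    """One wind record per flight-season day in the configured year range."""
    rng = np.random.default_rng(cfg.seed)
    probs = np.asarray(cfg.bin_probabilities)
    days: list[WindDay] = []
    for year in range(cfg.years[0], cfg.years[1] + 1):
        for month in _FLIGHT_MONTHS:
            _, n_days = calendar.monthrange(year, month)
            for day in range(1, n_days + 1):
                sector = int(rng.choice(N_BINS, p=probs))
                direction = (sector + rng.random()) * BIN_WIDTH_DEG
                days.append(WindDay(date=_date(year, month, day), direction_deg=direction))
    return days
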