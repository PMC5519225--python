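"""Dispersal-graph inference under nearest-higher-level adjacency rules.

Two rules turn a classified, stem-mapped stand into a directed dispersal
graph: (1) an infested tree is assumed to have received its beetles from the
nearest tree with a strictly higher infestation level — each A tree from its
nearest B-or-C tree, each B tree from its nearest C tree; (2) a tree can be
the source for many trees but receives beetles exactly once, so every
infested non-root tree is the target of exactly one edge.  C trees receive
no in-edge; with several C trees each heads its own subtree, while the
stand's root is the single earliest-dated tree.  Edges run strictly down the
level order, so the graph is acyclic by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from standspread.core_io import InfestationLevel, Stand, StateError, ValidationError
from standspread.damage_dating import tree_earliest_years
from standspread.stats import TestResult, ks_two_sample, median_iqr
from standspread.wind import bearing_between


class OrphanTreeError(ValidationError):
    """An infested tree has no eligible source anywhere in the stand."""


@dataclass(frozen=True)
class DispersalEdge:
    """One inferred dispersal event (adjacency vector), source -> target."""

    source_id: str
    target_id: str
    distance_m: float
    bearing_deg: float

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValidationError(
                f"edge {self.source_id}->{self.target_id}: distance must be positive"
            )
        object.__setattr__(self, "bearing_deg", float(self.bearing_deg) % 360.0)


@dataclass
class DispersalGraph:
    root_id: str | None
    edges: list[DispersalEdge] = field(default_factory=list)

    @property
    def target_ids(self) -> set[str]:
        return {e.target_id for e in self.edges}

    @property
    def source_ids(self) -> set[str]:
        return {e.source_id for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(
                e.source_id, e.target_id,
                distance_m=e.distance_m, bearing_deg=e.bearing_deg,
            )
        if self.root_id is not None:
            g.add_node(self.root_id)
        return g


def _infested(stand: Stand):
    trees = []
    for t in stand:
        if t.level is None:
            raise StateError(
                f"tree {t.tree_id!r} has no infestation level; classify first"
            )
        if t.level is not InfestationLevel.NONE:
            trees.append(t)
    return trees


def identify_root(stand: Stand) -> str:
    """Name the stand's source tree: the earliest dated oviposition.

    Ties are broken by, in order: earlier earliest exit year, more exit
    holes, lexicographic tree id.  Requires dated wood sections
    (see :func:`standspread.damage_dating.date_stand`).
    """
    candidates = []
    for t in _infested(stand):
        pit_year, exit_year = tree_earliest_years(t)
        if pit_year is None and exit_year is None:
            continue
        candidates.append(
            (
                pit_year if pit_year is not None else math.inf,
                exit_year if exit_year is not None else math.inf,
                -t.exit_count,
                t.tree_id,
            )
        )
    if not candidates:
        raise StateError(
            "cannot identify a root: no infested tree carries dated damage"
        )
    return min(candidates)[3]


def build_graph(stand: Stand, root_id: str | None = None) -> DispersalGraph:
    """Apply the adjacency rules to a classified, stem-mapped stand.

    Every A tree is linked from its nearest B-or-C tree and every B tree
    from its nearest C tree (Euclidean distance; exact ties broken by
    lexicographic source id).  A missing eligible source anywhere in the
    stand is a structural error naming the orphan.
    """
    infested = _infested(stand)
    for t in infested:
        if not t.has_coords:
            raise StateError(f"tree {t.tree_id!r} has unresolved coordinates")
    by_level = {
        level: [t for t in infested if t.level is level]
        for level in (InfestationLevel.A, InfestationLevel.B, InfestationLevel.C)
    }
    edges: list[DispersalEdge] = []
    for target_level, source_levels in (
        (InfestationLevel.A, (InfestationLevel.B, InfestationLevel.C)),
        (InfestationLevel.B, (InfestationLevel.C,)),
    ):
        sources = [t for lvl in source_levels for t in by_level[lvl]]
        for target in by_level[target_level]:
            if not sources:
                raise OrphanTreeError(
                    f"tree {target.tree_id!r} (level {target.level.name}) has no "
                    "higher-level source tree in the stand"
                )
            tx, ty = target.coords
            best = min(
                (math.hypot(s.x_m - tx, s.y_m - ty), s.tree_id, s) for s in sources
            )
            dist, _, source = best
            edges.append(
                DispersalEdge(
                    source_id=source.tree_id,
                    target_id=target.tree_id,
                    distance_m=dist,
                    bearing_deg=bearing_between(source.coords, target.coords),
                )
            )
    return DispersalGraph(root_id=root_id, edges=edges)


def inferred_distances(graph: DispersalGraph) -> list[float]:
    """Edge lengths of the dispersal graph, meters."""
    return [e.distance_m for e in graph.edges]


def _root_tree(stand: Stand, root_id: str):
    tree = stand.tree(root_id)
    if not tree.has_coords:
        raise StateError(f"root {root_id!r} has unresolved coordinates")
    return tree


def potential_distances(stand: Stand, root_id: str) -> list[float]:
    """Distance from the root to every other tree in the stand, infested or
    not — the distances available had beetles moved without preference."""
    root = _root_tree(stand, root_id)
    rx, ry = root.coords
    return [
        math.hypot(t.x_m - rx, t.y_m - ry)
        for t in stand
        if t.tree_id != root_id and t.has_coords
    ]


def observed_source_distances(stand: Stand, root_id: str) -> list[float]:
    """Distance from the root to each other infested tree."""
    root = _root_tree(stand, root_id)
    rx, ry = root.coords
    return [
        math.hypot(t.x_m - rx, t.y_m - ry)
        for t in _infested(stand)
        if t.tree_id != root_id
    ]


@dataclass
class DistanceComparison:
    """Inferred (or observed) vs potential dispersal-distance comparison."""

    inferred: list[float]
    potential: list[float]
    ks: TestResult
    median_inferred: float
    iqr_inferred: float
    median_potential: float
    iqr_potential: float
    label: str = "inferred_vs_potential"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ks.statistic_value <= 1.0):
            raise ValidationError("KS D out of [0, 1]")
        if self.iqr_inferred < 0 or self.iqr_potential < 0:
            raise ValidationError("IQR cannot be negative")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "ks_D": self.ks.statistic_value,
            "ks_p_approx": self.ks.p_value,
            "n_inferred": len(self.inferred),
            "n_potential": len(self.potential),
            "median_inferred_m": self.median_inferred,
            "iqr_inferred_m": self.iqr_inferred,
            "median_potential_m": self.median_potential,
            "iqr_potential_m": self.iqr_potential,
            "quantile_convention": "linear interpolation; IQR = Q3 - Q1",
        }


def compare(
    inferred_or_observed: list[float],
    potential: list[float],
    label: str = "inferred_vs_potential",
) -> DistanceComparison:
    """KS comparison plus medians and IQRs of the two distance samples.

    The first argument may be either the graph's edge lengths (inferred
    dispersal events) or the root-to-infested distances (observed spread);
    ``label`` records which framing was fed in.
    """
    if not inferred_or_observed or not potential:
        raise ValidationError("distance comparison requires two non-empty samples")
    ks = ks_two_sample(inferred_or_observed, potential)
    med_i, iqr_i = median_iqr(inferred_or_observed)
    med_p, iqr_p = median_iqr(potential)
    return DistanceComparison(
        inferred=list(map(float, inferred_or_observed)),
        potential=list(map(float, potential)),
        ks=ks,
        median_inferred=med_i,
        iqr_inferred=iqr_i,
        median_potential=med_p,
        iqr_potential=iqr_p,
        label=label,
    )
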