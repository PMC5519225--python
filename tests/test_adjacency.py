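"""Root identification, dispersal-graph inference, distance distributions."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from standspread.adjacency import (
    OrphanTreeError,
    build_graph,
    compare,
    identify_root,
    inferred_distances,
    observed_source_distances,
    potential_distances,
)
from standspread.core_io import (
    DamageKind,
    InfestationLevel,
    Stand,
    ValidationError,
    WoodSectionRecord,
)
from standspread.damage_dating import date_stand
from standspread.infestation import classify_stand
from standspread.survey_geometry import pairwise_distances
from tests.conftest import make_tree


def tree_with_damage(tree_id, x, y, *, pit_rings=None, exit_rings=(), pits=1):
    """Tree whose sections date to felling_year - rings for each entry."""
    sections = []
    if pit_rings is not None:
        sections.append(
            WoodSectionRecord(
                DamageKind.OVIPOSITION_PIT, healed=pit_rings > 0, rings_over=pit_rings
            )
        )
    for r in exit_rings:
        sections.append(
            WoodSectionRecord(DamageKind.EXIT_HOLE, healed=r > 0, rings_over=r)
        )
    return make_tree(tree_id, x, y, pit_count=pits, sections=sections)


def prepared(stand: Stand) -> Stand:
    date_stand(stand)
    return classify_stand(stand)


class TestIdentifyRoot:
    def test_earliest_oviposition_wins(self):
        stand = prepared(
            Stand(
                trees=[
                    tree_with_damage("late", 0, 0, pit_rings=2),  # 2011
                    tree_with_damage("mid", 1, 0, pit_rings=4),  # 2009
                    tree_with_damage("early", 2, 0, pit_rings=5),  # 2008
                ],
                felling_year=2013,
            )
        )
        assert identify_root(stand) == "early"

    def test_single_infested_tree(self):
        stand = prepared(
            Stand(trees=[tree_with_damage("only", 0, 0, pit_rings=3)], felling_year=2013)
        )
        assert identify_root(stand) == "only"

    def test_tie_broken_by_earlier_exit_year(self):
        stand = prepared(
            Stand(
                trees=[
                    tree_with_damage("slow", 0, 0, pit_rings=5, exit_rings=[2]),  # exit 2011
                    tree_with_damage("fast", 1, 0, pit_rings=5, exit_rings=[3]),  # exit 2010
                ],
                felling_year=2013,
            )
        )
        assert identify_root(stand) == "fast"

    def test_no_dated_damage_is_an_error(self):
        stand = classify_stand(
            Stand(trees=[make_tree("t", 0, 0, pit_count=3)], felling_year=2013)
        )
        with pytest.raises(Exception, match="dated"):
            identify_root(stand)


class TestBuildGraph:
    def test_forced_single_edge(self):
        stand = prepared(
            Stand(
                trees=[
                    tree_with_damage("C1", 0, 0, pit_rings=5, exit_rings=[3] * 12),
                    tree_with_damage("A1", 3, 4, pit_rings=0),
                ],
                felling_year=2013,
            )
        )
        graph = build_graph(stand, root_id="C1")
        assert len(graph.edges) == 1
        edge = graph.edges[0]
        assert (edge.source_id, edge.target_id) == ("C1", "A1")
        assert edge.distance_m == pytest.approx(5.0)
        assert inferred_distances(graph) == [pytest.approx(5.0)]

    def test_a_takes_nearest_higher_level_b_over_farther_c(self):
        stand = prepared(
            Stand(
                trees=[
                    tree_with_damage("A1", 0, 0, pit_rings=0),
                    tree_with_damage("B1", 0, 2, pit_rings=2, exit_rings=[1]),
                    tree_with_damage("C1", 0, 10, pit_rings=5, exit_rings=[3] * 12),
                ],
                felling_year=2013,
            )
        )
        graph = build_graph(stand)
        edges = {e.target_id: e.source_id for e in graph.edges}
        assert edges == {"A1": "B1", "B1": "C1"}

    def test_orphan_b_without_c_is_structural_error(self):
        stand = prepared(
            Stand(
                trees=[tree_with_damage("B1", 0, 0, pit_rings=2, exit_rings=[1])],
                felling_year=2013,
            )
        )
        with pytest.raises(OrphanTreeError, match="B1"):
            build_graph(stand)

    def test_matches_exhaustive_oracle_on_random_stand(self):
        """Edge set identical to a brute-force scan over eligible sources."""
        rng = np.random.default_rng(1)
        trees = []
        levels = {}
        for i in range(30):
            x, y = rng.uniform(0, 40, 2)
            kind = ("A", "B", "C", "NONE")[int(rng.integers(0, 4))]
            tid = f"t{i:02d}"
            levels[tid] = kind
            if kind == "A":
                trees.append(tree_with_damage(tid, x, y, pit_rings=0))
            elif kind == "B":
                trees.append(tree_with_damage(tid, x, y, pit_rings=2, exit_rings=[1, 1]))
            elif kind == "C":
                trees.append(
                    tree_with_damage(tid, x, y, pit_rings=5, exit_rings=[3] * 15)
                )
            else:
                trees.append(make_tree(tid, x, y))
        stand = prepared(Stand(trees=trees, felling_year=2013))

        graph = build_graph(stand)
        got = {(e.source_id, e.target_id) for e in graph.edges}

        coords = {t.tree_id: (t.x_m, t.y_m) for t in stand}
        expected = set()
        eligible = {"A": {"B", "C"}, "B": {"C"}}
        for tid, kind in levels.items():
            if kind not in eligible:
                continue
            candidates = [
                (math.dist(coords[tid], coords[sid]), sid)
                for sid, skind in levels.items()
                if skind in eligible[kind]
            ]
            expected.add((min(candidates)[1], tid))
        assert got == expected

    def test_edge_count_and_lengths_are_consistent(self):
        from standspread.synthetic_data import SpreadConfig, StandConfig, generate_stand, simulate_establishment

        stand = generate_stand(StandConfig(n_trees=200, seed=9))
        stand, _ = simulate_establishment(stand, SpreadConfig(seed=9, long_distance_rate=0.0))
        prepared(stand)
        graph = build_graph(stand)
        summary = {lvl: sum(t.level is lvl for t in stand) for lvl in InfestationLevel}
        assert len(graph.edges) == summary[InfestationLevel.A] + summary[InfestationLevel.B]
        # every edge length appears in the stand's pairwise-distance table
        table = pairwise_distances(stand)
        for e in graph.edges:
            assert e.distance_m == pytest.approx(table.loc[e.source_id, e.target_id])
        assert nx.is_directed_acyclic_graph(graph.to_networkx())


class TestDistances:
    def test_potential_distance_values_and_count(self, three_tree_stand):
        distances = potential_distances(three_tree_stand, "R")
        assert sorted(distances) == [pytest.approx(5.0), pytest.approx(10.0)]

    def test_observed_is_subset_of_potential(self):
        from standspread.synthetic_data import SpreadConfig, StandConfig, generate_stand, simulate_establishment

        stand = generate_stand(StandConfig(n_trees=150, seed=4))
        stand, truth = simulate_establishment(stand, SpreadConfig(seed=4, n_founders=1))
        prepared(stand)
        root = truth.root_id
        observed = observed_source_distances(stand, root)
        potential = potential_distances(stand, root)
        assert len(observed) == len(stand.infested()) - 1
        assert len(potential) == len(stand) - 1
        pot = sorted(potential)
        for d in observed:
            i = np.searchsorted(pot, d - 1e-9)
            assert abs(pot[int(i)] - d) < 1e-8

    def test_no_other_infested_gives_empty_observed(self):
        stand = prepared(
            Stand(trees=[tree_with_damage("R", 0, 0, pit_rings=3)], felling_year=2013)
        )
        assert observed_source_distances(stand, "R") == []


class TestCompare:
    def test_identical_lists(self):
        result = compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.ks.statistic_value == 0.0
        assert result.median_inferred == result.median_potential

    def test_disjoint_supports(self):
        assert compare([1, 2, 3], [101, 102, 103]).ks.statistic_value == 1.0

    def test_hand_computed_ecdf_value(self):
        assert compare([1, 2], [2, 3]).ks.statistic_value == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            compare([], [1.0])
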