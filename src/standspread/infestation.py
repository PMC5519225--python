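"""Infestation-level classification and stand-level summaries.

Severity levels follow the eradication-program convention: a tree with
oviposition pits but no emergence (exit) holes is level A; 1-10 exit holes
is level B; 11-100 exit holes is level C.  Exit holes dominate: a tree with
exit holes is B or C regardless of its pit count, since emergence implies
prior oviposition.  Counts above 100 have no named level and are mapped to
C with a warning rather than inventing a new category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from standspread.core_io import InfestationLevel, Stand, TreeRecord, ValidationError
from standspread.stats import TestResult, wilcoxon_rank_sum


def classify_tree(pit_count: int, exit_count: int) -> InfestationLevel:
    """Classify one tree from its damage counts."""
    if pit_count < 0 or exit_count < 0:
        raise ValidationError(
            f"damage counts must be non-negative, got pits={pit_count}, "
            f"exits={exit_count}"
        )
    if exit_count == 0:
        return InfestationLevel.A if pit_count > 0 else InfestationLevel.NONE
    if exit_count <= 10:
        return InfestationLevel.B
    if exit_count > 100:
        warnings.warn(
            f"exit-hole count {exit_count} exceeds the C-level ceiling of 100; "
            "classified as C",
            stacklevel=2,
        )
    return InfestationLevel.C


def classify_stand(stand: Stand) -> Stand:
    """Assign a level to every tree in place and return the stand."""
    for tree in stand:
        tree.level = classify_tree(tree.pit_count, tree.exit_count)
    return stand


@dataclass(frozen=True)
class LevelSummary:
    counts: dict = field(default_factory=dict)

    @property
    def infested(self) -> int:
        return sum(
            self.counts.get(level, 0)
            for level in (InfestationLevel.A, InfestationLevel.B, InfestationLevel.C)
        )

    @property
    def n_trees(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            **{level.name: self.counts.get(level, 0) for level in InfestationLevel},
            "infested": self.infested,
            "n_trees": self.n_trees,
        }


def summarize_levels(stand: Stand) -> LevelSummary:
    """Per-level tree counts; classifies on the fly where levels are unset."""
    counts = {level: 0 for level in InfestationLevel}
    for tree in stand:
        level = tree.level
        if level is None:
            level = classify_tree(tree.pit_count, tree.exit_count)
        counts[level] += 1
    return LevelSummary(counts=counts)


def dbh_rank_sum(stand: Stand, alternative: str = "two-sided") -> TestResult:
    """Rank-sum comparison of trunk diameters, infested vs un-infested.

    The comparison is restricted to the species actually infested: the
    un-infested group contains only trees whose (genus, species) occurs
    among the infested trees, so size is compared within the host taxon
    rather than against the whole species mix.  ``alternative='greater'``
    tests whether infested trees are larger.
    """
    infested = [t for t in stand if t.pit_count > 0 or t.exit_count > 0]
    if not infested:
        raise ValidationError("no infested trees; nothing to compare")
    taxa = {(t.genus, t.species) for t in infested}
    uninfested = [
        t
        for t in stand
        if (t.genus, t.species) in taxa and t.pit_count == 0 and t.exit_count == 0
    ]
    if not uninfested:
        raise ValidationError("no un-infested trees of the infested taxa")
    return wilcoxon_rank_sum(
        [t.dbh_cm for t in infested],
        [t.dbh_cm for t in uninfested],
        alternative=alternative,
    )
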