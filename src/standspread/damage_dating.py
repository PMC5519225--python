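"""Calendar dating of beetle damage from growth-ring counts.

A cross-cut section through an exit hole or oviposition pit shows how many
annual rings have formed over the wound.  An unhealed wound is dated to the
felling year; a healed or partially healed wound with k rings formed over it
is dated k years earlier.  Partial healing is treated identically to full
healing (the rings over the wound are what carry the date).  Oviposition
pits are dated by the same overgrowth rule.  Ring counting itself (wood
surface to integer) is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

from standspread.core_io import (
    DamageKind,
    Stand,
    TreeRecord,
    ValidationError,
    WoodSectionRecord,
)


class EmptyDatingError(ValueError):
    """No dated damage was available for a summary."""


@dataclass(frozen=True)
class DatingResult:
    """Stand-level dating summary.

    ``development_period_years`` is the gap between the earliest oviposition
    and the earliest adult emergence — the apparent egg-to-adult development
    time of the founding cohort.
    """

    earliest_oviposition_year: int
    earliest_exit_year: int
    development_period_years: int

    def __post_init__(self) -> None:
        if self.earliest_exit_year < self.earliest_oviposition_year:
            raise ValidationError(
                "earliest exit hole predates the earliest oviposition pit "
                f"({self.earliest_exit_year} < {self.earliest_oviposition_year}); "
                "the dating evidence is contradictory"
            )
        expected = self.earliest_exit_year - self.earliest_oviposition_year
        if self.development_period_years != expected:
            raise ValidationError(
                f"development period {self.development_period_years} != "
                f"{expected} (exit - oviposition)"
            )


def date_damage(rec: WoodSectionRecord, felling_year: int) -> int:
    """Assign a calendar year to one wood section.

    Unhealed damage is dated to the felling ("current") year.  Healed damage
    with k rings over it is dated ``felling_year - k``.  A section claiming
    to be healed with zero rings over it is contradictory and rejected.
    """
    if rec.healed and rec.rings_over == 0:
        raise ValidationError(
            "healed section with rings_over = 0: healing without ring formation "
            "is contradictory evidence"
        )
    if not rec.healed:
        rec.assigned_year = int(felling_year)
    else:
        rec.assigned_year = int(felling_year) - int(rec.rings_over)
    return rec.assigned_year


def date_stand(stand: Stand) -> Stand:
    """Date every wood section in the stand against its felling year."""
    if stand.felling_year is None:
        raise ValidationError("stand has no felling_year; dating requires one")
    for tree in stand:
        for rec in tree.sections:
            date_damage(rec, stand.felling_year)
    return stand


def tree_earliest_years(tree: TreeRecord) -> tuple[int | None, int | None]:
    """(earliest oviposition year, earliest exit year) for one tree, from
    its dated sections; ``None`` where no dated section of that kind exists."""
    pit_years = [
        s.assigned_year
        for s in tree.sections
        if s.damage_kind is DamageKind.OVIPOSITION_PIT and s.assigned_year is not None
    ]
    exit_years = [
        s.assigned_year
        for s in tree.sections
        if s.damage_kind is DamageKind.EXIT_HOLE and s.assigned_year is not None
    ]
    return (min(pit_years) if pit_years else None, min(exit_years) if exit_years else None)


def summarize_dating(stand: Stand) -> DatingResult:
    """Earliest oviposition and emergence years over the stand, plus the
    implied development period.

    Requires at least one dated pit and one dated exit hole.  If every exit
    hole predates every pit the evidence is contradictory and a validation
    error is raised rather than a silently inconsistent summary.
    """
    pit_years: list[int] = []
    exit_years: list[int] = []
    for tree in stand:
        pit, exit_ = tree_earliest_years(tree)
        if pit is not None:
            pit_years.append(pit)
        if exit_ is not None:
            exit_years.append(exit_)
    if not pit_years or not exit_years:
        raise EmptyDatingError(
            "dating summary requires at least one dated oviposition pit and "
            "one dated exit hole"
        )
    earliest_pit = min(pit_years)
    earliest_exit = min(exit_years)
    return DatingResult(
        earliest_oviposition_year=earliest_pit,
        earliest_exit_year=earliest_exit,
        development_period_years=earliest_exit - earliest_pit,
    )
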