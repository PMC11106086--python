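"""Felling-date qualities, contemporaneous felling phases, activity spans.

Once per-sample end years are anchored to the calendar, each timber's
felling date is classified by its preserved outermost wood: a waney edge
gives the exact felling year (felling in the dormant season after that
final ring), partial sapwood bounds the number of lost outer rings, and
heartwood alone gives only a terminus post quem.  Exact felling years are
then grouped into construction phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .calendar_units import CalendarYear

__all__ = [
    "DatedElement",
    "FellingDate",
    "FellingPhase",
    "felling_quality",
    "group_phases",
    "activity_span",
]


@dataclass
class DatedElement:
    """One anchored construction timber."""

    sample_id: str
    end_year: int  # astronomical year of the last measured ring
    genus: str = ""
    has_waney_edge: bool = False
    n_sapwood_rings: Optional[int] = None  # None = sapwood not identified
    x: Optional[float] = None  # optional planar site coordinates
    y: Optional[float] = None

    def __post_init__(self):
        if self.n_sapwood_rings is not None and self.n_sapwood_rings < 0:
            raise ValueError("sapwood count must be >= 0")


@dataclass
class FellingDate:
    """Quality-classified felling date of one element.

    kind is "exact" (waney edge), "estimated" (sapwood-bounded range) or
    "tpq" (terminus post quem only).  year_lo/year_hi bound the felling
    year inclusively; for "tpq" only year_lo is meaningful.
    """

    sample_id: str
    kind: str
    year_lo: int
    year_hi: Optional[int]

    def __str__(self) -> str:
        if self.kind == "exact":
            return f"{self.sample_id}: felled {CalendarYear(self.year_lo)}"
        if self.kind == "estimated":
            return (f"{self.sample_id}: felled between {CalendarYear(self.year_lo)}"
                    f" and {CalendarYear(self.year_hi)}")
        return f"{self.sample_id}: felled after {CalendarYear(self.year_lo)}"


@dataclass
class FellingPhase:
    """Timbers felled within a small tolerance of one another."""

    member_ids: list
    year_lo: int
    year_hi: int
    consistent_ids: list = field(default_factory=list)  # non-exact, overlapping


def felling_quality(
    e: DatedElement, sapwood_range: tuple[int, int] = (20, 30)
) -> FellingDate:
    """Classify an element's felling date.

    With a waney edge the felling year equals the end year exactly.  With
    ``s`` observed sapwood rings but no waney edge, at most
    ``max_sapwood - s`` outer rings are missing, so the felling year lies
    in ``[end, end + max(0, max_sapwood - s)]``.  Heartwood only gives a
    terminus post quem at the end year.
    """
    _, hi_sap = sapwood_range
    if e.has_waney_edge:
        return FellingDate(e.sample_id, "exact", e.end_year, e.end_year)
    s = e.n_sapwood_rings
    if s is not None and s > 0:
        return FellingDate(
            e.sample_id, "estimated", e.end_year, e.end_year + max(0, hi_sap - s)
        )
    return FellingDate(e.sample_id, "tpq", e.end_year, None)


def group_phases(
    elements: Sequence[DatedElement],
    tolerance: int = 2,
    sapwood_range: tuple[int, int] = (20, 30),
) -> list[FellingPhase]:
    """Single-linkage grouping of exact felling years into phases.

    Exact years whose successive gaps are <= tolerance join one phase;
    output is ordered by year.  Elements with only an estimated range are
    attached to every phase their range overlaps, as "consistent with".
    """
    dates = [felling_quality(e, sapwood_range) for e in elements]
    exact = sorted(
        (d for d in dates if d.kind == "exact"), key=lambda d: (d.year_lo, d.sample_id)
    )
    if not exact:
        return []
    phases: list[list[FellingDate]] = [[exact[0]]]
    for d in exact[1:]:
        if d.year_lo - phases[-1][-1].year_lo <= tolerance:
            phases[-1].append(d)
        else:
            phases.append([d])
    out = []
    estimated = [d for d in dates if d.kind == "estimated"]
    for grp in phases:
        lo = grp[0].year_lo
        hi = grp[-1].year_lo
        consistent = [d.sample_id for d in estimated
                      if d.year_lo <= hi and d.year_hi >= lo]
        out.append(FellingPhase([d.sample_id for d in grp], lo, hi, consistent))
    return out


def activity_span(elements: Sequence[DatedElement],
                  sapwood_range: tuple[int, int] = (20, 30)) -> int:
    """Years between the earliest and latest exact felling dates."""
    exact = [felling_quality(e, sapwood_range) for e in elements]
    years = [d.year_lo for d in exact if d.kind == "exact"]
    if len(years) < 2:
        raise ValueError("activity span needs at least two exact felling years")
    return max(years) - min(years)
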