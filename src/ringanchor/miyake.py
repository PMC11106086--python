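"""Chi-square placement of single-year 14C series and event anchoring.

A wood sample dissected at annual resolution yields measurements
R_i +/- dR_i at ring offsets r_i counted back from the waney edge
(r = 0 is the final growth ring).  Placing the waney edge at candidate
calendar year x, the goodness of fit against an annual reference curve
C +/- dC is

    chi2(x) = sum_i (R_i - C(x - r_i))^2 / (dR_i^2 + dC(x - r_i)^2)

which is minimal at the correct placement.  A one-to-two-year atmospheric
14C rise of >= 1 percent (a Miyake / solar-energetic-particle event) in
the reference pins the match to a single year; the anchored event ring
then dates the whole cross-dated floating chronology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .calendar_units import CalendarYear
from .refcurve import ReferenceCurve

__all__ = [
    "SampleSeries",
    "MatchScan",
    "chi_squared_at",
    "chi_squared_scan",
    "detect_excursions",
    "anchor_chronology",
    "consensus_anchor",
]


@dataclass
class SampleSeries:
    """Annual 14C measurements of one wood sample, indexed by ring offset.

    offsets : ring number counted from the waney edge (0 = final ring),
        non-negative and strictly distinct.
    values, sigmas : measurements and 1-sigma errors; ``quantity`` says
        whether they are Delta-14C (per mil) or 14C ages (yr BP).
    end_relative_year : dendro position of the final measured ring on the
        floating chronology (None while unplaced).
    """

    sample_id: str
    offsets: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray
    quantity: str = "delta14c"
    waney_edge_present: bool = True
    end_relative_year: Optional[int] = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.offsets) == len(self.values) == len(self.sigmas)):
            raise ValueError("offsets, values, sigmas must have equal length")
        if np.any(self.offsets < 0):
            raise ValueError("ring offsets must be >= 0")
        if len(np.unique(self.offsets)) != len(self.offsets):
            raise ValueError("ring offsets must be strictly distinct")
        if np.any(self.sigmas <= 0):
            raise ValueError("measurement sigmas must be > 0")

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class MatchScan:
    """chi2(x) over all admissible end years x, with the 5% screening level."""

    sample_id: str
    x: np.ndarray  # candidate end years, astronomical
    chi2: np.ndarray
    n_points: int
    alpha: float = 0.05

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=int)
        self.chi2 = np.asarray(self.chi2, dtype=float)
        if len(self.x) != len(self.chi2):
            raise ValueError("x and chi2 length mismatch")
        if np.any(self.chi2 < -1e-12):
            raise ValueError("chi2 must be non-negative")

    @property
    def chi2_min(self) -> float:
        return float(self.chi2.min())

    @property
    def minimizers(self) -> np.ndarray:
        """All end years attaining the minimum (ties are not broken)."""
        return self.x[np.isclose(self.chi2, self.chi2_min, rtol=0, atol=1e-9)]

    @property
    def best_x(self) -> int:
        return int(self.minimizers[0])

    @property
    def dof(self) -> int:
        return self.n_points - 1

    @property
    def critical_value(self) -> float:
        return float(stats.chi2.ppf(1.0 - self.alpha, self.dof))

    @property
    def passes(self) -> bool:
        return self.chi2_min <= self.critical_value


def chi_squared_at(
    sample: SampleSeries,
    rc: ReferenceCurve,
    x: int,
    return_contributions: bool = False,
):
    """Evaluate chi2 with the sample's waney edge placed at year x.

    Raises KeyError when any measured ring falls outside the reference
    coverage (the placement is inadmissible, not silently zero).
    """
    years = int(x) - sample.offsets
    if years.min() < rc.first_year or years.max() > rc.last_year:
        raise KeyError(
            f"placement x={x} needs reference years "
            f"[{years.min()}, {years.max()}] outside coverage "
            f"[{rc.first_year}, {rc.last_year}]"
        )
    idx = years - rc.first_year
    c = rc.c[idx]
    dc = rc.dc[idx]
    contrib = (sample.values - c) ** 2 / (sample.sigmas**2 + dc**2)
    total = float(contrib.sum())
    if return_contributions:
        return total, contrib
    return total


def chi_squared_scan(
    sample: SampleSeries,
    rc: ReferenceCurve,
    x_range: Optional[tuple[int, int]] = None,
    alpha: float = 0.05,
) -> MatchScan:
    """chi2(x) at every admissible integer end year within coverage.

    By default the scan is global over all x for which every ring offset
    maps into the reference; ``x_range`` restricts it (both ends
    inclusive) for speed.
    """
    lo = rc.first_year + int(sample.offsets.max())
    hi = rc.last_year + int(sample.offsets.min())
    if x_range is not None:
        lo, hi = max(lo, x_range[0]), min(hi, x_range[1])
    if hi - lo + 1 < 2:
        raise ValueError("fewer than 2 admissible candidate end years")
    xs = np.arange(lo, hi + 1)
    # vectorized: years matrix (n_x, n_meas)
    years = xs[:, None] - sample.offsets[None, :]
    idx = years - rc.first_year
    c = rc.c[idx]
    dc = rc.dc[idx]
    chi2 = (((sample.values[None, :] - c) ** 2)
            / (sample.sigmas[None, :] ** 2 + dc**2)).sum(axis=1)
    return MatchScan(sample.sample_id, xs, chi2, len(sample), alpha)


def detect_excursions(
    rc: ReferenceCurve, threshold_permil: float = 10.0, window_years: int = 2
) -> list[int]:
    """Years of abrupt Delta-14C rises (>= threshold within the window).

    A year y is flagged when C(y) - C(y-k) >= threshold for any
    k in {1..window_years}; consecutive flagged years are merged into one
    event reported at the year with the largest single-year rise.
    """
    c = rc.c
    flagged = np.zeros(len(c), dtype=bool)
    for k in range(1, window_years + 1):
        flagged[k:] |= (c[k:] - c[:-k]) >= threshold_permil
    events = []
    i = 0
    step = np.empty(len(c))
    step[0] = -np.inf
    step[1:] = np.diff(c)
    while i < len(c):
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(c) and flagged[j + 1]:
            j += 1
        run = slice(i, j + 1)
        events.append(rc.first_year + i + int(np.argmax(step[run])))
        i = j + 1
    return events


def anchor_chronology(
    event_relative_year: int,
    chronology_length: int,
    event_calendar_year: CalendarYear | int,
) -> CalendarYear:
    """Calendar year of a floating chronology's final ring.

    The ring carrying the event sits at ``event_relative_year`` (1-based)
    of a chronology ``chronology_length`` rings long; the event's calendar
    year then dates the final ring at
    event_year + (length - event_relative_year) on the astronomical axis.
    """
    if not 1 <= event_relative_year <= chronology_length:
        raise ValueError(
            f"event relative year {event_relative_year} outside chronology "
            f"1..{chronology_length}"
        )
    ev = (event_calendar_year.astronomical
          if isinstance(event_calendar_year, CalendarYear)
          else int(event_calendar_year))
    return CalendarYear(ev + (chronology_length - event_relative_year))


@dataclass
class ConsensusReport:
    """Per-sample agreement between chi2 placement and dendro position."""

    residuals: dict  # sample_id -> best_x - dendro-implied end year
    implied_end_years: dict  # sample_id -> astronomical year
    excluded: list  # sample ids with no admissible scan / no dendro position
    consensus: bool
    chronology_end_year: Optional[CalendarYear] = None


def consensus_anchor(
    scans: Sequence[MatchScan],
    samples: Sequence[SampleSeries],
    event_relative_year: int,
    chronology_length: int,
    event_calendar_year: CalendarYear | int,
) -> ConsensusReport:
    """Check that every sample's chi2 placement matches its dendro position.

    Each sample's dendro-implied calendar end year follows from anchoring
    the chronology at the event; the residual is best_x minus that year.
    Consensus holds only when every scanned sample has residual 0 and a
    unique minimizer; disagreement is reported, never outvoted.
    """
    ev = (event_calendar_year.astronomical
          if isinstance(event_calendar_year, CalendarYear)
          else int(event_calendar_year))
    by_id = {s.sample_id: s for s in samples}
    residuals, implied, excluded = {}, {}, []
    for scan in scans:
        s = by_id.get(scan.sample_id)
        if s is None or s.end_relative_year is None or len(scan.x) == 0:
            excluded.append(scan.sample_id)
            continue
        implied_end = ev + (s.end_relative_year - event_relative_year)
        implied[scan.sample_id] = implied_end
        mins = scan.minimizers
        if len(mins) > 1:
            residuals[scan.sample_id] = [int(m) - implied_end for m in mins]
        else:
            residuals[scan.sample_id] = int(mins[0]) - implied_end
    consensus = bool(residuals) and all(
        r == 0 for r in residuals.values() if not isinstance(r, list)
    ) and not any(isinstance(r, list) for r in residuals.values())
    end = (anchor_chronology(event_relative_year, chronology_length, ev)
           if consensus else None)
    return ConsensusReport(residuals, implied, excluded, consensus, end)
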