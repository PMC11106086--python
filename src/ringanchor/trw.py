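"""Ring-width series, chronology building and cross-dating statistics.

Widths are stored as integers in 0.01 mm units (the measuring-table
precision), which keeps RWL round trips exact.  Cross-dating statistics
operate on dimensionless indices and are therefore invariant to the unit
and to multiplying a series by any positive constant.

Two classical t statistics are provided: the Baillie–Pilcher form (Pearson
correlation of 5-yr moving-average log-indices) and the Hollstein form
(correlation of year-to-year log growth ratios), together with the
Gleichlaeufigkeit (GLK) sign-agreement percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthSeries",
    "Chronology",
    "average_radii",
    "detrend",
    "t_value_bp",
    "t_value_hollstein",
    "glk",
    "crossdate_scan",
    "build_chronology",
    "mean_interseries_correlation",
]


@dataclass
class RingWidthSeries:
    """One sample's annual ring widths on a relative-year axis.

    widths are in 0.01 mm units and must be strictly positive.
    ``n_sapwood_rings`` is None when sapwood was not identified.
    """

    sample_id: str
    first_relative_year: int
    widths: np.ndarray
    n_sapwood_rings: Optional[int] = None
    has_waney_edge: bool = False
    has_pith: bool = False
    genus: str = ""

    def __post_init__(self):
        self.widths = np.asarray(self.widths)
        if self.widths.ndim != 1 or len(self.widths) < 1:
            raise ValueError("widths must be a non-empty 1-D sequence")
        if np.any(self.widths <= 0):
            raise ValueError("all ring widths must be strictly positive")
        if self.n_sapwood_rings is not None and self.n_sapwood_rings < 0:
            raise ValueError("n_sapwood_rings must be >= 0")

    def __len__(self) -> int:
        return len(self.widths)

    @property
    def last_relative_year(self) -> int:
        return self.first_relative_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_relative_year, self.last_relative_year + 1)


@dataclass
class Chronology:
    """Mean-index chronology with per-year replication (sample depth)."""

    first_relative_year: int
    mean_index: np.ndarray
    replication: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    avg_segment_length: float = float("nan")

    def __post_init__(self):
        self.mean_index = np.asarray(self.mean_index, dtype=float)
        self.replication = np.asarray(self.replication, dtype=int)
        if len(self.mean_index) != len(self.replication):
            raise ValueError("mean_index and replication length mismatch")
        if np.any(self.replication < 1):
            raise ValueError("replication must be >= 1 wherever the mean is defined")

    def __len__(self) -> int:
        return len(self.mean_index)

    @property
    def last_relative_year(self) -> int:
        return self.first_relative_year + len(self.mean_index) - 1

    @property
    def span(self) -> int:
        return len(self.mean_index)


def average_radii(radii: Sequence[RingWidthSeries]) -> RingWidthSeries:
    """Average 2-4 radius measurements of one sample into its series.

    All radii must share the same relative-year axis (same first year and
    length, i.e. aligned by ring count).  Metadata is merged by taking the
    maximum information across radii.
    """
    if not 1 <= len(radii) <= 4:
        raise ValueError("expected 1-4 radii per sample")
    first = radii[0]
    for r in radii[1:]:
        if r.first_relative_year != first.first_relative_year or len(r) != len(first):
            raise ValueError(
                f"radii of sample {first.sample_id!r} are not aligned: "
                f"({r.first_relative_year}, n={len(r)}) vs "
                f"({first.first_relative_year}, n={len(first)})"
            )
    stacked = np.vstack([r.widths.astype(float) for r in radii])
    mean = np.rint(stacked.mean(axis=0)).astype(int)
    sap = [r.n_sapwood_rings for r in radii if r.n_sapwood_rings is not None]
    return RingWidthSeries(
        sample_id=first.sample_id,
        first_relative_year=first.first_relative_year,
        widths=np.maximum(mean, 1),
        n_sapwood_rings=max(sap) if sap else None,
        has_waney_edge=any(r.has_waney_edge for r in radii),
        has_pith=any(r.has_pith for r in radii),
        genus=first.genus,
    )


def detrend(widths, window: int = 5) -> np.ndarray:
    """Log-index standardisation: log(100 * w_t / centered moving average).

    At the series ends the window shrinks symmetrically so that it stays
    centered.  Constant series map to a constant log(100); rescaling the
    series leaves the indices unchanged.
    """
    if isinstance(widths, RingWidthSeries):
        widths = widths.widths
    w = np.asarray(widths, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n = len(w)
    if n <= window:
        raise ValueError(f"series length {n} must exceed window {window}")
    half = window // 2
    ma = np.empty(n)
    for t in range(n):
        h = min(half, t, n - 1 - t)
        ma[t] = w[t - h : t + h + 1].mean()
    return np.log(100.0 * w / ma)


def _overlap(a_years, a_vals, b_years, b_vals, lag: int):
    """Values of a and b on their common years after shifting b by +lag."""
    b_years = b_years + lag
    lo = max(a_years[0], b_years[0])
    hi = min(a_years[-1], b_years[-1])
    if hi < lo:
        return np.empty(0), np.empty(0)
    ia = lo - a_years[0]
    ib = lo - b_years[0]
    n = hi - lo + 1
    return a_vals[ia : ia + n], b_vals[ib : ib + n]


def _t_from_r(r: float, n: int) -> float:
    if abs(r) >= 1.0 - 1e-12:
        return math.copysign(math.inf, r)
    return r * math.sqrt((n - 2) / (1.0 - r * r))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def t_value_bp(
    a: RingWidthSeries, b: RingWidthSeries, lag: int = 0, window: int = 5,
    min_overlap: int = 10,
) -> tuple[float, float, int]:
    """Baillie–Pilcher t statistic of b placed at +lag relative to b's axis.

    Returns ``(t, r, n)`` with r the Pearson correlation of the two
    detrended index series over their overlap and
    t = r * sqrt((n-2)/(1-r^2)); perfectly correlated series return an
    infinite sentinel rather than raising.
    """
    ia = detrend(a.widths, window)
    ib = detrend(b.widths, window)
    x, y = _overlap(a.years, ia, b.years, ib, lag)
    n = len(x)
    if n < min_overlap:
        raise ValueError(f"overlap {n} at lag {lag} is below minimum {min_overlap}")
    r = _pearson(x, y)
    return _t_from_r(r, n), r, n


def t_value_hollstein(
    a: RingWidthSeries, b: RingWidthSeries, lag: int = 0, min_overlap: int = 10
) -> tuple[float, float, int]:
    """Hollstein t statistic: correlation of log growth ratios log(w_{t+1}/w_t)."""
    ga = np.diff(np.log(a.widths.astype(float)))
    gb = np.diff(np.log(b.widths.astype(float)))
    x, y = _overlap(a.years[:-1], ga, b.years[:-1], gb, lag)
    n = len(x)
    if n < min_overlap:
        raise ValueError(f"overlap {n} at lag {lag} is below minimum {min_overlap}")
    r = _pearson(x, y)
    return _t_from_r(r, n), r, n


def glk(a: RingWidthSeries, b: RingWidthSeries, lag: int = 0) -> float:
    """Gleichlaeufigkeit: % agreement of year-to-year change signs.

    Per change pair: 1 if both strictly agree in sign or both are zero,
    0.5 if exactly one change is zero, else 0.
    """
    da = np.sign(np.diff(a.widths.astype(float)))
    db = np.sign(np.diff(b.widths.astype(float)))
    x, y = _overlap(a.years[:-1], da, b.years[:-1], db, lag)
    if len(x) < 1:
        raise ValueError("GLK requires an overlap of at least 2 years")
    score = np.where(
        x == y, 1.0, np.where((x == 0) | (y == 0), 0.5, 0.0)
    )
    return float(100.0 * score.mean())


def _master_as_series(master) -> RingWidthSeries:
    if isinstance(master, RingWidthSeries):
        return master
    if isinstance(master, Chronology):
        # Index back to a dimensionless width-like series so the same
        # statistics apply; exp(index) is ~100 with the common variation.
        return RingWidthSeries(
            sample_id="<master>",
            first_relative_year=master.first_relative_year,
            widths=np.exp(master.mean_index),
        )
    raise TypeError("master must be a RingWidthSeries or Chronology")


def crossdate_scan(
    series: RingWidthSeries, master, min_overlap: int = 10, window: int = 5
) -> pd.DataFrame:
    """Score every admissible lag of ``series`` against a master.

    Returns a DataFrame with columns (lag, t_bp, t_hollstein, glk, n)
    sorted by t_bp descending; no admissible lag yields an empty table.
    The lag is the shift added to the series' own year axis.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    m = _master_as_series(master)
    rows = []
    # lag range where overlap >= min_overlap
    lo = m.first_relative_year - series.last_relative_year + (min_overlap - 1)
    hi = m.last_relative_year - series.first_relative_year - (min_overlap - 1)
    for lag in range(lo, hi + 1):
        try:
            t_bp, _, n = t_value_bp(m, series, lag, window, min_overlap)
            t_h, _, _ = t_value_hollstein(m, series, lag, max(2, min_overlap - 1))
            g = glk(m, series, lag)
        except ValueError:
            continue
        rows.append({"lag": lag, "t_bp": t_bp, "t_hollstein": t_h, "glk": g, "n": n})
    df = pd.DataFrame(rows, columns=["lag", "t_bp", "t_hollstein", "glk", "n"])
    return df.sort_values("t_bp", ascending=False, kind="stable").reset_index(drop=True)


def build_chronology(
    series: Sequence[RingWidthSeries],
    lags: Optional[Sequence[int]] = None,
    window: int = 5,
) -> Chronology:
    """Average detrended indices of cross-dated series into a chronology.

    ``lags[i]`` is added to series i's year axis before averaging (default
    all zero, i.e. the series axes are already aligned).
    """
    if lags is None:
        lags = [0] * len(series)
    if len(lags) != len(series):
        raise ValueError("one lag per series required")
    firsts = [s.first_relative_year + l for s, l in zip(series, lags)]
    lasts = [s.last_relative_year + l for s, l in zip(series, lags)]
    lo, hi = min(firsts), max(lasts)
    n = hi - lo + 1
    total = np.zeros(n)
    depth = np.zeros(n, dtype=int)
    for s, l in zip(series, lags):
        idx = detrend(s.widths, window)
        i0 = s.first_relative_year + l - lo
        total[i0 : i0 + len(idx)] += idx
        depth[i0 : i0 + len(idx)] += 1
    if np.any(depth == 0):
        gap = lo + int(np.argmin(depth > 0))
        raise ValueError(f"chronology has a replication gap at relative year {gap}")
    return Chronology(
        first_relative_year=lo,
        mean_index=total / depth,
        replication=depth,
        sample_ids=[s.sample_id for s in series],
        avg_segment_length=float(np.mean([len(s) for s in series])),
    )


def mean_interseries_correlation(
    series: Sequence[RingWidthSeries],
    lags: Optional[Sequence[int]] = None,
    window: int = 5,
    min_overlap: int = 10,
) -> tuple[float, list[str]]:
    """rbar: mean correlation of each series against the mean of the others.

    Returns ``(rbar, excluded_ids)`` where excluded series had no
    sufficient overlap with the rest.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    if lags is None:
        lags = [0] * len(series)
    aligned = []
    for s, l in zip(series, lags):
        aligned.append((s.first_relative_year + l, detrend(s.widths, window)))
    lo = min(f for f, _ in aligned)
    hi = max(f + len(ix) - 1 for f, ix in aligned)
    n = hi - lo + 1
    mat = np.full((len(aligned), n), np.nan)
    for k, (f, ix) in enumerate(aligned):
        mat[k, f - lo : f - lo + len(ix)] = ix
    rs, excluded = [], []
    for k in range(len(aligned)):
        others = np.delete(mat, k, axis=0)
        counts = (~np.isnan(others)).sum(axis=0)
        sums = np.nansum(others, axis=0)
        others_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mask = ~np.isnan(mat[k]) & ~np.isnan(others_mean)
        if mask.sum() < min_overlap:
            excluded.append(series[k].sample_id)
            continue
        rs.append(_pearson(mat[k][mask], others_mean[mask]))
    if not rs:
        raise ValueError("no series has sufficient overlap with the others")
    return float(np.mean(rs)), excluded
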