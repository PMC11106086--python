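"""Annual Delta-14C reference curves and block-resolution calibration curves.

Single-year Delta-14C measurements from several labs/archives are compiled
into an annually resolved mean curve (inverse-variance weighting, with the
larger of the internal and external error as the per-year uncertainty).
IntCal-style calibration curves (".14c" five-column text) can be read,
written, interpolated to annual resolution, and locally replaced by the
annual reference ("plus" splice) around an event year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .calendar_units import (
    RadiocarbonValue,
    CalendarYear,
    bc_ad_to_calbp,
    calbp_to_astronomical,
    convert,
)

__all__ = [
    "AnnualDelta14CDataset",
    "ReferenceCurve",
    "CalibrationCurve",
    "build_annual_reference",
    "read_intcal",
    "write_intcal",
    "interpolate_annual",
    "splice_plus",
]

_DATASET_COLUMNS = ["lab", "archive", "year", "delta14c", "sigma"]


@dataclass
class AnnualDelta14CDataset:
    """Single-year Delta-14C records from one or more labs and archives.

    ``records`` columns: lab, archive, year (astronomical), delta14c (per
    mil), sigma (1-sigma, per mil).  ``archive_year_offsets`` maps an
    archive code to an integer shift applied to that archive's years
    (e.g. a +1 correction to a master chronology's dating).
    """

    records: pd.DataFrame
    archive_year_offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in _DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.records["sigma"] <= 0).any():
            raise ValueError("all record sigmas must be > 0")

    def with_offsets_applied(self) -> pd.DataFrame:
        df = self.records.copy()
        if self.archive_year_offsets:
            shift = df["archive"].map(self.archive_year_offsets).fillna(0).astype(int)
            df["year"] = df["year"].astype(int) + shift
        dup = df.duplicated(subset=["lab", "archive", "year"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["lab", "archive", "year"]].tolist()
            raise ValueError(f"duplicate record for (lab, archive, year) = {pair}")
        return df

    @classmethod
    def from_csv(cls, path, archive_year_offsets: Optional[dict] = None):
        df = pd.read_csv(path)
        df = df.rename(columns={"year_astronomical": "year"})
        return cls(df[_DATASET_COLUMNS].copy(), archive_year_offsets or {})


@dataclass
class ReferenceCurve:
    """Annually resolved Delta-14C mean curve on a gap-free year grid."""

    first_year: int  # astronomical
    c: np.ndarray  # mean Delta-14C per year (per mil)
    dc: np.ndarray  # 1-sigma per year (per mil)
    n_records: np.ndarray = None

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        self.dc = np.asarray(self.dc, dtype=float)
        if self.n_records is None:
            self.n_records = np.ones(len(self.c), dtype=int)
        self.n_records = np.asarray(self.n_records, dtype=int)
        if not (len(self.c) == len(self.dc) == len(self.n_records)):
            raise ValueError("curve arrays must have equal length")
        # dc == 0 is admitted so that noise-free truth curves from the
        # simulator can be matched against exactly.
        if np.any(self.dc < 0):
            raise ValueError("per-year sigma must be >= 0")

    def __len__(self) -> int:
        return len(self.c)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.c) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def covers(self, year: int) -> bool:
        return self.first_year <= year <= self.last_year

    def at(self, year: int) -> tuple[float, float]:
        """(mean, sigma) at an astronomical year; KeyError outside coverage."""
        if not self.covers(year):
            raise KeyError(f"year {year} outside curve coverage "
                           f"[{self.first_year}, {self.last_year}]")
        i = year - self.first_year
        return float(self.c[i]), float(self.dc[i])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"year": self.years, "delta14c": self.c, "sigma": self.dc,
             "n_records": self.n_records}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceCurve":
        df = pd.read_csv(path).sort_values("year")
        years = df["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise ValueError("reference curve CSV must be annual and gap-free")
        n = df["n_records"].to_numpy() if "n_records" in df else None
        return cls(int(years[0]), df["delta14c"].to_numpy(),
                   df["sigma"].to_numpy(), n)


def build_annual_reference(
    datasets: Union[AnnualDelta14CDataset, Sequence[AnnualDelta14CDataset]],
    coverage: Optional[tuple[int, int]] = None,
    weighted: bool = True,
    allow_gaps: bool = False,
) -> ReferenceCurve:
    """Compile per-year means from multi-lab single-year measurements.

    Per year the mean is the inverse-variance weighted mean (or the plain
    mean when ``weighted=False``) and the uncertainty is the larger of the
    internal error 1/sqrt(sum w_i) and the external error (weighted
    standard deviation of the mean).  A year with a single record carries
    that record's sigma.  Archive year offsets are applied first.
    """
    if isinstance(datasets, AnnualDelta14CDataset):
        datasets = [datasets]
    df = pd.concat([d.with_offsets_applied() for d in datasets], ignore_index=True)
    if coverage is None:
        coverage = (int(df["year"].min()), int(df["year"].max()))
    lo, hi = coverage
    years = np.arange(lo, hi + 1)
    c = np.full(len(years), np.nan)
    dc = np.full(len(years), np.nan)
    count = np.zeros(len(years), dtype=int)
    grouped = df.groupby("year")
    for year, g in grouped:
        if not lo <= year <= hi:
            continue
        i = int(year) - lo
        v = g["delta14c"].to_numpy(dtype=float)
        s = g["sigma"].to_numpy(dtype=float)
        count[i] = len(v)
        if len(v) == 1:
            c[i], dc[i] = v[0], s[0]
            continue
        w = 1.0 / s**2 if weighted else np.ones_like(s)
        mean = float(np.sum(w * v) / np.sum(w))
        internal = (1.0 / math.sqrt(np.sum(1.0 / s**2)))
        external = math.sqrt(
            float(np.sum(w * (v - mean) ** 2) / ((len(v) - 1) * np.sum(w)))
        )
        c[i], dc[i] = mean, max(internal, external)
    gaps = years[count == 0]
    if len(gaps):
        if not allow_gaps:
            raise ValueError(
                f"no records for {len(gaps)} year(s) within requested coverage, "
                f"first gap at {gaps[0]}; pass allow_gaps=True to truncate"
            )
        # keep the longest contiguous covered run containing most records
        runs = _contiguous_runs(count > 0)
        best = max(runs, key=lambda ab: count[ab[0]:ab[1]].sum())
        years, c, dc, count = (arr[best[0]:best[1]] for arr in (years, c, dc, count))
    return ReferenceCurve(int(years[0]), c, dc, count)


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


@dataclass
class CalibrationCurve:
    """IntCal-style calibration curve: knots of (cal BP, 14C age BP, sigma).

    Knots may be multi-year blocks (decadal/bidecadal); cal BP is strictly
    monotone.  Delta-14C columns are retained when present.
    """

    calbp: np.ndarray
    age: np.ndarray
    sigma: np.ndarray
    delta14c: Optional[np.ndarray] = None
    delta14c_sigma: Optional[np.ndarray] = None

    def __post_init__(self):
        self.calbp = np.asarray(self.calbp, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = np.diff(self.calbp)
        if np.any(d == 0) or (np.any(d > 0) and np.any(d < 0)):
            bad = int(np.argmin(d > 0) if d[0] > 0 else np.argmin(d < 0)) + 1
            raise ValueError(f"cal BP not strictly monotone at row {bad}")
        # sigma == 0 is admitted for exact synthetic curves.
        if np.any(self.sigma < 0):
            raise ValueError("age sigma must be >= 0")

    def __len__(self) -> int:
        return len(self.calbp)

    def sorted_ascending(self) -> "CalibrationCurve":
        if len(self.calbp) < 2 or self.calbp[1] > self.calbp[0]:
            return self
        sl = slice(None, None, -1)
        return CalibrationCurve(
            self.calbp[sl], self.age[sl], self.sigma[sl],
            None if self.delta14c is None else self.delta14c[sl],
            None if self.delta14c_sigma is None else self.delta14c_sigma[sl],
        )


def read_intcal(path_or_file: Union[str, TextIO]) -> CalibrationCurve:
    """Read an IntCal ``.14c`` 5-column file (cal BP, age, sigma, D14C, sigma).

    Lines starting with '#' are headers; fields are comma- or
    whitespace-separated.
    """
    close = False
    if isinstance(path_or_file, str):
        fh = open(path_or_file)
        close = True
    else:
        fh = path_or_file
    rows = []
    try:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"line {ln}: expected >= 3 columns, got {len(parts)}")
            rows.append([float(p) for p in parts[:5]])
    finally:
        if close:
            fh.close()
    arr = np.array([r + [np.nan] * (5 - len(r)) for r in rows])
    return CalibrationCurve(
        arr[:, 0], arr[:, 1], arr[:, 2],
        arr[:, 3] if arr.shape[1] > 3 else None,
        arr[:, 4] if arr.shape[1] > 4 else None,
    )


def write_intcal(curve: CalibrationCurve, path_or_file: Union[str, TextIO]) -> None:
    """Write the 5-column ``.14c`` text format (comma separated)."""
    close = False
    if isinstance(path_or_file, str):
        fh = open(path_or_file, "w")
        close = True
    else:
        fh = path_or_file
    try:
        fh.write("# CAL BP, 14C age, Sigma, Delta 14C, Sigma\n")
        d = curve.delta14c
        ds = curve.delta14c_sigma
        for i in range(len(curve)):
            dd = "" if d is None or np.isnan(d[i]) else f"{d[i]:.2f}"
            dds = "" if ds is None or np.isnan(ds[i]) else f"{ds[i]:.2f}"
            fh.write(f"{curve.calbp[i]:.1f},{curve.age[i]:.2f},"
                     f"{curve.sigma[i]:.2f},{dd},{dds}\n")
    finally:
        if close:
            fh.close()


def interpolate_annual(
    curve: CalibrationCurve, span: Optional[tuple[int, int]] = None
) -> CalibrationCurve:
    """Linear interpolation of mean and sigma onto an annual cal BP grid.

    ``span`` is (calbp_lo, calbp_hi) inclusive; it must lie within knot
    coverage (extrapolation refused).  Exact at knots.
    """
    c = curve.sorted_ascending()
    lo_cov, hi_cov = c.calbp[0], c.calbp[-1]
    if span is None:
        span = (int(math.ceil(lo_cov)), int(math.floor(hi_cov)))
    lo, hi = span
    if lo < lo_cov or hi > hi_cov:
        raise ValueError(
            f"span [{lo}, {hi}] extends outside knot coverage [{lo_cov}, {hi_cov}]"
        )
    grid = np.arange(lo, hi + 1, dtype=float)
    age = np.interp(grid, c.calbp, c.age)
    sig = np.interp(grid, c.calbp, c.sigma)
    d = ds = None
    if c.delta14c is not None and not np.any(np.isnan(c.delta14c)):
        d = np.interp(grid, c.calbp, c.delta14c)
        if c.delta14c_sigma is not None and not np.any(np.isnan(c.delta14c_sigma)):
            ds = np.interp(grid, c.calbp, c.delta14c_sigma)
    return CalibrationCurve(grid, age, sig, d, ds)


def splice_plus(
    base: CalibrationCurve,
    annual: ReferenceCurve,
    center_year: Optional[int] = None,
    width: int = 82,
    window: Optional[tuple[int, int]] = None,
) -> CalibrationCurve:
    """Replace base-curve knots around an event by annual reference knots.

    The window is given either explicitly as astronomical years
    ``(year_lo, year_hi)`` inclusive, or as ``center_year`` plus a total
    ``width`` in years (default 82, centred).  Base knots whose cal BP
    falls inside the window are dropped and annual Delta-14C values,
    converted to 14C age BP, are inserted as annual knots; outside the
    window the base curve is untouched.  Idempotent for a fixed window.
    """
    if window is None:
        if center_year is None:
            raise ValueError("give either window=(lo, hi) or center_year")
        half = width // 2
        window = (center_year - half, center_year + (width - 1 - half))
    ylo, yhi = window
    if yhi < ylo:
        return base.sorted_ascending()
    if not (annual.covers(ylo) and annual.covers(yhi)):
        raise ValueError(
            f"annual reference [{annual.first_year}, {annual.last_year}] does not "
            f"cover the splice window [{ylo}, {yhi}]"
        )
    c = base.sorted_ascending()
    bp_hi = bc_ad_to_calbp(ylo)  # earlier year -> larger cal BP
    bp_lo = bc_ad_to_calbp(yhi)
    keep = (c.calbp < bp_lo) | (c.calbp > bp_hi)
    years = np.arange(ylo, yhi + 1)
    new_bp, new_age, new_sig = [], [], []
    for y in years:
        mean, sd = annual.at(int(y))
        rv = convert(
            RadiocarbonValue("delta14c", mean, sd, CalendarYear(int(y))), "age_bp"
        )
        new_bp.append(float(bc_ad_to_calbp(int(y))))
        new_age.append(rv.value)
        new_sig.append(rv.sigma)
    calbp = np.concatenate([c.calbp[keep], new_bp])
    age = np.concatenate([c.age[keep], new_age])
    sig = np.concatenate([c.sigma[keep], new_sig])
    order = np.argsort(calbp)
    return CalibrationCurve(calbp[order], age[order], sig[order])
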