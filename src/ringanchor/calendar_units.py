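"""Calendar-axis arithmetic and radiocarbon unit conversions.

Calendar years are kept on the astronomical axis internally (0 = 1 BC,
negative = earlier BC); the historical BC/AD labelling, which has no year
zero, appears only at the I/O boundary.  Radiocarbon quantities are
interconverted among fraction modern (F14C), conventional radiocarbon age
(years BP, Libby mean life 8033 yr) and the decay-corrected atmospheric
deviation Delta-14C (per mil, true mean life 8267 yr), with first-order
(delta-method) error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "LIBBY_MEAN_LIFE",
    "TRUE_MEAN_LIFE",
    "REFERENCE_YEAR",
    "CalendarYear",
    "RadiocarbonValue",
    "bc_ad_to_calbp",
    "calbp_to_astronomical",
    "convert",
    "apply_age_offset",
    "delta14c_shift_for_age_offset",
]

#: Libby mean life (yr) used for conventional radiocarbon ages.
LIBBY_MEAN_LIFE = 8033.0
#: True mean life (yr) used for the Delta-14C decay correction.
TRUE_MEAN_LIFE = 8267.0
#: Calendar reference year for "before present".
REFERENCE_YEAR = 1950

_QUANTITIES = ("F14C", "age_bp", "delta14c")


@dataclass(frozen=True, order=True)
class CalendarYear:
    """A calendar year on the astronomical axis (0 = 1 BC, -1 = 2 BC, ...)."""

    astronomical: int

    @classmethod
    def from_bc_ad(cls, year: int, era: str) -> "CalendarYear":
        """Build from a historical label, e.g. ``from_bc_ad(5259, "BC")``.

        The historical calendar has no year 0, so ``year`` must be >= 1.
        """
        era = era.upper()
        if era not in ("BC", "AD"):
            raise ValueError(f"era must be 'BC' or 'AD', got {era!r}")
        if year < 1:
            raise ValueError(
                f"historical year must be >= 1 (there is no year 0 in the "
                f"BC/AD calendar); got {year} {era}"
            )
        return cls(-(year - 1) if era == "BC" else year)

    def to_bc_ad(self) -> tuple[int, str]:
        """Return ``(year, era)``; never emits a year 0."""
        if self.astronomical <= 0:
            return (1 - self.astronomical, "BC")
        return (self.astronomical, "AD")

    def __str__(self) -> str:
        year, era = self.to_bc_ad()
        return f"{year} {era}"


def _as_astronomical(year) -> int:
    if isinstance(year, CalendarYear):
        return year.astronomical
    return int(year)


def bc_ad_to_calbp(year: CalendarYear | int) -> int:
    """Calendar year -> cal BP (years before AD 1950)."""
    return REFERENCE_YEAR - _as_astronomical(year)


def calbp_to_astronomical(calbp: int) -> int:
    """Inverse of :func:`bc_ad_to_calbp`."""
    return REFERENCE_YEAR - int(calbp)


@dataclass(frozen=True)
class RadiocarbonValue:
    """One radiocarbon measurement in one of three equivalent representations.

    quantity : {"F14C", "age_bp", "delta14c"}
    value, sigma : measurement and its 1-sigma uncertainty, same units
        (dimensionless fraction, 14C yr BP, or per mil respectively).
    cal_year : calendar year of growth; required whenever delta14c is the
        source or target of a conversion (the decay correction depends on it).
    """

    quantity: str
    value: float
    sigma: float = 0.0
    cal_year: Optional[CalendarYear] = None

    def __post_init__(self):
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}; expected one of {_QUANTITIES}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.quantity == "F14C" and self.value <= 0:
            raise ValueError("F14C must be strictly positive")


def _f14c_of(v: RadiocarbonValue) -> tuple[float, float]:
    """Convert any representation to (F14C, sigma_F14C)."""
    if v.quantity == "F14C":
        return v.value, v.sigma
    if v.quantity == "age_bp":
        f = math.exp(-v.value / LIBBY_MEAN_LIFE)
        return f, f * v.sigma / LIBBY_MEAN_LIFE
    # delta14c: F = (d/1000 + 1) / exp((1950 - t)/true_mean_life)
    t = _require_year(v)
    decay = math.exp((REFERENCE_YEAR - t) / TRUE_MEAN_LIFE)
    f = (v.value / 1000.0 + 1.0) / decay
    if f <= 0:
        raise ValueError(f"delta14c = {v.value} per mil implies non-positive F14C")
    return f, (v.sigma / 1000.0) / decay


def _require_year(v: RadiocarbonValue) -> int:
    if v.cal_year is None:
        raise ValueError("cal_year is required to convert to/from delta14c")
    return _as_astronomical(v.cal_year)


def convert(value: RadiocarbonValue, target: str) -> RadiocarbonValue:
    """Convert among F14C, age_bp and delta14c with delta-method errors.

    Round trips are identity to better than 1e-9 relative.
    """
    if target not in _QUANTITIES:
        raise ValueError(f"unknown target quantity {target!r}")
    if target == value.quantity:
        return value
    f, sf = _f14c_of(value)
    if target == "F14C":
        return RadiocarbonValue("F14C", f, sf, value.cal_year)
    if target == "age_bp":
        age = -LIBBY_MEAN_LIFE * math.log(f)
        return RadiocarbonValue("age_bp", age, LIBBY_MEAN_LIFE * sf / f, value.cal_year)
    t = _require_year(value)
    decay = math.exp((REFERENCE_YEAR - t) / TRUE_MEAN_LIFE)
    d = (f * decay - 1.0) * 1000.0
    return RadiocarbonValue("delta14c", d, 1000.0 * sf * decay, value.cal_year)


def apply_age_offset(
    value: RadiocarbonValue, offset_years: float, offset_sigma: float = 0.0
) -> RadiocarbonValue:
    """Remove a constant radiocarbon-age bias (e.g. a bad standard batch).

    A measured bias of ``+offset_years`` 14C yr is subtracted from the age;
    its uncertainty combines in quadrature.  The result is returned in the
    input's representation.
    """
    age = convert(value, "age_bp")
    corrected = RadiocarbonValue(
        "age_bp",
        age.value - offset_years,
        math.hypot(age.sigma, offset_sigma),
        age.cal_year,
    )
    return convert(corrected, value.quantity)


def delta14c_shift_for_age_offset(
    offset_years: float,
    cal_year: CalendarYear | int,
    ambient_delta14c: float,
) -> float:
    """Delta-14C shift (per mil) produced by removing a +offset 14C-age bias.

    The shift depends on the ambient Delta-14C level at ``cal_year``: a
    +30.9 yr bias removed from mid-6th-millennium BC samples (ambient
    ~+90 per mil) shifts Delta-14C by about +4 per mil.
    """
    biased = RadiocarbonValue(
        "delta14c", ambient_delta14c, 0.0, _coerce_year(cal_year)
    )
    return convert(apply_age_offset(biased, offset_years), "delta14c").value - ambient_delta14c


def _coerce_year(year) -> CalendarYear:
    return year if isinstance(year, CalendarYear) else CalendarYear(int(year))
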