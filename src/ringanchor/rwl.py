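"""Tucson (decadal RWL) ring-width file reader and writer.

Each data line carries an 8-character sample id, the year of the first
value on the line, and up to ten width values; the first line of a series
runs from its first year to the end of that decade, later lines cover full
decades.  Two dialects are supported and auto-detected on read via the
end-of-series terminator: 999 (widths in 0.01 mm) and -9999 (widths in
0.001 mm).  Widths are returned in 0.01 mm units regardless of dialect.
"""

from __future__ import annotations

from typing import Iterable, TextIO, Union

from .trw import RingWidthSeries

__all__ = ["read_rwl", "write_rwl"]

_TERMINATORS = {"999": 100.0, "-9999": 1000.0}  # terminator -> units per mm


def _decade_chunks(first_year: int, n: int) -> list[tuple[int, int, int]]:
    """(line start year, start index, count) triples covering n years."""
    chunks = []
    year = first_year
    i = 0
    while i < n:
        end_of_decade = (year // 10) * 10 + 9
        count = min(end_of_decade - year + 1, n - i)
        chunks.append((year, i, count))
        year += count
        i += count
    return chunks


def write_rwl(
    series: Iterable[RingWidthSeries],
    path_or_file: Union[str, TextIO],
    dialect: str = "0.01mm",
) -> None:
    """Write series in Tucson decadal format.

    dialect "0.01mm" uses terminator 999, "0.001mm" uses -9999.
    """
    if dialect == "0.01mm":
        scale, terminator = 1.0, "999"
    elif dialect == "0.001mm":
        scale, terminator = 10.0, "-9999"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    close = False
    if isinstance(path_or_file, str):
        fh = open(path_or_file, "w")
        close = True
    else:
        fh = path_or_file
    try:
        for s in series:
            sid = s.sample_id[:8]
            values = [int(round(float(w) * scale)) for w in s.widths]
            chunks = _decade_chunks(s.first_relative_year, len(values))
            for ci, (year, i, count) in enumerate(chunks):
                vals = values[i : i + count]
                if ci == len(chunks) - 1:
                    vals = vals + [int(terminator)]
                fh.write(
                    f"{sid:<8s}{year:>4d}" + "".join(f"{v:>6d}" for v in vals) + "\n"
                )
    finally:
        if close:
            fh.close()


def read_rwl(path_or_file: Union[str, TextIO]) -> list[RingWidthSeries]:
    """Read a Tucson decadal RWL file; dialect auto-detected per series."""
    close = False
    if isinstance(path_or_file, str):
        fh = open(path_or_file)
        close = True
    else:
        fh = path_or_file
    try:
        raw: dict[str, list[tuple[int, list[str]]]] = {}
        order: list[str] = []
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                continue
            try:
                year = int(rest[0])
            except ValueError:
                continue  # header line
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((year, rest[1:]))
    finally:
        if close:
            fh.close()

    out = []
    for sid in order:
        lines = sorted(raw[sid], key=lambda t: t[0])
        first_year = lines[0][0]
        tokens: list[str] = []
        for _, vals in lines:
            tokens.extend(vals)
        units_per_mm = None
        for term, upm in _TERMINATORS.items():
            if tokens and tokens[-1] == term:
                units_per_mm = upm
                tokens = tokens[:-1]
                break
        if units_per_mm is None:
            raise ValueError(
                f"series {sid!r}: missing end-of-series terminator (999 or -9999)"
            )
        widths = [float(t) * 100.0 / units_per_mm for t in tokens]
        if units_per_mm == 100.0:
            widths = [int(round(w)) for w in widths]
        out.append(
            RingWidthSeries(sample_id=sid, first_relative_year=first_year, widths=widths)
        )
    return out
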