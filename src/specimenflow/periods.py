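"""Temporal binning of collection years into analysis periods."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Period:
    label: str
    start_year: int
    end_year: int  # inclusive
    midpoint: float

    def __contains__(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass(frozen=True)
class PeriodSpec:
    """Ordered, contiguous, non-overlapping set of year bins.

    Each in-range year maps to exactly one period; years outside
    ``[year_min, year_max]`` map to none.
    """

    periods: tuple[Period, ...]

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("PeriodSpec requires at least one period")
        prev_end = None
        for p in self.periods:
            if p.start_year > p.end_year:
                raise ValueError(f"period {p.label!r}: start after end")
            if prev_end is not None and p.start_year != prev_end + 1:
                raise ValueError(
                    f"periods must be contiguous and ascending; gap/overlap before {p.label!r}"
                )
            prev_end = p.end_year

    @property
    def year_min(self) -> int:
        return self.periods[0].start_year

    @property
    def year_max(self) -> int:
        return self.periods[-1].end_year

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.periods]

    @property
    def midpoints(self) -> list[float]:
        return [p.midpoint for p in self.periods]

    def assign(self, year: int) -> str:
        """Return the label of the period containing ``year``."""
        for p in self.periods:
            if year in p:
                return p.label
        raise ValueError(f"year {year} outside configured range "
                         f"[{self.year_min}, {self.year_max}]")

    def midpoint_of(self, label: str) -> float:
        for p in self.periods:
            if p.label == label:
                return p.midpoint
        raise KeyError(label)


def _mk(start: int, end: int, midpoint: float | None = None) -> Period:
    mid = midpoint if midpoint is not None else (start + end) / 2.0
    return Period(f"{start}-{end}", start, end, mid)


def default_periods() -> PeriodSpec:
    """Four ~30-year bins, 1900-2020, with fixed regression midpoints."""
    return PeriodSpec((
        _mk(1900, 1929, 1915.0),
        _mk(1930, 1959, 1945.0),
        _mk(1960, 1989, 1975.0),
        _mk(1990, 2020, 2005.0),
    ))


def decadal_periods() -> PeriodSpec:
    """Decadal bins, 1900-2020 (last bin includes 2020)."""
    bins = [_mk(y, y + 9) for y in range(1900, 2010, 10)]
    bins.append(_mk(2010, 2020))
    return PeriodSpec(tuple(bins))


def forty_year_periods() -> PeriodSpec:
    """Three ~40-year bins covering 1900-2020."""
    return PeriodSpec((
        _mk(1900, 1939),
        _mk(1940, 1979),
        _mk(1980, 2020),
    ))


PERIOD_PRESETS = {
    "default": default_periods,
    "decadal": decadal_periods,
    "forty_year": forty_year_periods,
}
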