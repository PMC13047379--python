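"""Occurrence-table parsing, record filtering and country standardisation.

Filtering applies a fixed, ordered rule list; each row is removed by the
FIRST rule it fails, so removal attribution in the audit log is
deterministic and rule counts are exactly reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .periods import PeriodSpec, default_periods

#: sentinel returned by resolution helpers when a value cannot be resolved
UNRESOLVED = "__UNRESOLVED__"

#: removal rules in application order (first failing rule wins)
FILTER_RULES = (
    "basis_of_record",
    "missing_origin",
    "unresolved_holding",
    "out_of_range_year",
    "missing_year",
    "absent_status",
    "zero_count",
    "invalid_country",
)

DEFAULT_COLUMN_MAPPING = {
    "family": "family",
    "basis_of_record": "basisOfRecord",
    "country": "country",
    "country_code": "countryCode",
    "institution_code": "institutionCode",
    "owner_institution_code": "ownerInstitutionCode",
    "year": "year",
    "event_date": "eventDate",
    "individual_count": "individualCount",
    "occurrence_status": "occurrenceStatus",
}

_ACCEPTED_BASES = {"preservedspecimen", "preserved_specimen"}
_YEAR_RE = re.compile(r"\b(1[0-9]{3}|2[0-9]{3})\b")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One cleaned preserved-specimen record."""

    family: str
    origin_country: str
    holding_country: str
    year: int
    count: int
    source_row: int


@dataclass
class FilterLog:
    """Per-rule removal accounting; conserves every input row."""

    removed: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_RULES})
    input_total: int = 0
    output_total: int = 0

    def check(self) -> bool:
        return self.input_total == self.output_total + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"input_total": self.input_total,
                "output_total": self.output_total,
                "removed": dict(self.removed)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class CountryLookup:
    """Exact-match (case-insensitive, trimmed) name/code → ISO3 resolution.

    Built from a 2/3-column table: raw_value, iso3[, kind].  The ``kind``
    column distinguishes name rows, code rows and the manual-override
    section (historical entities etc.); all are resolved the same way, the
    override section simply documents curation intent.
    """

    def __init__(self, table: pd.DataFrame):
        if not {"raw_value", "iso3"}.issubset(table.columns):
            raise ValueError("lookup table needs raw_value and iso3 columns")
        self._map: dict[str, str] = {}
        self.valid_codes: set[str] = set()
        for row in table.itertuples(index=False):
            raw = str(row.raw_value).strip().lower()
            code = str(row.iso3).strip().upper()
            self._map[raw] = code
            self.valid_codes.add(code)

    @classmethod
    def from_csv(cls, path) -> "CountryLookup":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def resolve(self, raw: str) -> str:
        key = str(raw).strip().lower()
        if not key:
            return UNRESOLVED
        return self._map.get(key, UNRESOLVED)


class Registry:
    """Institution-code → holding-country registry (GRSciColl stand-in)."""

    def __init__(self, table: pd.DataFrame):
        if not {"institution_code", "country_iso3"}.issubset(table.columns):
            raise ValueError(
                "registry needs institution_code and country_iso3 columns")
        self._map = {
            str(r.institution_code).strip().upper(): str(r.country_iso3).strip().upper()
            for r in table.itertuples(index=False)
        }

    @classmethod
    def from_csv(cls, path) -> "Registry":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def resolve(self, institution_code: str) -> str:
        key = str(institution_code).strip().upper()
        if not key:
            return UNRESOLVED
        return self._map.get(key, UNRESOLVED)


def standardize_country(raw: str, lookup: CountryLookup) -> str:
    """ISO3 code for a raw country name/code, or UNRESOLVED (never a guess)."""
    return lookup.resolve(raw)


def resolve_holding_country(institution_code: str, owner_institution_code: str,
                            registry: Registry) -> str:
    """Holding country with ownerInstitutionCode precedence when resolvable."""
    owner = registry.resolve(owner_institution_code)
    if owner != UNRESOLVED:
        return owner
    return registry.resolve(institution_code)


def assign_period(year: int, period_spec: PeriodSpec | None = None) -> str:
    spec = period_spec or default_periods()
    return spec.assign(year)


def parse_occurrences(path_or_stream, column_mapping: dict | None = None,
                      delimiter: str | None = None) -> pd.DataFrame:
    """Read a raw occurrence table; no filtering, all fields kept as strings.

    Raises if any mapped column is absent from the header, naming the
    missing column.  Extra columns are carried through untouched.
    """
    mapping = dict(DEFAULT_COLUMN_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    kwargs = {"dtype": str, "keep_default_na": False}
    if delimiter is not None:
        kwargs["sep"] = delimiter
    else:
        kwargs["sep"] = None
        kwargs["engine"] = "python"
    df = pd.read_csv(path_or_stream, **kwargs)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_year(year_field: str, event_date: str) -> int | None:
    """Explicit year column wins; eventDate is a fallback only."""
    y = year_field.strip()
    if y:
        try:
            return int(float(y))
        except ValueError:
            return None
    m = _YEAR_RE.search(event_date)
    if m:
        return int(m.group(0))
    return None


def filter_records(raw: pd.DataFrame, registry: Registry,
                   lookup: CountryLookup,
                   period_spec: PeriodSpec | None = None,
                   column_mapping: dict | None = None,
                   ) -> tuple[list[OccurrenceRecord], FilterLog]:
    """Apply the ordered filter rules; every input row is accounted for.

    Surviving records satisfy all OccurrenceRecord invariants: valid ISO3
    origin and holding, year within the period range, count >= 1 (missing
    or non-numeric individualCount treated as a single specimen).
    """
    spec = period_spec or default_periods()
    mapping = dict(DEFAULT_COLUMN_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    col = {k: raw[v] for k, v in mapping.items() if v in raw.columns}
    missing_cols = [v for v in mapping.values() if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {', '.join(missing_cols)}")

    log = FilterLog(input_total=len(raw))
    out: list[OccurrenceRecord] = []

    for i in range(len(raw)):
        basis = str(col["basis_of_record"].iat[i]).strip().lower()
        if basis.replace("_", "") not in {b.replace("_", "") for b in _ACCEPTED_BASES}:
            log.removed["basis_of_record"] += 1
            continue

        country = str(col["country"].iat[i]).strip()
        country_code = str(col["country_code"].iat[i]).strip()
        origin_raw = country_code or country
        if not origin_raw:
            log.removed["missing_origin"] += 1
            continue

        holding = resolve_holding_country(
            str(col["institution_code"].iat[i]),
            str(col["owner_institution_code"].iat[i]), registry)
        if holding == UNRESOLVED:
            log.removed["unresolved_holding"] += 1
            continue

        year = _parse_year(str(col["year"].iat[i]),
                           str(col["event_date"].iat[i]))
        if year is not None and not (spec.year_min <= year <= spec.year_max):
            log.removed["out_of_range_year"] += 1
            continue
        if year is None:
            log.removed["missing_year"] += 1
            continue

        status = str(col["occurrence_status"].iat[i]).strip().lower()
        if status != "present":
            log.removed["absent_status"] += 1
            continue

        count_raw = str(col["individual_count"].iat[i]).strip()
        try:
            count = int(float(count_raw)) if count_raw else 1
        except ValueError:
            count = 1  # non-numeric counts treated as single specimens
        if count < 1:
            log.removed["zero_count"] += 1
            continue

        origin = standardize_country(origin_raw, lookup)
        if origin == UNRESOLVED:
            log.removed["invalid_country"] += 1
            continue

        out.append(OccurrenceRecord(
            family=str(col["family"].iat[i]).strip(),
            origin_country=origin, holding_country=holding,
            year=year, count=count, source_row=i))

    log.output_total = len(out)
    assert log.check()
    return out, log


def records_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family, r.origin_country, r.holding_country, r.year, r.count,
          r.source_row) for r in records],
        columns=["family", "origin_country", "holding_country", "year",
                 "count", "source_row"])


def records_from_frame(df: pd.DataFrame) -> list[OccurrenceRecord]:
    return [OccurrenceRecord(str(r.family), str(r.origin_country),
                             str(r.holding_country), int(r.year),
                             int(r.count), int(r.source_row))
            for r in df.itertuples(index=False)]
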