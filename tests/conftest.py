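import pandas as pd
import pytest

from specimenflow.ingest import (CountryLookup, OccurrenceRecord, Registry)

RAW_COLUMNS = ["family", "basisOfRecord", "country", "countryCode",
               "institutionCode", "ownerInstitutionCode", "year", "eventDate",
               "individualCount", "occurrenceStatus"]


def _row(**kw):
    base = {"family": "Canidae", "basisOfRecord": "PreservedSpecimen",
            "country": "Kenya", "countryCode": "KEN",
            "institutionCode": "AMNH", "ownerInstitutionCode": "",
            "year": "1950", "eventDate": "", "individualCount": "2",
            "occurrenceStatus": "present"}
    base.update(kw)
    return base


@pytest.fixture
def toy_registry():
    return Registry(pd.DataFrame([
        {"institution_code": "AMNH", "country_iso3": "USA"},
        {"institution_code": "NHMO", "country_iso3": "NOR"},
    ]))


@pytest.fixture
def toy_lookup():
    return CountryLookup(pd.DataFrame([
        {"raw_value": "Kenya", "iso3": "KEN", "kind": "name"},
        {"raw_value": "KEN", "iso3": "KEN", "kind": "code"},
        {"raw_value": "Norway", "iso3": "NOR", "kind": "name"},
        {"raw_value": "NOR", "iso3": "NOR", "kind": "code"},
        {"raw_value": "United States", "iso3": "USA", "kind": "name"},
        {"raw_value": "USA", "iso3": "USA", "kind": "code"},
        {"raw_value": "Zaire", "iso3": "COD", "kind": "override"},
    ]))


@pytest.fixture
def defect_table():
    """One row per filter rule (in rule order) plus one clean survivor."""
    rows = [
        _row(),                                     # clean
        _row(basisOfRecord="FossilSpecimen"),       # basis_of_record
        _row(country="", countryCode=""),           # missing_origin
        _row(institutionCode="XYZ"),                # unresolved_holding
        _row(year="1899"),                          # out_of_range_year
        _row(year="", eventDate=""),                # missing_year
        _row(occurrenceStatus="absent"),            # absent_status
        _row(individualCount="0"),                  # zero_count
        _row(country="Congo?", countryCode=""),     # invalid_country
    ]
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def _rec(origin, holding, count, family="Felidae", year=1950, row=0):
    return OccurrenceRecord(family=family, origin_country=origin,
                            holding_country=holding, year=year, count=count,
                            source_row=row)


@pytest.fixture
def six_record_slice():
    """Hand-traceable slice: see tests for the expected aggregation."""
    return [
        _rec("KEN", "USA", 1, row=0),
        _rec("KEN", "USA", 2, row=1),
        _rec("USA", "USA", 5, row=2),
        _rec("BRA", "USA", 4, row=3),
        _rec("USA", "KEN", 6, row=4),
        _rec("BRA", "NOR", 7, row=5),
    ]


@pytest.fixture
def make_record():
    return _rec
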