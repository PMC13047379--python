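"""Synthetic occurrence-table generator with controlled statistical structure.

Produces GBIF-like delimited tables (Darwin-Core-style columns), an
institution registry and a country-name lookup, so the whole downstream
pipeline is testable without any external download.

Structure knobs
---------------
* ``concentration_alpha`` — symmetric Dirichlet parameter over holding-country
  shares; small alpha → concentrated holdings (high Gini), large → even.
* ``reciprocity_target`` — probability that a realised country pair is made
  bidirectional.  Implemented with common random numbers per pair, so the
  measured reciprocity is monotone in the target for a fixed seed, exactly 0
  at target 0 and exactly 1 at target 1 when origin and holding pools
  coincide (pairs whose origin has no institutions can never be mutual and
  are reported via ``attrs['ineligible_pairs']``).
* ``domestic_fraction`` — share of records collected and held in the same
  country (self-loops).
* ``contamination_rates`` — per-defect injection rates; defects are mutually
  exclusive per row so downstream filter-log counts are exactly predictable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._countrydata import ISO3_CODES, ISO3_NAMES
from .inequality import gini
from .periods import PeriodSpec, default_periods

DEFECT_KINDS = (
    "missing_year",
    "pre_1900_year",
    "invalid_country_code",
    "missing_origin",
    "missing_institution",
    "zero_count",
    "non_specimen_basis",
    "absent_status",
)

OCCURRENCE_COLUMNS = [
    "family",
    "basisOfRecord",
    "country",
    "countryCode",
    "institutionCode",
    "ownerInstitutionCode",
    "year",
    "eventDate",
    "individualCount",
    "occurrenceStatus",
]

_NON_SPECIMEN_BASES = ("HumanObservation", "FossilSpecimen", "LivingSpecimen")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset.

    Country pools are drawn deterministically from the built-in ISO3 table:
    holding countries are a subset of origin countries (set
    ``n_origin_countries == n_holding_countries`` to make the pools equal).
    """

    n_origin_countries: int = 40
    n_holding_countries: int = 12
    n_records: int = 5000
    concentration_alpha: float = 0.5
    reciprocity_target: float = 0.05
    domestic_fraction: float = 0.2
    period_weights: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    contamination_rates: dict[str, float] = field(default_factory=dict)
    families: tuple[str, ...] = ("Canidae", "Felidae", "Mustelidae")
    seed: int = 0
    period_spec: PeriodSpec = field(default_factory=default_periods)

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not (1 <= self.n_holding_countries <= self.n_origin_countries):
            raise ValueError(
                "need 1 <= n_holding_countries <= n_origin_countries")
        if self.n_origin_countries > len(ISO3_CODES):
            raise ValueError(
                f"n_origin_countries exceeds built-in pool ({len(ISO3_CODES)})")
        if self.concentration_alpha <= 0:
            raise ValueError("concentration_alpha must be positive")
        if not (0.0 <= self.reciprocity_target <= 1.0):
            raise ValueError("reciprocity_target must be in [0, 1]")
        if not (0.0 <= self.domestic_fraction <= 1.0):
            raise ValueError("domestic_fraction must be in [0, 1]")
        if len(self.period_weights) != len(self.period_spec.periods):
            raise ValueError("period_weights length must match period count")
        if any(w < 0 for w in self.period_weights):
            raise ValueError("period_weights must be nonnegative")
        if abs(sum(self.period_weights) - 1.0) > 1e-9:
            raise ValueError("period_weights must sum to 1")
        unknown = set(self.contamination_rates) - set(DEFECT_KINDS)
        if unknown:
            raise ValueError(f"unknown contamination classes: {sorted(unknown)}")
        if any(not (0.0 <= r <= 1.0) for r in self.contamination_rates.values()):
            raise ValueError("contamination rates must be in [0, 1]")
        if sum(self.contamination_rates.values()) > 1.0 + 1e-12:
            raise ValueError("contamination rates must sum to <= 1")
        if not self.families:
            raise ValueError("at least one family required")

    # Pool selection is a pure function of the seed so that registry and
    # occurrence generation stay consistent without passing pools around.
    def holding_countries(self) -> list[str]:
        rng = np.random.default_rng(self.seed)
        picked = rng.choice(len(ISO3_CODES), size=self.n_origin_countries,
                            replace=False)
        origin = sorted(ISO3_CODES[i] for i in picked)
        return origin[: self.n_holding_countries]

    def origin_countries(self) -> list[str]:
        rng = np.random.default_rng(self.seed)
        picked = rng.choice(len(ISO3_CODES), size=self.n_origin_countries,
                            replace=False)
        return sorted(ISO3_CODES[i] for i in picked)


def generate_registry(n_institutions: int, holding_countries: list[str],
                      seed: int) -> pd.DataFrame:
    """Institution-code → country registry (GRSciColl stand-in).

    Every holding country receives at least one institution; remaining
    institutions are assigned uniformly at random.
    """
    if not holding_countries:
        raise ValueError("holding_countries must be non-empty")
    if n_institutions < len(holding_countries):
        raise ValueError("need n_institutions >= len(holding_countries)")
    bad = [c for c in holding_countries if c not in ISO3_NAMES]
    if bad:
        raise ValueError(f"not valid ISO3 codes: {bad}")
    rng = np.random.default_rng(seed)
    countries = list(holding_countries)
    extra = rng.choice(len(countries),
                       size=n_institutions - len(countries)).tolist()
    assigned = countries + [countries[i] for i in extra]
    rows = [
        {"institution_code": f"INST{i:04d}{c}", "country_iso3": c}
        for i, c in enumerate(assigned)
    ]
    return pd.DataFrame(rows, columns=["institution_code", "country_iso3"])


def generate_lookup(countries: list[str]) -> pd.DataFrame:
    """Country lookup: name→code and code→code rows plus manual overrides."""
    rows = []
    for c in sorted(countries):
        rows.append({"raw_value": ISO3_NAMES[c], "iso3": c, "kind": "name"})
        rows.append({"raw_value": c, "iso3": c, "kind": "code"})
    overrides = [("Zaire", "COD"), ("Congo-Brazzaville", "COG"),
                 ("USSR", "RUS")]
    for raw, code in overrides:
        if code in countries:
            rows.append({"raw_value": raw, "iso3": code, "kind": "override"})
    return pd.DataFrame(rows, columns=["raw_value", "iso3", "kind"])


def _assign_defects(rng: np.random.Generator, n: int,
                    rates: dict[str, float]) -> np.ndarray:
    """Per-row defect tag ('' = clean); defects are mutually exclusive."""
    kinds = [k for k in DEFECT_KINDS if rates.get(k, 0.0) > 0]
    tags = np.full(n, "", dtype=object)
    if not kinds:
        return tags
    probs = [rates[k] for k in kinds]
    clean_p = 1.0 - sum(probs)
    choice = rng.choice(len(kinds) + 1, size=n, p=probs + [clean_p])
    for i, k in enumerate(kinds):
        tags[choice == i] = k
    return tags


def generate_occurrences(config: SynthConfig,
                         registry: pd.DataFrame) -> pd.DataFrame:
    """Generate a raw occurrence table of exactly ``config.n_records`` rows.

    The returned frame carries the Darwin-Core-style columns plus a
    provenance column ``_defect`` ('' for clean rows).  Generation metadata
    (injected-defect counts, holding shares, pair-eligibility diagnostics)
    is attached in ``DataFrame.attrs``.
    """
    holding_pool = config.holding_countries()
    origin_pool = config.origin_countries()
    reg_countries = set(registry["country_iso3"])
    if set(holding_pool) - reg_countries:
        raise ValueError("registry does not cover all config holding countries")

    n = config.n_records
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    # dedicated streams so the pair-level mutuality coin flips stay aligned
    # across different reciprocity_target values (common random numbers)
    rng_mutual = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rng_fix = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    tags = _assign_defects(rng, n, dict(config.contamination_rates))

    shares = rng.dirichlet(np.full(config.n_holding_countries,
                                   config.concentration_alpha))
    hold_idx = rng.choice(config.n_holding_countries, size=n, p=shares)
    holding = np.array(holding_pool, dtype=object)[hold_idx]

    domestic = rng.random(n) < config.domestic_fraction
    origin = np.empty(n, dtype=object)
    origin_arr = np.array(origin_pool, dtype=object)
    pos = {c: i for i, c in enumerate(origin_pool)}
    # uniform over origin pool excluding the holding country
    raw_pick = rng.integers(0, len(origin_pool) - 1, size=n)
    for i in range(n):
        if domestic[i]:
            origin[i] = holding[i]
        else:
            j = raw_pick[i]
            if j >= pos[holding[i]]:
                j += 1
            origin[i] = origin_arr[j]

    periods = config.period_spec.periods
    p_idx = rng.choice(len(periods), size=n, p=list(config.period_weights))
    starts = np.array([p.start_year for p in periods])
    ends = np.array([p.end_year for p in periods])
    year = starts[p_idx] + (rng.random(n)
                            * (ends[p_idx] - starts[p_idx] + 1)).astype(int)

    family = np.array(config.families, dtype=object)[
        rng.integers(0, len(config.families), size=n)]
    count = 1 + rng.binomial(4, 0.04, size=n)

    recs: list[dict] = [
        {"family": family[i], "origin": origin[i], "holding": holding[i],
         "year": int(year[i]), "count": int(count[i]), "tag": tags[i]}
        for i in range(n)
    ]

    diag = _inject_reciprocity(recs, config.reciprocity_target,
                               set(holding_pool), rng_mutual, rng_fix,
                               config.period_spec)
    assert len(recs) == n

    df = _materialise(recs, registry, rng, config)
    counts = pd.Series([r["tag"] for r in recs]).value_counts().to_dict()
    counts.pop("", None)
    df.attrs["defect_counts"] = {k: int(counts.get(k, 0)) for k in DEFECT_KINDS}
    df.attrs["n_clean"] = int(n - sum(df.attrs["defect_counts"].values()))
    df.attrs["holding_shares"] = dict(zip(holding_pool, shares.tolist()))
    df.attrs.update(diag)
    return df


def _inject_reciprocity(recs: list[dict], target: float,
                        holding_pool: set[str],
                        rng_mutual: np.random.Generator,
                        rng_fix: np.random.Generator,
                        period_spec: PeriodSpec) -> dict:
    """Rewrite flows so pair-level bidirectionality tracks ``target``.

    Operates on clean, non-domestic rows.  Each realised unordered country
    pair whose both members can hold specimens is made mutual with
    probability ``target`` (one coin per pair; every coin is drawn from a
    dedicated stream regardless of the outcome, so the coins are identical
    across targets — measured reciprocity is then monotone in the target
    for a fixed seed).

    Non-mutual pairs that happen to be realised in both directions are
    collapsed by RE-ASSIGNING the origin of the minority-direction records
    to another country (one whose reverse edge is absent): the holding
    country of every record is preserved, so the holdings distribution —
    and hence the measured Gini — is untouched by reciprocity enforcement.
    At target 0 the resulting edge set has reciprocity exactly 0 unless no
    replacement origin exists (counted in ``unresolved_collisions``).

    A mutual pair backed by a single record gains its reverse record by
    merging two same-edge, same-slice records elsewhere, keeping the row
    count fixed; when no donor exists the pair is left one-way and counted
    in ``unsatisfied_mutual``.
    """
    groups: dict[frozenset, list[int]] = {}
    order: list[frozenset] = []
    origin_pool_sorted: set[str] = set()
    edge_count: dict[tuple[str, str], int] = {}
    for i, r in enumerate(recs):
        if r["tag"] != "":
            continue
        origin_pool_sorted.add(r["origin"])
        origin_pool_sorted.add(r["holding"])
        if r["origin"] == r["holding"]:
            continue
        key = frozenset((r["origin"], r["holding"]))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
        d = (r["origin"], r["holding"])
        edge_count[d] = edge_count.get(d, 0) + 1
    all_countries = sorted(origin_pool_sorted)

    coins = rng_mutual.random(len(order))
    unsatisfied = 0
    ineligible = 0
    collisions = 0
    pending: list[frozenset] = []

    def _move_edge(i: int, new_origin: str) -> None:
        r = recs[i]
        old = (r["origin"], r["holding"])
        edge_count[old] -= 1
        if edge_count[old] == 0:
            del edge_count[old]
        r["origin"] = new_origin
        new = (new_origin, r["holding"])
        edge_count[new] = edge_count.get(new, 0) + 1

    def _flip(i: int) -> None:
        r = recs[i]
        old = (r["origin"], r["holding"])
        edge_count[old] -= 1
        if edge_count[old] == 0:
            del edge_count[old]
        r["origin"], r["holding"] = r["holding"], r["origin"]
        new = (r["origin"], r["holding"])
        edge_count[new] = edge_count.get(new, 0) + 1

    for key, u in zip(order, coins):
        a, b = sorted(key)
        eligible = a in holding_pool and b in holding_pool
        idxs = groups[key]
        dirs: dict[tuple[str, str], list[int]] = {}
        for i in idxs:
            d = (recs[i]["origin"], recs[i]["holding"])
            if d in ((a, b), (b, a)):  # skip records already moved away
                dirs.setdefault(d, []).append(i)
        if not dirs:
            continue
        if eligible and u < target:
            if len(dirs) == 2:
                continue
            live = [i for lst in dirs.values() for i in lst]
            if len(live) >= 2:
                _flip(live[-1])
            else:
                pending.append(key)
        else:
            if not eligible:
                ineligible += 1
            if len(dirs) == 2:
                (d1, l1), (d2, l2) = sorted(dirs.items(),
                                            key=lambda kv: (-len(kv[1]), kv[0]))
                holder = d2[1]
                # candidates: keep the holder, swap in an origin whose
                # reverse edge is absent; prefer existing same-holder edges
                # so the pair set stays stable
                existing = [c for c in all_countries
                            if (c, holder) in edge_count
                            and (holder, c) not in edge_count and c != holder]
                fresh = [c for c in all_countries
                         if (holder, c) not in edge_count
                         and (c, holder) not in edge_count and c != holder]
                for i in list(l2):
                    cands = existing or fresh
                    if not cands:
                        collisions += 1
                        break
                    c = cands[rng_fix.integers(0, len(cands))]
                    _move_edge(i, c)

    # resolve singleton mutual pairs by freeing a row slot via a same-edge,
    # same-slice merge (network and slice structure are unchanged)
    for key in pending:
        live = [i for i in groups[key]
                if frozenset((recs[i]["origin"], recs[i]["holding"])) == key]
        if not live:
            continue
        i = live[0]
        donor = _find_donor(recs, period_spec)
        if donor is None:
            unsatisfied += 1
            continue
        j, k = donor
        recs[j]["count"] += recs[k]["count"]
        src = recs[i]
        recs[k] = {"family": src["family"], "origin": src["holding"],
                   "holding": src["origin"], "year": src["year"],
                   "count": 1, "tag": src["tag"]}

    return {"unsatisfied_mutual": unsatisfied, "ineligible_pairs": ineligible,
            "unresolved_collisions": collisions, "n_pairs": len(order)}


def _find_donor(recs: list[dict],
                period_spec: PeriodSpec) -> tuple[int, int] | None:
    """Two clean rows sharing family, period and directed edge (mergeable)."""
    seen: dict[tuple, int] = {}
    for j, r in enumerate(recs):
        if r["tag"] not in ("", "clean") or r["origin"] == r["holding"]:
            continue
        key = (r["family"], period_spec.assign(r["year"]),
               r["origin"], r["holding"])
        if key in seen:
            return seen[key], j
        seen[key] = j
    return None


def _materialise(recs: list[dict], registry: pd.DataFrame,
                 rng: np.random.Generator, config: SynthConfig) -> pd.DataFrame:
    inst_by_country: dict[str, list[str]] = {}
    for code, c in registry.itertuples(index=False):
        inst_by_country.setdefault(c, []).append(code)

    n = len(recs)
    has_eventdate = rng.random(n) < 0.5
    has_owner = rng.random(n) < 0.1
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    pre1900 = rng.integers(1800, 1900, size=n)
    basis_pick = rng.integers(0, len(_NON_SPECIMEN_BASES), size=n)

    rows = []
    for i, r in enumerate(recs):
        insts = inst_by_country.get(r["holding"], [])
        inst = insts[rng.integers(0, len(insts))] if insts else ""
        owner = ""
        if has_owner[i] and len(insts) > 1:
            owner = insts[rng.integers(0, len(insts))]
        row = {
            "family": r["family"],
            "basisOfRecord": "PreservedSpecimen",
            "country": ISO3_NAMES.get(r["origin"], r["origin"]),
            "countryCode": r["origin"],
            "institutionCode": inst,
            "ownerInstitutionCode": owner,
            "year": str(r["year"]),
            "eventDate": (f"{r['year']}-{month[i]:02d}-{day[i]:02d}"
                          if has_eventdate[i] else ""),
            "individualCount": str(r["count"]),
            "occurrenceStatus": "present",
            "_defect": r["tag"],
        }
        tag = r["tag"]
        if tag == "missing_year":
            row["year"] = ""
            row["eventDate"] = ""
        elif tag == "pre_1900_year":
            row["year"] = str(pre1900[i])
            row["eventDate"] = ""
        elif tag == "invalid_country_code":
            row["country"] = "Atlantis"
            row["countryCode"] = "ZZ"
        elif tag == "missing_origin":
            row["country"] = ""
            row["countryCode"] = ""
        elif tag == "missing_institution":
            row["institutionCode"] = ""
            row["ownerInstitutionCode"] = ""
        elif tag == "zero_count":
            row["individualCount"] = "0"
        elif tag == "non_specimen_basis":
            row["basisOfRecord"] = _NON_SPECIMEN_BASES[basis_pick[i]]
        elif tag == "absent_status":
            row["occurrenceStatus"] = "absent"
        rows.append(row)

    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS + ["_defect"])


def generate_dataset(config: SynthConfig, n_institutions: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience bundle: (occurrences, registry, country lookup)."""
    holding = config.holding_countries()
    if n_institutions is None:
        n_institutions = max(2 * len(holding), len(holding))
    registry = generate_registry(n_institutions, holding, config.seed)
    lookup = generate_lookup(config.origin_countries())
    occ = generate_occurrences(config, registry)
    return occ, registry, lookup


def reference_gini(concentration_alpha: float, n_holding: int, n_reps: int,
                   seed: int, n_records: int | None = None) -> dict[str, float]:
    """Monte-Carlo expected Gini of Dirichlet(alpha) share vectors.

    With ``n_records`` set, each replicate additionally draws multinomial
    counts of that size and applies the participants-only convention —
    matching what the occurrence generator plus the filtering/holdings
    pipeline actually measure on a finite table (near-zero shares truncate
    to zero counts, which matters at small alpha).

    Returns mean, per-draw standard deviation ``sd``, standard error of the
    mean ``se`` and ``n_reps``.  Used as the parameter-recovery oracle for
    the occurrence generator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if concentration_alpha <= 0 or n_holding < 1:
        raise ValueError("need positive alpha and n_holding >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(np.full(n_holding, concentration_alpha),
                          size=n_reps)
    if n_records is not None:
        counts = np.array([rng.multinomial(n_records, row) for row in draws])
        ginis = np.array([gini(row) for row in counts])
    else:
        ginis = np.array([gini(row) for row in draws])
    sd = float(ginis.std(ddof=1)) if n_reps > 1 else 0.0
    return {
        "mean": float(ginis.mean()),
        "sd": sd,
        "se": sd / np.sqrt(n_reps),
        "n_reps": n_reps,
    }


def write_occurrences(df: pd.DataFrame, path, debug: bool = False) -> None:
    """Write the occurrence table as UTF-8 CSV; provenance column only in debug."""
    out = df if debug else df[OCCURRENCE_COLUMNS]
    out.to_csv(path, index=False, lineterminator="\n")


def write_registry(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, index=False, lineterminator="\n")


def write_lookup(lookup: pd.DataFrame, path) -> None:
    lookup.to_csv(path, index=False, lineterminator="\n")
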