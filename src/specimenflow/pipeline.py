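"""End-to-end pipeline: synthesise-or-read, filter, networks, statistics.

A run is fully described by a RunConfig; reruns with an identical config
(and seed) produce byte-identical output bundles.  The manifest lists every
artefact with a SHA-256 checksum plus the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .inequality import gini_by_slice
from .ingest import (CountryLookup, Registry, filter_records,
                     parse_occurrences, records_to_frame)
from .network import build_flow_network, metrics_by_slice
from .periods import PERIOD_PRESETS
from .rankings import rankings_by_slice
from .trends import (early_vs_recent, gini_two_way_anova, metric_couplings,
                     sensitivity_suite, trend_table)

ARTEFACTS = ("filter_log.json", "records.csv", "edges.csv", "metrics.csv",
             "gini.csv", "rankings.csv", "trends.csv", "sensitivity.csv")


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    occurrences_path: str | None = None
    registry_path: str | None = None
    lookup_path: str | None = None
    periods: str = "default"
    families: tuple[str, ...] = ("Canidae", "Felidae", "Mustelidae")
    thresholds: tuple[int, ...] = (1, 5, 10)
    gini_variants: tuple[str, ...] = ("participants_only", "include_zeros")
    top_k: int = 5
    seed: int = 0
    out_dir: str = "out"
    # synthetic-mode knobs
    n_records: int = 5000
    n_origin_countries: int = 40
    n_holding_countries: int = 12
    n_institutions: int = 30
    concentration_alpha: float = 0.5
    reciprocity_target: float = 0.05
    domestic_fraction: float = 0.2
    period_weights: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    contamination_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            for name in ("occurrences_path", "registry_path", "lookup_path"):
                p = getattr(self, name)
                if not p:
                    raise ValueError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")
        if self.periods not in PERIOD_PRESETS:
            raise ValueError(f"unknown periods preset {self.periods!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("families", "thresholds", "gini_variants",
                    "period_weights"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def canonical_json(self) -> str:
        # out_dir is a location, not content: excluded so identical runs
        # into different directories produce identical manifests
        d = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute every stage and write the artefact bundle; returns the manifest."""

    def _log(stage: str, t0: float) -> None:
        if log is not None:
            log(f"[{stage}] {time.perf_counter() - t0:.2f}s")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            synth_cfg = synthetic.SynthConfig(
                n_origin_countries=config.n_origin_countries,
                n_holding_countries=config.n_holding_countries,
                n_records=config.n_records,
                concentration_alpha=config.concentration_alpha,
                reciprocity_target=config.reciprocity_target,
                domestic_fraction=config.domestic_fraction,
                period_weights=tuple(config.period_weights),
                contamination_rates=dict(config.contamination_rates),
                families=tuple(config.families),
                seed=config.seed,
                period_spec=PERIOD_PRESETS[config.periods](),
            )
            occ, registry_df, lookup_df = synthetic.generate_dataset(
                synth_cfg, n_institutions=config.n_institutions)
            raw = occ[synthetic.OCCURRENCE_COLUMNS]
            registry = Registry(registry_df)
            lookup = CountryLookup(lookup_df)
        else:
            raw = parse_occurrences(config.occurrences_path)
            registry = Registry.from_csv(config.registry_path)
            lookup = CountryLookup.from_csv(config.lookup_path)
        _log(stage, t0)

        stage = "filter"
        t0 = time.perf_counter()
        spec = PERIOD_PRESETS[config.periods]()
        records, flog = filter_records(raw, registry, lookup, spec)
        flog.to_json(out / "filter_log.json")
        _write_csv(records_to_frame(records), out / "records.csv")
        _log(stage, t0)

        stage = "networks"
        t0 = time.perf_counter()
        families = sorted({r.family for r in records}) or list(config.families)
        edge_rows = []
        for fam in families:
            for p in spec.labels:
                net = build_flow_network(records, fam, p, spec)
                for (o, h), w in sorted(net.edges.items()):
                    edge_rows.append({"family": fam, "period": p, "origin": o,
                                      "holding": h, "weight": w,
                                      "domestic": 0})
                for c, w in sorted(net.domestic.items()):
                    edge_rows.append({"family": fam, "period": p, "origin": c,
                                      "holding": c, "weight": w,
                                      "domestic": 1})
        _write_csv(pd.DataFrame(
            edge_rows, columns=["family", "period", "origin", "holding",
                                "weight", "domestic"]), out / "edges.csv")
        _log(stage, t0)

        stage = "metrics"
        t0 = time.perf_counter()
        metrics = metrics_by_slice(records, spec, families, seed=config.seed)
        _write_csv(metrics, out / "metrics.csv")
        _log(stage, t0)

        stage = "gini"
        t0 = time.perf_counter()
        gtab = gini_by_slice(records, spec, families,
                             variants=tuple(config.gini_variants))
        _write_csv(gtab, out / "gini.csv")
        _log(stage, t0)

        stage = "rankings"
        t0 = time.perf_counter()
        per_family = rankings_by_slice(records, spec, families, k=config.top_k)
        pooled = rankings_by_slice(records, spec, families, k=config.top_k,
                                   pooled=True)
        _write_csv(pd.concat([per_family, pooled], ignore_index=True),
                   out / "rankings.csv")
        _log(stage, t0)

        stage = "trends"
        t0 = time.perf_counter()
        ttab = trend_table(metrics, gtab, spec)
        extra = []
        base_gini = gtab[gtab["variant"] == "participants_only"]
        if (len(families) >= 2 and len(spec.labels) >= 2
                and base_gini["gini"].notna().all()):
            anova = gini_two_way_anova(base_gini)
            extra.append(anova.assign(kind="gini_two_way_anova"))
        welch = early_vs_recent(metrics)
        coup = metric_couplings(metrics)
        frames = [ttab.assign(kind="linear_trend")]
        if not welch.empty:
            frames.append(welch.assign(kind="welch_early_vs_recent"))
        if not coup.empty:
            frames.append(coup.assign(kind="coupling"))
        frames.extend(extra)
        _write_csv(pd.concat(frames, ignore_index=True, sort=False),
                   out / "trends.csv")
        _log(stage, t0)

        stage = "sensitivity"
        t0 = time.perf_counter()
        sens = sensitivity_suite(records, thresholds=tuple(config.thresholds),
                                 gini_variants=tuple(config.gini_variants),
                                 seed=config.seed)
        _write_csv(sens, out / "sensitivity.csv")
        _log(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": json.loads(config.canonical_json()),
        "artefacts": {name: _sha256(out / name) for name in ARTEFACTS},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
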