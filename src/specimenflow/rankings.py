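"""Net importer/exporter tables and top-k rankings per slice."""

from __future__ import annotations

import pandas as pd

from .ingest import OccurrenceRecord
from .network import FlowNetwork, build_flow_network, node_strengths
from .periods import PeriodSpec, default_periods


def net_flow_table(net: FlowNetwork) -> pd.DataFrame:
    """One row per country in the node set: strengths, net and balance.

    Ranking key downstream is the raw net count; the normalised balance
    (in-out)/(in+out) is reported alongside.
    """
    rows = []
    for s in node_strengths(net):
        if s.in_strength == 0 and s.out_strength == 0:
            continue  # domestic-only countries are not in the node set
        rows.append({"family": net.family, "period": net.period,
                     "country": s.country,
                     "in_strength": s.in_strength,
                     "out_strength": s.out_strength,
                     "net": s.net, "net_balance": s.net_balance})
    return pd.DataFrame(rows, columns=["family", "period", "country",
                                       "in_strength", "out_strength",
                                       "net", "net_balance"])


def top_net(table: pd.DataFrame, direction: str, k: int = 5) -> pd.DataFrame:
    """Top-k net importers (net desc) or exporters (net asc); ties by ISO3."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("importers", "exporters"):
        raise ValueError("direction must be 'importers' or 'exporters'")
    ascending = direction == "exporters"
    ranked = table.sort_values(["net", "country"],
                               ascending=[ascending, True],
                               kind="mergesort")
    return ranked.head(k).reset_index(drop=True)


def rankings_by_slice(records: list[OccurrenceRecord],
                      period_spec: PeriodSpec | None = None,
                      families: list[str] | None = None,
                      k: int = 5, pooled: bool = False) -> pd.DataFrame:
    """Long-format top importer/exporter table across slices.

    With ``pooled=True`` families are combined before ranking (one set of
    lists per period); otherwise one set per family × period.
    """
    spec = period_spec or default_periods()
    fams: list[str | None]
    if pooled:
        fams = [None]
    else:
        fams = list(families or sorted({r.family for r in records}))
    out = []
    for fam in fams:
        for p in spec.labels:
            net = build_flow_network(records, fam, p, spec)
            table = net_flow_table(net)
            if table.empty:
                continue
            for direction in ("importers", "exporters"):
                top = top_net(table, direction, k)
                top = top.assign(direction=direction,
                                 rank=range(1, len(top) + 1),
                                 family=fam if fam is not None else "all")
                out.append(top)
    if not out:
        return pd.DataFrame(columns=["family", "period", "country",
                                     "in_strength", "out_strength", "net",
                                     "net_balance", "direction", "rank"])
    return pd.concat(out, ignore_index=True)
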