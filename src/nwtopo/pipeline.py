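"""Ensemble sweeps, summary tables and group comparisons.

``run_sweep`` walks a declarative configuration over the network
families — nanowire depositions, Watts–Strogatz graphs (degree-matched to
the same-size depositions), the layered ANN and a connectome — computing
the full metric battery for each network and emitting one summary record
per network, plus tidy tables for the Watts–Strogatz plane, the propensity
comparison and the cartographic profiles.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import cartography, metrics, reference, wires
from .exceptions import UndefinedMetricError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "swp_null": 10,
    "asn": {
        "sizes": [100, 500, 1000, 2000],
        "mean_lengths": [6.0, 7.0, 8.0, 9.0],
        "dispersions": [0.0, 0.1, 0.2, 0.5],
        "replicates": 1,
        "plane": [30.0, 30.0],
    },
    "ws": {"sizes": [100, 500], "beta_step": 0.05},
    "ann": {"layers": [10, 160, 160, 160, 10]},
    "connectome": {"path": None, "synthetic": True},
}


@dataclass
class SummaryRecord:
    """Per-network row of the summary table."""

    family: str
    size: int
    params: dict
    mean_pl: float
    sd_pl: float
    mean_cc: float
    sd_cc: float
    mean_pcoeff: float
    sd_pcoeff: float
    mean_mz: float
    sd_mz: float
    swp_phi: float


@dataclass
class GroupComparison:
    groups: dict
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: pd.DataFrame


def summarize_network(
    graph: nx.Graph,
    family: str,
    params: Mapping | None = None,
    seed: int = 0,
    n_null: int = 10,
) -> SummaryRecord:
    """Compute the full metric battery for one network."""
    pl = metrics.mean_path_length(graph)
    cc = metrics.clustering(graph)
    swp = metrics.small_world_propensity(graph, n_null=n_null, seed=seed)
    _, carto = cartography.cartographic_profile(graph, seed=seed)
    return SummaryRecord(
        family=family,
        size=graph.number_of_nodes(),
        params=dict(params or {}),
        mean_pl=pl.mean_pl,
        sd_pl=pl.sd_pl,
        mean_cc=cc.mean_cc,
        sd_cc=cc.sd_cc,
        mean_pcoeff=carto["mean_pcoeff"],
        sd_pcoeff=carto["sd_pcoeff"],
        mean_mz=carto["mean_mz"],
        sd_mz=carto["sd_mz"],
        swp_phi=swp.phi,
    )


def _asn_networks(cfg: Mapping, seed: int) -> list[wires.NanowireNetwork]:
    grid = {
        "n_wires": cfg["sizes"],
        "mean_length": cfg["mean_lengths"],
        "dispersion": cfg["dispersions"],
    }
    return wires.generate_ensemble(
        grid,
        replicates=cfg.get("replicates", 1),
        seed=seed,
        plane=tuple(cfg.get("plane", (30.0, 30.0))),
    )


def run_sweep(config: Mapping | None = None, out_dir: str | Path | None = None
              ) -> list[SummaryRecord]:
    """Run the configured family sweep; optionally write artifact tables.

    Every failure is logged and skips only the offending network.  With
    ``out_dir`` set, writes ``summary.csv``, ``ws_plane.csv``, ``swp.csv``,
    per-network cartography tables and a ``manifest.json`` recording the
    config and seed.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg.get("seed", 0))
    n_null = int(cfg.get("swp_null", 10))
    records: list[SummaryRecord] = []
    carto_tables: dict[str, pd.DataFrame] = {}

    def process(graph, family, params, net_seed):
        try:
            rec = summarize_network(graph, family, params, seed=net_seed, n_null=n_null)
            records.append(rec)
            nodes, _ = cartography.cartographic_profile(graph, seed=net_seed)
            name = f"{family}_{len(records):03d}"
            carto_tables[name] = pd.DataFrame(
                [dataclasses.asdict(r) for r in nodes]
            )
        except UndefinedMetricError as exc:
            logger.error("skipping %s %s: %s", family, params, exc)

    asn_nets: list[wires.NanowireNetwork] = []
    if cfg.get("asn"):
        asn_nets = _asn_networks(cfg["asn"], seed)
        for net in asn_nets:
            p = net.params
            process(
                net.graph, "ASN",
                {"n_wires": p.n_wires, "mean_length": p.mean_length,
                 "dispersion": p.dispersion, "seed": p.seed},
                p.seed,
            )

    if cfg.get("ws"):
        betas = cfg["ws"].get("betas") or reference.beta_sweep(
            cfg["ws"].get("beta_step", 0.05)
        )
        for size in cfg["ws"].get("sizes", []):
            k = matched_k_for_size(asn_nets, size)
            for bi, beta in enumerate(betas):
                g = reference.watts_strogatz(
                    reference.WSParams(size, k, float(beta),
                                       seed=wires.derive_seed(seed, 10_000 + bi))
                )
                process(g, "WS", {"n": size, "k": k, "beta": float(beta)},
                        wires.derive_seed(seed, 20_000 + bi))

    if cfg.get("ann"):
        spec = reference.LayeredAnnSpec(tuple(cfg["ann"]["layers"]))
        process(reference.layered_ann(spec), "ANN",
                {"layers": list(spec.layer_sizes)}, seed)

    ccfg = cfg.get("connectome") or {}
    if ccfg.get("path"):
        conn = reference.load_connectome(ccfg["path"], ccfg.get("format"))
        process(conn.graph, "connectome", {"path": str(ccfg["path"])}, seed)
    elif ccfg.get("synthetic"):
        conn = reference.synthetic_connectome(seed=seed)
        process(conn.graph, "connectome", {"synthetic": True}, seed)

    if out_dir is not None:
        _write_artifacts(Path(out_dir), cfg, records, carto_tables)
    return records


def matched_k_for_size(
    asn_nets: Sequence[wires.NanowireNetwork], size: int
) -> int:
    """k for a WS graph degree-matched to the same-size depositions; falls
    back to k=2 when no deposition of that size is available."""
    degs = [net.mean_degree for net in asn_nets if net.params.n_wires == size]
    if not degs:
        return 2
    return reference.k_from_mean_degree(float(np.mean(degs)))


def _write_artifacts(out, cfg, records, carto_tables) -> None:
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df["params"] = df["params"].map(json.dumps)
    df.to_csv(out / "summary.csv", index=False)
    df[["family", "size", "mean_cc", "mean_pl"]].to_csv(
        out / "ws_plane.csv", index=False
    )
    df[["family", "size", "swp_phi"]].to_csv(out / "swp.csv", index=False)
    cdir = out / "cartography"
    cdir.mkdir(exist_ok=True)
    for name, table in carto_tables.items():
        table.to_csv(cdir / f"{name}.csv", index=False)
    manifest = {"config": _jsonable(cfg), "n_records": len(records)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def path_profile(graph: nx.Graph, source) -> dict:
    """Hop distances from ``source`` plus the all-pairs histogram.

    Returns ``distances`` (node -> hops from source), ``histogram``
    (hop count -> number of pairs) and the all-pairs mean and median.
    """
    if source not in graph:
        raise UndefinedMetricError(f"source {source!r} not in graph")
    ps = metrics.mean_path_length(graph, source=source)
    lengths = ps.pair_lengths.astype(int)
    counts = np.bincount(lengths)
    return {
        "distances": ps.source_distances,
        "histogram": {int(h): int(c) for h, c in enumerate(counts) if h and c},
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
    }


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across labelled groups with Bonferroni post-hocs.

    Raises when fewer than two groups are given or all observations are
    identical (zero total variance leaves F undefined).
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2 or any(len(d) == 0 for d in data):
        raise UndefinedMetricError("need >= 2 non-empty groups")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0.0:
        raise UndefinedMetricError("all observations identical; F undefined")
    f_stat, p = stats.f_oneway(*data)
    n_total = len(pooled)
    df_between = len(data) - 1
    df_within = n_total - len(data)

    pairs = list(itertools.combinations(range(len(names)), 2))
    rows = []
    for i, j in pairs:
        if len(data[i]) > 1 or len(data[j]) > 1:
            t, praw = stats.ttest_ind(data[i], data[j])
        else:
            t, praw = np.nan, np.nan
        rows.append({
            "group_a": names[i],
            "group_b": names[j],
            "t": float(t),
            "p_raw": float(praw),
            "p_bonferroni": float(min(1.0, praw * len(pairs)))
            if np.isfinite(praw) else np.nan,
        })
    return GroupComparison(
        groups={n: list(map(float, d)) for n, d in zip(names, data)},
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p),
        posthoc=pd.DataFrame(rows),
    )
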