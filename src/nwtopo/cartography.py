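"""Functional cartography: modules, participation, within-module degree.

Nodes are characterised by where their edges go relative to a modular
partition.  The participation coefficient P_i = 1 - sum_s (k_is / k_i)^2
is 0 when all of node i's edges stay inside its own module and approaches
1 when they spread evenly across modules.  The within-module degree
z-score standardises a node's within-module degree against its module's
mean and SD; z >= 2.5 marks module hubs.  The (P, z) plane is tiled into
seven regions (Guimera–Amaral cartography) used to classify every node.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ParameterError, UndefinedMetricError
from .metrics import largest_component

#: z-score at or above which a node counts as a module hub
HUB_Z = 2.5
#: participation boundaries for non-hub nodes: peripheral / connector / kinless
NONHUB_P = (0.62, 0.80)
#: participation boundaries for hub nodes: provincial / connector / kinless
HUB_P = (0.30, 0.75)

REGIONS = (
    "ultra-peripheral",
    "peripheral",
    "non-hub connector",
    "non-hub kinless",
    "provincial hub",
    "connector hub",
    "kinless hub",
)


@dataclass
class Partition:
    """Node -> module assignment with its modularity score; module ids are
    contiguous integers from 0."""

    assignment: dict
    modularity_q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return out


@dataclass
class NodeCartography:
    node: object
    degree: int
    module: int
    pcoeff: float
    mz: float
    region: str


def detect_communities(graph: nx.Graph, seed: int = 0) -> Partition:
    """Louvain modularity maximisation, deterministic under ``seed``."""
    if graph.number_of_edges() == 0:
        raise UndefinedMetricError("community detection needs >= 1 edge")
    comms = nx.community.louvain_communities(graph, seed=seed)
    q = nx.community.modularity(graph, comms)
    assignment = {}
    for mod, members in enumerate(sorted(comms, key=lambda c: sorted(map(str, c))[0])):
        for node in members:
            assignment[node] = mod
    return Partition(assignment=assignment, modularity_q=float(q))


def participation_coefficient(graph: nx.Graph, partition: Partition) -> dict:
    """P_i = 1 - sum over modules of (edges into module / degree)^2."""
    assignment = partition.assignment
    out = {}
    for node in graph:
        k = graph.degree(node)
        if k == 0:
            out[node] = 0.0
            continue
        counts = Counter(assignment[nb] for nb in graph[node])
        out[node] = 1.0 - sum((c / k) ** 2 for c in counts.values())
    return out


def within_module_z(graph: nx.Graph, partition: Partition) -> dict:
    """z_i of the within-module degree against the node's own module.

    Modules whose members all share the same within-module degree (zero
    SD) give z = 0 for every member, so each module's mean z is always 0.
    """
    out = {}
    for _, members in partition.members().items():
        memberset = set(members)
        kappa = np.array(
            [sum(1 for nb in graph[n] if nb in memberset) for n in members],
            dtype=float,
        )
        sd = kappa.std()
        if sd < 1e-12:
            z = np.zeros_like(kappa)
        else:
            z = (kappa - kappa.mean()) / sd
        out.update(zip(members, map(float, z)))
    return out


def classify_node(pcoeff: float, mz: float) -> str:
    """Deterministic seven-region cartographic label for one node.

    Non-hubs (z < 2.5) split at participation 0 / 0.62 / 0.80; hubs
    (z >= 2.5) split at 0.30 / 0.75.  Boundary participation values fall
    in the upper region; boundary z = 2.5 counts as hub.
    """
    eps = 1e-12
    if not -eps <= pcoeff <= 1.0 + eps:
        raise ParameterError(f"participation coefficient out of [0, 1]: {pcoeff}")
    if mz >= HUB_Z:
        if pcoeff < HUB_P[0]:
            return "provincial hub"
        if pcoeff < HUB_P[1]:
            return "connector hub"
        return "kinless hub"
    if pcoeff <= eps:
        return "ultra-peripheral"
    if pcoeff < NONHUB_P[0]:
        return "peripheral"
    if pcoeff < NONHUB_P[1]:
        return "non-hub connector"
    return "non-hub kinless"


def cartographic_profile(
    graph: nx.Graph, seed: int = 0
) -> tuple[list[NodeCartography], dict]:
    """Partition the LCC and map every node onto the cartographic plane.

    Returns per-node records (degree, module, participation, z, region)
    and a summary with mean/SD participation and z, region counts,
    modularity and module count.
    """
    lcc, excluded = largest_component(graph)
    partition = detect_communities(lcc, seed=seed)
    pc = participation_coefficient(lcc, partition)
    mz = within_module_z(lcc, partition)
    records = [
        NodeCartography(
            node=n,
            degree=lcc.degree(n),
            module=partition.assignment[n],
            pcoeff=pc[n],
            mz=mz[n],
            region=classify_node(pc[n], mz[n]),
        )
        for n in lcc
    ]
    pvals = np.array([r.pcoeff for r in records])
    zvals = np.array([r.mz for r in records])
    summary = {
        "mean_pcoeff": float(pvals.mean()),
        "sd_pcoeff": float(pvals.std()),
        "mean_mz": float(zvals.mean()),
        "sd_mz": float(zvals.std()),
        "region_counts": dict(Counter(r.region for r in records)),
        "modularity_q": partition.modularity_q,
        "n_modules": partition.n_modules,
        "excluded_fraction": excluded,
    }
    return records, summary
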