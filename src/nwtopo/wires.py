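"""Random nanowire deposition and junction-graph extraction.

Self-assembled nanowire networks are modelled structurally: each nanowire
is a 1D straight segment whose midpoint is uniform on a rectangular plane,
whose orientation is uniform on [0, 2pi), and whose length is drawn from a
normal distribution parameterised by a mean (micrometres) and a dispersion
(standard deviation over mean).  Every crossing point between two wires is
taken to be a junction, and the network is summarised as an undirected
simple graph with one node per wire and one edge per intersecting pair of
wires.  Wires may overhang the plane boundary; only midpoints are
constrained.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

#: absolute tolerance, in micrometres, within which touching endpoints count
#: as an intersection
TOUCH_TOL = 1e-9

_PAIR_CHUNK = 4_000_000  # pairs processed per vectorized block


@dataclass(frozen=True)
class WireEnsembleParams:
    """Parameters of one random nanowire deposition.

    Lengths are in micrometres.  ``dispersion`` is the ratio of the
    standard deviation to the mean of the wire-length distribution
    (0 means all wires share ``mean_length`` exactly).
    """

    n_wires: int
    mean_length: float
    dispersion: float
    plane_width: float = 30.0
    plane_height: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wires < 1:
            raise ParameterError(f"n_wires must be >= 1, got {self.n_wires}")
        if not self.mean_length > 0:
            raise ParameterError(f"mean_length must be > 0, got {self.mean_length}")
        if not 0.0 <= self.dispersion <= 1.0:
            raise ParameterError(f"dispersion must lie in [0, 1], got {self.dispersion}")
        if not (self.plane_width > 0 and self.plane_height > 0):
            raise ParameterError("plane dimensions must be positive")


@dataclass(frozen=True)
class Wire:
    """A 1D nanowire segment: midpoint, orientation, length (micrometres)."""

    id: int
    cx: float
    cy: float
    angle: float
    length: float

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        dx = 0.5 * self.length * math.cos(self.angle)
        dy = 0.5 * self.length * math.sin(self.angle)
        return (self.cx - dx, self.cy - dy), (self.cx + dx, self.cy + dy)


@dataclass(frozen=True)
class Junction:
    """Crossing point of two wires; ``wire_a < wire_b`` by convention."""

    wire_a: int
    wire_b: int
    x: float
    y: float


@dataclass
class NanowireNetwork:
    """A sampled deposition together with its junction graph."""

    params: WireEnsembleParams | None
    wires: list[Wire]
    junctions: list[Junction]
    graph: nx.Graph = field(repr=False)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def mean_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2.0 * self.graph.number_of_edges() / n if n else 0.0


def sample_wires(params: WireEnsembleParams) -> list[Wire]:
    """Draw a random wire deposition, reproducible from ``params.seed``.

    Lengths come from Normal(mean, dispersion * mean) with non-positive
    samples redrawn, so the support is strictly positive.  At dispersion 0
    every wire has exactly the mean length.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_wires
    cx = rng.uniform(0.0, params.plane_width, n)
    cy = rng.uniform(0.0, params.plane_height, n)
    angle = rng.uniform(0.0, 2.0 * np.pi, n)
    if params.dispersion == 0.0:
        lengths = np.full(n, float(params.mean_length))
    else:
        sd = params.dispersion * params.mean_length
        lengths = rng.normal(params.mean_length, sd, n)
        while True:
            bad = lengths <= 0.0
            if not bad.any():
                break
            lengths[bad] = rng.normal(params.mean_length, sd, int(bad.sum()))
    return [
        Wire(i, float(cx[i]), float(cy[i]), float(angle[i]), float(lengths[i]))
        for i in range(n)
    ]


def segment_intersection(
    a: Wire, b: Wire, tol: float = TOUCH_TOL
) -> tuple[float, float] | None:
    """Return the proper crossing point of two wires, or ``None``.

    Parallel and disjoint segments yield ``None``.  Collinear overlapping
    segments (a measure-zero configuration) also yield ``None`` — a contact
    line is not a crossing point — with a logged warning.  Endpoints that
    touch within ``tol`` micrometres count as an intersection.
    """
    (ax1, ay1), (ax2, ay2) = a.endpoints
    (bx1, by1), (bx2, by2) = b.endpoints
    rx, ry = ax2 - ax1, ay2 - ay1
    sx, sy = bx2 - bx1, by2 - by1
    rxs = rx * sy - ry * sx
    qpx, qpy = bx1 - ax1, by1 - ay1
    if abs(rxs) <= 1e-14 * a.length * b.length:
        # parallel; check for collinear overlap purely to warn about it
        if abs(qpx * ry - qpy * rx) <= tol * max(a.length, b.length):
            t0 = (qpx * rx + qpy * ry) / (rx * rx + ry * ry)
            t1 = t0 + (sx * rx + sy * ry) / (rx * rx + ry * ry)
            if min(t0, t1) <= 1.0 and max(t0, t1) >= 0.0:
                logger.warning(
                    "collinear overlapping wires %d and %d: no junction recorded",
                    a.id, b.id,
                )
        return None
    t = (qpx * sy - qpy * sx) / rxs
    u = (qpx * ry - qpy * rx) / rxs
    ta, tb = tol / a.length, tol / b.length
    if -ta <= t <= 1.0 + ta and -tb <= u <= 1.0 + tb:
        return (ax1 + t * rx, ay1 + t * ry)
    return None


def _endpoint_arrays(wires: Sequence[Wire]) -> tuple[np.ndarray, ...]:
    cx = np.array([w.cx for w in wires])
    cy = np.array([w.cy for w in wires])
    ang = np.array([w.angle for w in wires])
    ln = np.array([w.length for w in wires])
    dx = 0.5 * ln * np.cos(ang)
    dy = 0.5 * ln * np.sin(ang)
    return cx - dx, cy - dy, cx + dx, cy + dy, ln


def build_network(
    wires: Sequence[Wire], params: WireEnsembleParams | None = None
) -> NanowireNetwork:
    """Extract the junction graph of a wire deposition.

    All pairwise crossings are found with a vectorized orientation test
    (chunked so memory stays bounded for large depositions); every crossing
    becomes a junction and an edge, under the simplifying assumption that
    each wire-wire intersection forms a junction.
    """
    if len(wires) == 0:
        raise ParameterError("cannot build a network from an empty wire list")
    n = len(wires)
    x1, y1, x2, y2, ln = _endpoint_arrays(wires)
    ii, jj = np.triu_indices(n, 1)

    junctions: list[Junction] = []
    edges: list[tuple[int, int]] = []
    for start in range(0, ii.size, _PAIR_CHUNK):
        i = ii[start : start + _PAIR_CHUNK]
        j = jj[start : start + _PAIR_CHUNK]
        rx, ry = x2[i] - x1[i], y2[i] - y1[i]
        sx, sy = x2[j] - x1[j], y2[j] - y1[j]
        rxs = rx * sy - ry * sx
        qpx, qpy = x1[j] - x1[i], y1[j] - y1[i]
        nonpar = np.abs(rxs) > 1e-14 * ln[i] * ln[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(nonpar, (qpx * sy - qpy * sx) / rxs, -1.0)
            u = np.where(nonpar, (qpx * ry - qpy * rx) / rxs, -1.0)
        ta, tb = TOUCH_TOL / ln[i], TOUCH_TOL / ln[j]
        hit = (
            nonpar
            & (t >= -ta) & (t <= 1.0 + ta)
            & (u >= -tb) & (u <= 1.0 + tb)
        )
        hx = x1[i][hit] + t[hit] * rx[hit]
        hy = y1[i][hit] + t[hit] * ry[hit]
        for a, b, x, y in zip(i[hit], j[hit], hx, hy):
            junctions.append(Junction(int(a), int(b), float(x), float(y)))
            edges.append((int(a), int(b)))

    graph = nx.Graph()
    graph.add_nodes_from(w.id for w in wires)
    graph.add_edges_from(edges)
    return NanowireNetwork(params=params, wires=list(wires), junctions=junctions, graph=graph)


def expected_junctions(n_wires: int, mean_length: float, plane_area: float) -> float:
    """Buffon-type estimate of the mean junction count: n(n-1) l^2 / (pi A).

    Two uniformly placed, uniformly oriented segments of length l cross
    with probability 2 l^2 / (pi A) (ignoring boundary effects), summed
    over the n(n-1)/2 unordered pairs.
    """
    return n_wires * (n_wires - 1) * mean_length**2 / (math.pi * plane_area)


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based per-network seed derived from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def generate_ensemble(
    params_grid: Mapping[str, Sequence],
    replicates: int = 1,
    seed: int = 0,
    plane: tuple[float, float] = (30.0, 30.0),
) -> list[NanowireNetwork]:
    """Generate one network per grid point per replicate.

    ``params_grid`` maps ``n_wires``, ``mean_length`` and ``dispersion`` to
    value lists; the full Cartesian product is enumerated.  Per-network
    seeds are derived deterministically from ``seed`` by a counter, so the
    whole ensemble is reproducible and any single member can be re-created
    from its recorded params.
    """
    sizes = list(params_grid.get("n_wires", []))
    lengths = list(params_grid.get("mean_length", []))
    dispersions = list(params_grid.get("dispersion", []))
    if not (sizes and lengths and dispersions) or replicates < 1:
        raise ParameterError("params_grid must be non-empty with >= 1 replicate")
    networks = []
    counter = itertools.count()
    for n, length, disp in itertools.product(sizes, lengths, dispersions):
        for _ in range(replicates):
            p = WireEnsembleParams(
                n_wires=int(n),
                mean_length=float(length),
                dispersion=float(disp),
                plane_width=float(plane[0]),
                plane_height=float(plane[1]),
                seed=derive_seed(seed, next(counter)),
            )
            networks.append(build_network(sample_wires(p), p))
    return networks
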