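"""Plain-text import/export: edge lists, wire tables, junction tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .exceptions import FormatError
from .wires import Junction, NanowireNetwork, Wire


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Two node ids per line, tab-separated, no attributes."""
    nx.write_edgelist(graph, str(path), data=False, delimiter="\t")


def read_edgelist(path: str | Path) -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    g = nx.read_edgelist(str(path), data=False, delimiter="\t")
    if g.number_of_nodes() == 0:
        raise FormatError(f"{path} contains no edges")
    return g


def write_wire_table(wires: Sequence[Wire], path: str | Path) -> None:
    pd.DataFrame(
        [(w.id, w.cx, w.cy, w.angle, w.length) for w in wires],
        columns=["id", "cx", "cy", "angle", "length"],
    ).to_csv(path, index=False)


def write_junction_table(junctions: Sequence[Junction], path: str | Path) -> None:
    pd.DataFrame(
        [(j.wire_a, j.wire_b, j.x, j.y) for j in junctions],
        columns=["wire_a", "wire_b", "x", "y"],
    ).to_csv(path, index=False)


def export_network(net: NanowireNetwork, out_dir: str | Path) -> None:
    """Write edges.tsv, wires.csv and junctions.csv for one deposition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edgelist(net.graph, out / "edges.tsv")
    write_wire_table(net.wires, out / "wires.csv")
    write_junction_table(net.junctions, out / "junctions.csv")
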