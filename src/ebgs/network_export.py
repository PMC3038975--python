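"""Marker interaction network from ranked epistatic effects.

Selected epistatic terms become edges of an undirected graph over the
markers they involve (isolated markers never appear); the edge weight is
the term's LOD score and its sign records the direction of the epistatic
effect.  Graphs export as tab-delimited edge lists or Graphviz DOT with
pen widths proportional to LOD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .association_stats import TermTest, rank_by_lod
from .errors import ValidationError

_PENWIDTH_RANGE = (0.5, 5.0)


@dataclass
class InteractionGraph:
    """Undirected marker graph; edge attrs: ``lod`` (>= 0) and ``sign`` (+-1)."""

    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_records(self) -> list[tuple[str, str, float, int]]:
        """Edges in canonical (a, b) order, strongest first."""
        recs = [
            (a, b, float(d["lod"]), int(d["sign"]))
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(recs, key=lambda r: (-r[2], r[0], r[1]))


def build_interaction_graph(
    tests: Sequence[TermTest],
    top_n: int | None = None,
    lod_min: float | None = None,
) -> InteractionGraph:
    """Graph of the strongest epistatic terms.

    Selection is by ``top_n`` LOD rank (ties resolved as in
    :func:`rank_by_lod`) or by the ``lod_min`` threshold.  Duplicate marker
    pairs are an error: each interaction must be tested once.
    """
    epi = [t for t in tests if t.term.kind == "epistatic"]
    if not epi:
        raise ValidationError("no epistatic terms among the tests")
    if top_n is not None and top_n <= 0:
        raise ValidationError("top_n must be positive")
    seen = set()
    for t in epi:
        key = tuple(t.term.markers)
        if key in seen:
            raise ValidationError(f"duplicate epistatic pair {key}")
        seen.add(key)
    if top_n is not None:
        order = rank_by_lod(epi).order[:top_n]
        chosen = [epi[i] for i in order]
    elif lod_min is not None:
        chosen = [t for t in epi if t.lod >= lod_min]
    else:
        chosen = list(epi)
    g = nx.Graph()
    for t in chosen:
        a, b = t.term.markers
        g.add_edge(a, b, lod=float(t.lod), sign=1 if t.effect >= 0 else -1)
    return InteractionGraph(g)


def write_graph(
    graph: InteractionGraph, path: str | Path, format: str = "edgelist"
) -> None:
    """Write the graph as a tab-delimited edge list or Graphviz DOT."""
    recs = graph.edge_records()
    try:
        with open(path, "w") as fh:
            if format == "edgelist":
                fh.write("marker_1\tmarker_2\tlod\tsign\n")
                for a, b, lod, sign in recs:
                    fh.write(f"{a}\t{b}\t{lod:.6g}\t{sign:+d}\n")
            elif format == "dot":
                lo, hi = _PENWIDTH_RANGE
                max_lod = max((r[2] for r in recs), default=1.0) or 1.0
                fh.write("graph interactions {\n")
                for a, b, lod, sign in recs:
                    pw = lo + (hi - lo) * lod / max_lod
                    style = "solid" if sign > 0 else "dashed"
                    fh.write(
                        f'  "{a}" -- "{b}" [penwidth={pw:.3f}, style={style}, '
                        f'label="{lod:.2f}"];\n'
                    )
                fh.write("}\n")
            else:
                raise ValidationError(f"unknown graph format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write graph to {path}: {exc}") from exc


def read_edgelist(path: str | Path) -> InteractionGraph:
    """Read back a tab-delimited edge list written by :func:`write_graph`."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker_1"):
            raise ValidationError(f"{path} is not an edge-list file")
        for line in fh:
            a, b, lod, sign = line.rstrip("\n").split("\t")
            g.add_edge(a, b, lod=float(lod), sign=int(sign))
    return InteractionGraph(g)
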