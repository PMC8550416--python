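"""Text interchange for network structures.

Three formats are supported:

* a compact model string ``[A][B|A][C|A:B]`` (node given colon-separated
  parents),
* GraphML via :mod:`networkx` (undirected PDAG edges are tagged with a
  ``directed="false"`` edge attribute),
* a minimal DOT dialect (``a -> b;`` for arcs, ``a -- b;`` for undirected
  edges) written and parsed directly so no graphviz binding is required.
"""

from __future__ import annotations

import re

import networkx as nx

from ..exceptions import ContractError
from .graph import Dag, Pdag

__all__ = [
    "to_model_string",
    "from_model_string",
    "write_graphml",
    "read_graphml",
    "write_dot",
    "read_dot",
]


# -- model strings ---------------------------------------------------------

def to_model_string(dag: Dag) -> str:
    """Render a DAG as ``[A][B|A][C|A:B]`` (nodes in topological order)."""
    parts = []
    for n in dag.topological_order():
        pa = sorted(dag.parents(n))
        parts.append(f"[{n}|{':'.join(pa)}]" if pa else f"[{n}]")
    return "".join(parts)


_MODEL_TOKEN = re.compile(r"\[([^\[\]|]+)(?:\|([^\[\]]+))?\]")


def from_model_string(text: str) -> Dag:
    """Parse a ``[A][B|A]`` model string back into a :class:`Dag`."""
    matches = list(_MODEL_TOKEN.finditer(text))
    if not matches or "".join(m.group(0) for m in matches) != text.strip():
        raise ContractError(f"malformed model string: {text!r}")
    nodes = []
    arcs = []
    for m in matches:
        child = m.group(1).strip()
        nodes.append(child)
        if m.group(2):
            for p in m.group(2).split(":"):
                arcs.append((p.strip(), child))
    dag = Dag()
    for n in nodes:
        dag.add_node(n)
    for u, v in arcs:
        if u not in dag.nodes:
            raise ContractError(f"parent {u!r} not declared in model string")
        dag.add_arc(u, v)
    return dag


# -- GraphML ---------------------------------------------------------------

def _as_nx(graph: Dag | Pdag, arc_attrs=None) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    if isinstance(graph, Dag):
        for u, v in graph.arcs():
            g.add_edge(u, v, directed="true")
    else:
        for u, v in sorted(graph.directed_arcs):
            g.add_edge(u, v, directed="true")
        for e in sorted(graph.undirected_edges, key=sorted):
            u, v = sorted(e)
            g.add_edge(u, v, directed="false")
    if arc_attrs:
        for (u, v), attrs in arc_attrs.items():
            if g.has_edge(u, v):
                g[u][v].update(attrs)
    return g


def write_graphml(graph: Dag | Pdag, path, arc_attrs=None) -> None:
    """Serialize to GraphML; ``arc_attrs`` maps ``(u, v)`` to attribute dicts
    (e.g. bootstrap strengths)."""
    nx.write_graphml(_as_nx(graph, arc_attrs), path)


def read_graphml(path) -> Dag | Pdag:
    g = nx.read_graphml(path)
    directed = []
    undirected = []
    for u, v, attrs in g.edges(data=True):
        if str(attrs.get("directed", "true")).lower() == "false":
            undirected.append((u, v))
        else:
            directed.append((u, v))
    if undirected:
        return Pdag(sorted(g.nodes), directed, undirected)
    return Dag(sorted(g.nodes), directed)


# -- DOT -------------------------------------------------------------------

def write_dot(graph: Dag | Pdag, path) -> None:
    lines = ["digraph G {"]
    for n in graph.nodes:
        lines.append(f'    "{n}";')
    if isinstance(graph, Dag):
        for u, v in graph.arcs():
            lines.append(f'    "{u}" -> "{v}";')
    else:
        for u, v in sorted(graph.directed_arcs):
            lines.append(f'    "{u}" -> "{v}";')
        for e in sorted(graph.undirected_edges, key=sorted):
            u, v = sorted(e)
            lines.append(f'    "{u}" -- "{v}";')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


_DOT_EDGE = re.compile(r'"([^"]+)"\s*(->|--)\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*;\s*$')


def read_dot(path) -> Dag | Pdag:
    nodes: list[str] = []
    directed: list[tuple[str, str]] = []
    undirected: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            m = _DOT_EDGE.search(line)
            if m:
                u, kind, v = m.groups()
                for n in (u, v):
                    if n not in nodes:
                        nodes.append(n)
                (directed if kind == "->" else undirected).append((u, v))
                continue
            m = _DOT_NODE.match(line)
            if m and m.group(1) not in nodes:
                nodes.append(m.group(1))
    if undirected:
        return Pdag(nodes, directed, undirected)
    return Dag(nodes, directed)
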