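"""Graph container, plain-text edge-list I/O and degree statistics.

Networks are undirected, unweighted simple graphs held in a
:class:`networkx.Graph`.  Node labels are opaque (strings when parsed from
a file, whatever the caller supplies otherwise); all algorithms in this
package treat them as hashable identifiers only.

The edge-list dialect accepted here covers the common formats of public
network repositories: one edge per line as two tokens separated by
whitespace or a single comma, ``#``/``%`` comment lines, and single-token
lines declaring isolated (degree-0) nodes.  Isolated nodes are first-class
citizens throughout the package — protein-interaction networks routinely
contain them, and the scoring algorithm must remain well-defined there.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import networkx as nx

logger = logging.getLogger("glinet")

#: comment markers recognised at the start of an edge-list line
COMMENT_PREFIXES = ("#", "%")

_SPLIT_RE = re.compile(r"[,\s]+")

PathOrStream = Union[str, Path, IO[str]]


class EdgeListParseError(ValueError):
    """A line of an edge list could not be interpreted."""

    def __init__(self, lineno: int, line: str, reason: str):
        self.lineno = lineno
        self.line = line
        super().__init__(f"line {lineno}: {reason!s} ({line!r})")


@dataclass(frozen=True)
class DegreeMap:
    """Per-node degree ``d(v)`` together with the network maximum ``maxD``.

    ``maxD`` is the global maximum over the whole graph (0 for an edgeless
    graph); it is the normalisation constant for neighbour contributions
    in the influence score.
    """

    degree: Mapping[object, int]
    max_degree: int

    def __getitem__(self, node) -> int:
        return self.degree[node]


def _tokenize(line: str) -> list[str]:
    return [t for t in _SPLIT_RE.split(line.strip()) if t]


def read_edge_list(
    source: PathOrStream,
    delimiter: str | None = None,
    comment_prefix: Iterable[str] = COMMENT_PREFIXES,
) -> nx.Graph:
    """Parse a plain-text edge list into an undirected simple graph.

    Parameters
    ----------
    source
        Path or open text stream.
    delimiter
        Explicit separator; by default any run of whitespace or a comma.
    comment_prefix
        Line prefixes to skip (default ``#`` and ``%``).

    Self-loops and duplicate edges are dropped (with a logged warning
    count), since the adjacency model is a 0/1 symmetric matrix.  A line
    with a single token declares an isolated node.  Extra columns beyond
    the first two (e.g. weights) are ignored.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_edge_list(fh, delimiter, comment_prefix)

    graph = nx.Graph()
    loops = dupes = 0
    prefixes = tuple(comment_prefix)
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(prefixes):
            continue
        if delimiter is not None:
            tokens = [t for t in line.split(delimiter) if t.strip()]
            tokens = [t.strip() for t in tokens]
        else:
            tokens = _tokenize(line)
        if not tokens:
            raise EdgeListParseError(lineno, raw.rstrip("\n"), "no tokens")
        if len(tokens) == 1:
            graph.add_node(tokens[0])
            continue
        u, v = tokens[0], tokens[1]
        if u == v:
            loops += 1
            graph.add_node(u)
            continue
        if graph.has_edge(u, v):
            dupes += 1
            continue
        graph.add_edge(u, v)
    if loops or dupes:
        logger.warning(
            "edge list simplified: %d self-loop(s) and %d duplicate edge(s) dropped",
            loops,
            dupes,
        )
    return graph


def write_edge_list(graph: nx.Graph, sink: PathOrStream) -> None:
    """Write ``graph`` as a plain-text edge list.

    Each edge appears exactly once with endpoints in canonical (sorted)
    order; isolated nodes are emitted as single-token lines.  The output
    round-trips through :func:`read_edge_list` up to node/edge set
    equality (labels are written as strings).
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_edge_list(graph, fh)
        return

    key = _label_sort_key
    for u, v in sorted(
        (tuple(sorted((u, v), key=key)) for u, v in graph.edges()),
        key=lambda e: (key(e[0]), key(e[1])),
    ):
        sink.write(f"{u} {v}\n")
    for node in sorted(graph.nodes(), key=key):
        if graph.degree(node) == 0:
            sink.write(f"{node}\n")


def _label_sort_key(label):
    """Deterministic total order over arbitrary node labels.

    Numeric labels (and numeric strings such as ``"10"``) sort by value,
    everything else lexicographically; the type tag keeps mixed sets
    well-ordered.
    """
    if isinstance(label, (int, float)):
        return (0, float(label), "")
    text = str(label)
    try:
        return (0, float(text), "")
    except ValueError:
        # natural sort: "v2" < "v10"
        parts = re.split(r"(\d+)", text)
        return (1, 0.0, tuple((int(p) if p.isdigit() else -1, p if not p.isdigit() else "") for p in parts if p))


def edge_list_string(graph: nx.Graph) -> str:
    """Render the canonical edge-list text for ``graph`` (convenience)."""
    buf = io.StringIO()
    write_edge_list(graph, buf)
    return buf.getvalue()


def degree_map(graph: nx.Graph) -> DegreeMap:
    """Degrees of every node and the network-wide maximum degree."""
    degrees = {v: int(d) for v, d in graph.degree()}
    max_degree = max(degrees.values(), default=0)
    return DegreeMap(degree=degrees, max_degree=max_degree)
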