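"""Network assembly, summary statistics and on-disk dialects.

Two text dialects are supported:

* **adjacency** — one line per node: the node ID followed by
  alternating ``neighbor<TAB>MI`` pairs; ``>``-prefixed header lines
  carry provenance.  Every node gets a line (isolated nodes too), so
  the node set survives a round trip even after heavy pruning.  Each
  undirected edge appears on both endpoint lines.
* **edge table** — a Cytoscape-importable TSV with columns
  ``node1 node2 locus1 locus2 symbol1 symbol2 mi p_value``; MI is
  printed with 6 decimals and the p-value as a decade string
  (``1e-30``), ``NA`` when unassigned.

Both writers sort deterministically so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .io import Annotation, ParseError, TFList, ValidationError
from .mi import MIEdge, make_edge

MI_DECIMALS = 6


@dataclass(frozen=True, eq=False)
class Network:
    """Undirected weighted interaction network over gene nodes.

    ``nodes`` is fixed at the pre-DPI edge incidence: pruning removes
    edges, never nodes, so node counts stay comparable across DPI
    tolerances built from the same inference run.
    """

    nodes: frozenset[str]
    edges: frozenset[MIEdge]
    tf_nodes: frozenset[str]
    dpi_epsilon: float | None = None
    annotation: Annotation | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        stray = {n for e in self.edges for n in e.pair} - self.nodes
        if stray:
            raise ValidationError(f"edge endpoints outside node set: {sorted(stray)[:5]}")
        if not self.tf_nodes <= self.nodes:
            raise ValidationError("tf_nodes must be a subset of nodes")

    # -- derived views ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def incident(self, gene_id: str) -> list[MIEdge]:
        return [e for e in self.edges if gene_id in e.pair]

    def interacting_tfs(self) -> frozenset[str]:
        """TF nodes incident to at least one edge."""
        touched = {n for e in self.edges for n in e.pair}
        return frozenset(self.tf_nodes & touched)

    def with_edges(self, edges: Iterable[MIEdge], dpi_epsilon: float | None = None) -> "Network":
        """Same node universe, different edge set (e.g. after pruning)."""
        return Network(
            nodes=self.nodes,
            edges=frozenset(edges),
            tf_nodes=self.tf_nodes,
            dpi_epsilon=self.dpi_epsilon if dpi_epsilon is None else dpi_epsilon,
            annotation=self.annotation,
            provenance=dict(self.provenance),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges):
            g.add_edge(e.a, e.b, mi=e.mi, p_decade=e.p_decade)
        return g

    def _annot(self, node: str) -> tuple[str, str]:
        """(semicolon-joined loci, semicolon-joined symbols) for a node."""
        if self.annotation is None or node not in self.annotation:
            return node, ""
        loci = self.annotation.loci(node)
        symbols = [s for s in (self.annotation.symbol(l) for l in loci) if s]
        return ";".join(loci), ";".join(symbols)

    def node_label(self, node: str) -> str:
        loci, symbols = self._annot(node)
        return symbols or loci


def build_network(
    edges: Iterable[MIEdge],
    tfs: TFList,
    annotation: Annotation | None = None,
    nodes: Iterable[str] | None = None,
    dpi_epsilon: float | None = None,
    provenance: Mapping[str, str] | None = None,
) -> Network:
    """Assemble a network from inferred edges.

    Duplicate encodings of the same undirected pair collapse to one
    stored edge (the one with the highest MI, for determinism).  When
    ``nodes`` is omitted the node set is the edge incidence.
    """
    best: dict[tuple[str, str], MIEdge] = {}
    for e in edges:
        cur = best.get(e.pair)
        if cur is None or (e.mi, e.p_decade or 0) > (cur.mi, cur.p_decade or 0):
            best[e.pair] = e
    if not best and nodes is None:
        raise ValidationError("cannot build a network from zero edges without a node set")
    edge_set = frozenset(best.values())
    node_set = frozenset(nodes) if nodes is not None else frozenset(
        n for e in edge_set for n in e.pair
    )
    if annotation is not None:
        unannotated = sorted(n for n in node_set if n not in annotation)
        if unannotated:
            warnings.warn(
                f"{len(unannotated)} node(s) missing from annotation "
                f"(e.g. {unannotated[:3]}); using locus-only labels",
                stacklevel=2,
            )
    return Network(
        nodes=node_set,
        edges=edge_set,
        tf_nodes=frozenset(t for t in tfs.ids if t in node_set),
        dpi_epsilon=dpi_epsilon,
        annotation=annotation,
        provenance=dict(provenance or {}),
    )


def network_stats(net: Network) -> tuple[int, int]:
    """(node count, edge count)."""
    return net.n_nodes, net.n_edges


# ---------------------------------------------------------------------------
# adjacency dialect
# ---------------------------------------------------------------------------


def write_adjacency(net: Network, path) -> None:
    with Path(path).open("w") as fh:
        for key in sorted(net.provenance):
            fh.write(f"> {key}\t{net.provenance[key]}\n")
        if net.dpi_epsilon is not None:
            fh.write(f"> dpi_epsilon\t{net.dpi_epsilon}\n")
        nbrs: dict[str, list[tuple[str, float]]] = {n: [] for n in net.nodes}
        for e in net.edges:
            nbrs[e.a].append((e.b, e.mi))
            nbrs[e.b].append((e.a, e.mi))
        for node in sorted(nbrs):
            parts = [node]
            for other, mi in sorted(nbrs[node]):
                parts.append(other)
                parts.append(f"{mi:.{MI_DECIMALS}f}")
            fh.write("\t".join(parts) + "\n")


def read_adjacency(path, tfs: TFList | None = None) -> Network:
    """Parse the adjacency dialect back into a :class:`Network`.

    p-value decades are not stored in this dialect, so edges come back
    with ``p_decade=None``; use the edge-table dialect when decades
    must round-trip.
    """
    nodes: set[str] = set()
    edges: dict[tuple[str, str], MIEdge] = {}
    provenance: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                kv = line[1:].strip().split("\t", 1)
                if len(kv) == 2:
                    provenance[kv[0]] = kv[1]
                continue
            tokens = line.split("\t")
            if len(tokens) % 2 != 1:
                raise ParseError(
                    f"{path}:{lineno}: expected 'node (neighbor mi)*', "
                    f"got {len(tokens)} tokens"
                )
            hub = tokens[0]
            nodes.add(hub)
            for k in range(1, len(tokens), 2):
                other = tokens[k]
                try:
                    mi = float(tokens[k + 1])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric MI '{tokens[k + 1]}'"
                    ) from None
                e = make_edge(hub, other, mi)
                prev = edges.get(e.pair)
                if prev is not None and abs(prev.mi - mi) > 10.0**-MI_DECIMALS:
                    raise ParseError(
                        f"{path}:{lineno}: conflicting MI for pair {e.pair}"
                    )
                edges[e.pair] = e
                nodes.add(other)
    eps = provenance.pop("dpi_epsilon", None)
    return Network(
        nodes=frozenset(nodes),
        edges=frozenset(edges.values()),
        tf_nodes=frozenset(tfs.intersection(nodes)) if tfs else frozenset(),
        dpi_epsilon=float(eps) if eps is not None else None,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# edge-table dialect (Cytoscape-compatible TSV)
# ---------------------------------------------------------------------------

EDGE_TABLE_COLUMNS = (
    "node1",
    "node2",
    "locus1",
    "locus2",
    "symbol1",
    "symbol2",
    "mi",
    "p_value",
)


def decade_str(p_decade: int | None) -> str:
    return "NA" if p_decade is None else f"1e{p_decade}"


def _parse_decade(text: str, where: str) -> int | None:
    if text == "NA":
        return None
    if not text.startswith("1e"):
        raise ParseError(f"{where}: bad p-value decade '{text}'")
    try:
        return int(text[2:])
    except ValueError:
        raise ParseError(f"{where}: bad p-value decade '{text}'") from None


def write_edge_table(net: Network, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for e in sorted(net.edges):
            l1, s1 = net._annot(e.a)
            l2, s2 = net._annot(e.b)
            fh.write(
                "\t".join(
                    (e.a, e.b, l1, l2, s1, s2, f"{e.mi:.{MI_DECIMALS}f}", decade_str(e.p_decade))
                )
                + "\n"
            )


def read_edge_table(path, tfs: TFList | None = None) -> Network:
    edges: set[MIEdge] = set()
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_TABLE_COLUMNS:
            raise ParseError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(EDGE_TABLE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(EDGE_TABLE_COLUMNS)} columns")
            try:
                mi = float(fields[6])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric MI '{fields[6]}'") from None
            edges.add(make_edge(fields[0], fields[1], mi, _parse_decade(fields[7], f"{path}:{lineno}")))
    nodes = frozenset(n for e in edges for n in e.pair)
    return Network(
        nodes=nodes,
        edges=frozenset(edges),
        tf_nodes=frozenset(tfs.intersection(nodes)) if tfs else frozenset(),
    )


def write_provenance(provenance: Mapping[str, object], path) -> None:
    with Path(path).open("w") as fh:
        for key in sorted(provenance):
            fh.write(f"{key}\t{provenance[key]}\n")
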