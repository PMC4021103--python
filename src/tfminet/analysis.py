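"""Downstream network interrogation.

These are the questions one asks of an inferred TF network: how many of
its TFs have independent experimental support (evidence overlap), who
are a gene's strongest partners (neighbor ranking), how does the
network organise a differential-expression hit list (induced
subnetworks, component analysis, time-course overlay), and which new
TFs does a seed module pull in (seed-gene expansion).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._util import round_half_up, round_half_up_int
from .io import EvidenceSet, TFList, ValidationError
from .mi import MIEdge
from .network import Network


# ---------------------------------------------------------------------------
# overlap reporting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    """Detected-out-of-total counts; percentages derive from the counts.

    Counts are the stored truth; ``percent`` renders half-up at one
    decimal and ``percent_int`` at integer precision (both conventions
    appear in published tables).
    """

    n_detected: int
    n_total: int

    def __post_init__(self):
        if not 0 <= self.n_detected <= self.n_total:
            raise ValidationError(
                f"need 0 <= detected ({self.n_detected}) <= total ({self.n_total})"
            )

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.n_detected / self.n_total, 1)

    @property
    def percent_int(self) -> int:
        return round_half_up_int(100.0 * self.n_detected / self.n_total)

    def __str__(self) -> str:
        return f"{self.n_detected}/{self.n_total} ({self.percent}%)"


def evidence_report(net: Network, ev: EvidenceSet) -> OverlapReport:
    """How many interacting TFs carry independent experimental support.

    The TF universe is every TF node incident to at least one edge in
    the (already pruned) network; a TF counts as detected when it
    appears in the evidence set under any source label.
    """
    interacting = net.interacting_tfs()
    if not interacting:
        raise ValidationError("network has no TF with at least one edge")
    detected = sum(1 for g in interacting if g in ev)
    return OverlapReport(n_detected=detected, n_total=len(interacting))


def overlap(list_a: Iterable[str], list_b: Iterable[str]) -> OverlapReport:
    """|A intersect B| out of |A| (A is the reference list)."""
    a = frozenset(list_a)
    if not a:
        raise ValidationError("reference list A is empty")
    b = frozenset(list_b)
    return OverlapReport(n_detected=len(a & b), n_total=len(a))


# ---------------------------------------------------------------------------
# neighbor ranking
# ---------------------------------------------------------------------------


def neighbors(net: Network, gene: str, p_cutoff_decade: int | None = None) -> list[MIEdge]:
    """Edges incident to ``gene``, strongest (highest MI) first.

    Restricted to edges at least as significant as ``p_cutoff_decade``
    when given; ties in MI break on the partner ID.  Unknown genes
    raise with closest-ID suggestions.
    """
    if gene not in net.nodes:
        hints = difflib.get_close_matches(gene, net.nodes, n=3)
        hint_txt = f"; did you mean {hints}?" if hints else ""
        raise KeyError(f"gene '{gene}' not in network{hint_txt}")
    out = [
        e
        for e in net.incident(gene)
        if p_cutoff_decade is None or (e.p_decade is not None and e.p_decade <= p_cutoff_decade)
    ]
    out.sort(key=lambda e: (-e.mi, e.other(gene)))
    return out


def neighbors_table(net: Network, gene: str, p_cutoff_decade: int | None = None) -> pd.DataFrame:
    """Neighbor ranking as a report table (locus, symbol, MI, p-value)."""
    rows = []
    for e in neighbors(net, gene, p_cutoff_decade):
        partner = e.other(gene)
        loci, symbols = net._annot(partner)
        rows.append(
            {
                "partner": partner,
                "locus": loci,
                "symbol": symbols,
                "mi": e.mi,
                "p_value": "NA" if e.p_decade is None else f"1e{e.p_decade}",
            }
        )
    return pd.DataFrame(rows, columns=["partner", "locus", "symbol", "mi", "p_value"])


# ---------------------------------------------------------------------------
# induced subnetworks of gene lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSummary:
    """Connected components of an induced subnetwork.

    ``largest_fraction_percent`` is the largest component's share of
    the *query* gene list (not of the subnetwork), half-up one decimal
    -- the convention used when reporting how much of a hit list the
    network gathers into one module.
    """

    components: tuple[frozenset[str], ...]
    n_query_genes: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def largest_size(self) -> int:
        return max((len(c) for c in self.components), default=0)

    @property
    def largest_fraction_percent(self) -> float:
        if self.n_query_genes == 0:
            return 0.0
        return round_half_up(100.0 * self.largest_size / self.n_query_genes, 1)


def induced_subnetwork(
    net: Network, genes: Iterable[str], p_cutoff_decade: int | None = None
) -> tuple[Network, ComponentSummary]:
    """Subnetwork of edges whose *both* endpoints lie in ``genes``.

    Nodes of the result are the endpoints of kept edges.  The component
    summary reports connected components sorted largest-first (size,
    then lexicographic smallest member for determinism).
    """
    query = frozenset(genes)
    if not query:
        raise ValidationError("gene list is empty")
    kept = [
        e
        for e in net.edges
        if e.a in query
        and e.b in query
        and (p_cutoff_decade is None or (e.p_decade is not None and e.p_decade <= p_cutoff_decade))
    ]
    nodes = frozenset(n for e in kept for n in e.pair)
    sub = Network(
        nodes=nodes,
        edges=frozenset(kept),
        tf_nodes=net.tf_nodes & nodes,
        dpi_epsilon=net.dpi_epsilon,
        annotation=net.annotation,
    )
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(sub.to_networkx())),
        key=lambda c: (-len(c), min(c)),
    )
    return sub, ComponentSummary(components=tuple(comps), n_query_genes=len(query))


# ---------------------------------------------------------------------------
# time-course overlay
# ---------------------------------------------------------------------------

STATES = ("down", "up")


@dataclass(frozen=True)
class TimeCourseStates:
    """Per-gene under/over-expression calls along a shared timepoint axis."""

    states: Mapping[str, tuple[str, ...]]
    timepoints: tuple[str, ...]

    def __post_init__(self):
        if len(self.timepoints) < 1:
            raise ValidationError("timepoint axis is empty")
        for g, seq in self.states.items():
            if len(seq) != len(self.timepoints):
                raise ValidationError(
                    f"gene '{g}' has {len(seq)} states for {len(self.timepoints)} timepoints"
                )
            bad = set(seq) - set(STATES)
            if bad:
                raise ValidationError(f"gene '{g}' has invalid states {sorted(bad)}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.states


def overlay_states(subnet: Network, tc: TimeCourseStates) -> pd.DataFrame:
    """Node x timepoint state table, joinable to the edge TSV.

    Nodes missing from the time course are flagged ``unknown`` at every
    timepoint rather than dropped.
    """
    if not tc.timepoints:
        raise ValidationError("timepoint axis is empty")
    rows = {
        node: list(tc.states[node]) if node in tc else ["unknown"] * len(tc.timepoints)
        for node in sorted(subnet.nodes)
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tc.timepoints))


def classify_switches(tc: TimeCourseStates) -> dict[str, frozenset[str]]:
    """Partition genes by their expression-state trajectory.

    Classes (exhaustive and mutually exclusive):

    * ``constant`` — no sign change;
    * ``down_to_up`` — exactly one change, starting down;
    * ``up_to_down`` — exactly one change, starting up;
    * ``multi_switch`` — more than one change.
    """
    if len(tc.timepoints) < 2:
        raise ValidationError("need at least two timepoints to classify switches")
    out: dict[str, set[str]] = {
        "down_to_up": set(),
        "up_to_down": set(),
        "constant": set(),
        "multi_switch": set(),
    }
    for gene, seq in tc.states.items():
        changes = sum(1 for s0, s1 in zip(seq, seq[1:]) if s0 != s1)
        if changes == 0:
            out["constant"].add(gene)
        elif changes > 1:
            out["multi_switch"].add(gene)
        elif seq[0] == "down":
            out["down_to_up"].add(gene)
        else:
            out["up_to_down"].add(gene)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# seed-gene module expansion
# ---------------------------------------------------------------------------


def seed_neighborhood(
    net: Network, seeds: Iterable[str], p_cutoff_decade: int | None = None
) -> Network:
    """All edges touching a seed gene, at the given significance cutoff.

    The result's nodes are the endpoints of kept edges (a star around
    each connected seed).  Seeds absent from the network are recorded
    under ``provenance['seeds_not_in_network']`` instead of being
    silently dropped -- hit lists routinely contain genes the platform
    never measured.
    """
    seed_set = frozenset(seeds)
    present = seed_set & net.nodes
    if not present:
        raise ValidationError("no seed gene is present in the network")
    kept = [
        e
        for e in net.edges
        if (e.a in seed_set or e.b in seed_set)
        and (p_cutoff_decade is None or (e.p_decade is not None and e.p_decade <= p_cutoff_decade))
    ]
    nodes = frozenset(n for e in kept for n in e.pair)
    missing = sorted(seed_set - net.nodes)
    prov = dict(net.provenance)
    prov["seeds_not_in_network"] = ";".join(missing)
    return Network(
        nodes=nodes,
        edges=frozenset(kept),
        tf_nodes=net.tf_nodes & nodes,
        dpi_epsilon=net.dpi_epsilon,
        annotation=net.annotation,
        provenance=prov,
    )


def candidate_new_tfs(
    neighborhood: Network, seeds: Iterable[str], tfs: TFList
) -> list[tuple[str, int, float]]:
    """Non-seed TFs in a seed neighborhood, most seed-connected first.

    Returns ``(tf, n_seed_neighbors, summed MI to seeds)`` tuples
    sorted by both criteria descending (ties break on the ID), the
    ranking used to nominate new members of a functional module.
    """
    seed_set = frozenset(seeds)
    scores: dict[str, tuple[int, float]] = {}
    for node in neighborhood.nodes:
        if node in seed_set or node not in tfs:
            continue
        touching = [e for e in neighborhood.edges if node in e.pair and e.other(node) in seed_set]
        if touching:
            scores[node] = (len(touching), sum(e.mi for e in touching))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    return [(g, n, mi_sum) for g, (n, mi_sum) in ranked]
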