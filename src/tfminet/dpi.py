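"""Data Processing Inequality pruning with tolerance and hub restriction.

For a Markov chain A -> C -> B, information theory guarantees
I(A;B) <= min(I(A;C), I(C;B)); the weakest edge of a triangle is
therefore the best candidate for an indirect interaction.  ``apply_dpi``
removes edge (A, B) when some common neighbour C of A and B in the
*input* graph satisfies

    MI(A, B) < (1 - epsilon) * min(MI(A, C), MI(C, B))

so epsilon = 0 breaks every triangle (strictest), epsilon = 1 removes
nothing, and intermediate values preserve triangles whose weakest edge
is within ``epsilon`` (fractionally) of the weaker flanking edge.  When
a hub (TF) list is supplied, only hubs may act as the mediator C, which
protects TF-TF edges from being explained away by non-TF intermediates.

All removal decisions are evaluated against the input graph and applied
simultaneously; this two-pass scheme makes the result independent of
edge enumeration order and yields the nesting property
output(eps1) subseteq output(eps2) for eps1 <= eps2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .io import TFList, ValidationError
from .mi import MIEdge


@dataclass(frozen=True)
class DpiParams:
    """Tolerance epsilon in [0, 1] plus optional hub (mediator) restriction."""

    epsilon: float
    hub_restricted: bool = False
    hubs: TFList | None = None

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValidationError(f"epsilon={self.epsilon} outside [0, 1]")
        if self.hub_restricted and (self.hubs is None or len(self.hubs) == 0):
            raise ValidationError("hub_restricted requires a non-empty hub list")

    def mediator_ok(self, gene_id: str) -> bool:
        return (not self.hub_restricted) or gene_id in self.hubs


def _validated_adjacency(edges: set[MIEdge]) -> dict[str, dict[str, float]]:
    adj: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, str]] = set()
    for e in edges:
        if e.pair in seen:
            raise ValidationError(f"duplicate edge {e.pair}")
        seen.add(e.pair)
        adj.setdefault(e.a, {})[e.b] = e.mi
        adj.setdefault(e.b, {})[e.a] = e.mi
    return adj


def apply_dpi(edges: set[MIEdge], params: DpiParams) -> set[MIEdge]:
    """Prune indirect edges by the tolerant DPI rule (two-pass).

    Strict inequality in the removal predicate means exactly tied MI
    values never trigger a removal: a perfectly symmetric triangle
    survives even at epsilon = 0.
    """
    adj = _validated_adjacency(edges)
    if params.epsilon >= 1.0:
        return set(edges)
    keep_below = 1.0 - params.epsilon
    removed: set[tuple[str, str]] = set()
    for e in edges:
        common = adj[e.a].keys() & adj[e.b].keys()
        for c in common:
            if params.mediator_ok(c) and e.mi < keep_below * min(adj[e.a][c], adj[e.b][c]):
                removed.add(e.pair)
                break
    return {e for e in edges if e.pair not in removed}


def dpi_oracle(edges: set[MIEdge], params: DpiParams) -> set[MIEdge]:
    """Brute-force reference: enumerate every node triple explicitly.

    Same contract as :func:`apply_dpi`; intended as an independent
    cross-check on small graphs (at most 1000 edges).
    """
    if len(edges) > 1000:
        raise ValidationError("dpi_oracle is for small graphs (<= 1000 edges)")
    adj = _validated_adjacency(edges)
    nodes = sorted(adj)
    if params.epsilon >= 1.0:
        return set(edges)
    keep_below = 1.0 - params.epsilon
    doomed: set[tuple[str, str]] = set()
    for x, y, z in combinations(nodes, 3):
        # all three edges present -> a triangle; test each edge with the
        # opposite vertex as mediator
        for a, b, c in ((x, y, z), (x, z, y), (y, z, x)):
            if b in adj[a] and c in adj[a] and c in adj[b]:
                if params.mediator_ok(c) and adj[a][b] < keep_below * min(adj[a][c], adj[b][c]):
                    doomed.add((a, b) if a < b else (b, a))
    return {e for e in edges if e.pair not in doomed}
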