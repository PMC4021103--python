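"""Model/Results facade over the inference pipeline.

:class:`TFNetworkModel` holds the data (expression matrix, TF list,
annotation) and the estimator configuration; :meth:`TFNetworkModel.fit`
runs rank transform -> bandwidth selection -> permutation-null
calibration -> TF-anchored MI scoring -> DPI pruning at each requested
tolerance, and returns a :class:`TFNetworkResults` carrying the
calibration coefficients, the networks, and the downstream query
methods (neighbor ranking, evidence overlap, induced subnetworks,
seed-module expansion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import __version__ as _pkg_version
from .analysis import (
    ComponentSummary,
    OverlapReport,
    TimeCourseStates,
    candidate_new_tfs,
    evidence_report,
    induced_subnetwork,
    neighbors,
    neighbors_table,
    overlay_states,
    seed_neighborhood,
)
from .dpi import DpiParams, apply_dpi
from .io import (
    Annotation,
    EvidenceSet,
    ExpressionMatrix,
    TFList,
    ValidationError,
    load_annotation,
    load_expression,
    load_tf_list,
    rank_transform,
)
from .mi import (
    DEFAULT_BANDWIDTH_CONST,
    KernelConfig,
    MAX_DECADE,
    ThresholdCalibration,
    calibrate_threshold,
    default_bandwidth,
    infer_edges,
)
from .network import Network, build_network, network_stats

MODES = ("full", "tfs_only")


class TFNetworkModel:
    """TF-anchored mutual-information network model for one matrix.

    Parameters
    ----------
    expression : ExpressionMatrix
        Normalised log-scale intensities, genes x samples.
    tf_list : TFList
        Genes allowed to anchor interactions (and, in ``full`` mode,
        to mediate DPI removals).
    annotation : Annotation, optional
        Probeset -> locus/symbol labels for exported tables.
    mode : {'full', 'tfs_only'}
        ``tfs_only`` subsets the matrix to TF rows and prunes without
        hub restriction; ``full`` keeps all genes, anchors pair
        enumeration on TFs and restricts DPI mediators to the TF list.
    bandwidth_const : float
        Constant ``c`` of the kernel bandwidth rule ``h = c*N**(-1/6)``.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        tf_list: TFList,
        annotation: Annotation | None = None,
        mode: str = "full",
        bandwidth_const: float = DEFAULT_BANDWIDTH_CONST,
    ):
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
        tf_present = tf_list.intersection(expression.gene_ids)
        if not tf_present:
            raise ValidationError("no TF from the list is present in the matrix")
        if mode == "tfs_only":
            expression = expression.subset(tf_present)
        if expression.n_genes < 2:
            raise ValidationError("need at least 2 genes for inference")
        self.expression = expression
        self.tf_list = tf_list
        self.annotation = annotation
        self.mode = mode
        self.bandwidth_const = bandwidth_const

    @classmethod
    def from_files(
        cls,
        expression_path,
        tf_list_path,
        annotation_path=None,
        mode: str = "full",
        bandwidth_const: float = DEFAULT_BANDWIDTH_CONST,
    ) -> "TFNetworkModel":
        return cls(
            load_expression(expression_path),
            load_tf_list(tf_list_path),
            load_annotation(annotation_path) if annotation_path else None,
            mode=mode,
            bandwidth_const=bandwidth_const,
        )

    def fit(
        self,
        dpi_epsilons: Sequence[float] = (0.0, 0.1, 0.2),
        p_cutoff_decade: int = MAX_DECADE,
        n_permutations: int = 2000,
        seed: int = 0,
    ) -> "TFNetworkResults":
        """Infer candidate edges and prune them at each DPI tolerance."""
        if not dpi_epsilons:
            raise ValidationError("at least one DPI tolerance is required")
        ranked = rank_transform(self.expression)
        cfg = default_bandwidth(ranked.n_samples, c=self.bandwidth_const)
        cal = calibrate_threshold(ranked.n_samples, n_permutations, cfg, seed=seed)
        candidate = infer_edges(ranked, self.tf_list, cal, cfg, p_cutoff_decade)
        provenance = {
            "mode": self.mode,
            "seed": str(seed),
            "n_samples": str(ranked.n_samples),
            "n_genes": str(ranked.n_genes),
            "bandwidth_h": f"{cfg.h:.6f}",
            "calibration_intercept": f"{cal.intercept:.6f}",
            "calibration_slope": f"{cal.slope:.6f}",
            "n_permutations": str(n_permutations),
            "p_cutoff_decade": str(p_cutoff_decade),
            "tfminet_version": _pkg_version,
        }
        base = build_network(
            candidate,
            self.tf_list,
            annotation=self.annotation,
            provenance=provenance,
            # an empty candidate set is a legitimate outcome (e.g. pure
            # noise); represent it as an empty network, not an error
            nodes=() if not candidate else None,
        )
        networks: dict[float, Network] = {}
        for eps in dpi_epsilons:
            params = DpiParams(
                epsilon=eps,
                hub_restricted=self.mode == "full",
                hubs=self.tf_list if self.mode == "full" else None,
            )
            pruned = apply_dpi(set(base.edges), params)
            networks[eps] = base.with_edges(pruned, dpi_epsilon=eps)
        return TFNetworkResults(
            model=self,
            kernel_config=cfg,
            calibration=cal,
            base_network=base,
            networks=networks,
            p_cutoff_decade=p_cutoff_decade,
            seed=seed,
        )


@dataclass(frozen=True, eq=False)
class TFNetworkResults:
    """Fitted networks plus the calibration that produced them.

    ``networks`` maps each DPI tolerance to a :class:`Network` sharing
    the pre-DPI node universe; ``base_network`` is the unpruned
    candidate set.  Downstream queries default to the strictest
    tolerance fitted.
    """

    model: TFNetworkModel
    kernel_config: KernelConfig
    calibration: ThresholdCalibration
    base_network: Network
    networks: Mapping[float, Network]
    p_cutoff_decade: int
    seed: int

    # -- selection ----------------------------------------------------
    def network(self, epsilon: float | None = None) -> Network:
        if epsilon is None:
            epsilon = min(self.networks)
        try:
            return self.networks[epsilon]
        except KeyError:
            raise KeyError(
                f"no network fitted at epsilon={epsilon}; have {sorted(self.networks)}"
            ) from None

    # -- summaries ----------------------------------------------------
    def stats(self) -> dict[float, tuple[int, int]]:
        return {eps: network_stats(net) for eps, net in sorted(self.networks.items())}

    def summary(self) -> str:
        """Human-readable fit report (statsmodels-style text table)."""
        cfg, cal = self.kernel_config, self.calibration
        lines = [
            "TF-anchored MI network inference",
            "=" * 54,
            f"mode:            {self.model.mode}",
            f"genes x samples: {self.model.expression.n_genes} x {cfg.n_samples}",
            f"TFs in matrix:   {len(self.model.tf_list.intersection(self.model.expression.gene_ids))}",
            f"bandwidth h:     {cfg.h:.6f}  (c={self.model.bandwidth_const})",
            f"null fit ln p =  {cal.intercept:.3f} + ({cal.slope:.3f}) * MI"
            f"   [{cal.n_permutations} permutations, seed {self.seed}]",
            f"MI at p=1e{self.p_cutoff_decade}: {cal.mi_at(10.0 ** self.p_cutoff_decade):.4f}",
            "-" * 54,
            f"{'DPI eps':>8} {'nodes':>8} {'edges':>8}",
        ]
        for eps, (n_nodes, n_edges) in self.stats().items():
            lines.append(f"{eps:>8.2f} {n_nodes:>8d} {n_edges:>8d}")
        lines.append("-" * 54)
        return "\n".join(lines)

    # -- downstream queries (delegate to analysis) --------------------
    def neighbors(self, gene: str, p_cutoff_decade: int | None = None, epsilon: float | None = None):
        return neighbors(self.network(epsilon), gene, p_cutoff_decade)

    def neighbors_table(self, gene: str, p_cutoff_decade: int | None = None, epsilon: float | None = None):
        return neighbors_table(self.network(epsilon), gene, p_cutoff_decade)

    def evidence_report(self, ev: EvidenceSet, epsilon: float | None = None) -> OverlapReport:
        return evidence_report(self.network(epsilon), ev)

    def induced_subnetwork(
        self, genes: Iterable[str], p_cutoff_decade: int | None = None, epsilon: float | None = None
    ) -> tuple[Network, ComponentSummary]:
        return induced_subnetwork(self.network(epsilon), genes, p_cutoff_decade)

    def overlay_states(self, subnet: Network, tc: TimeCourseStates):
        return overlay_states(subnet, tc)

    def seed_neighborhood(
        self, seeds: Iterable[str], p_cutoff_decade: int | None = None, epsilon: float | None = None
    ) -> Network:
        return seed_neighborhood(self.network(epsilon), seeds, p_cutoff_decade)

    def candidate_new_tfs(self, neighborhood: Network, seeds: Iterable[str]):
        return candidate_new_tfs(neighborhood, seeds, self.model.tf_list)

    # -- plotting ------------------------------------------------------
    def plot_network(self, epsilon: float | None = None, ax=None, seed: int = 0):
        """Spring-layout sketch of a fitted network (TFs highlighted).

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt
        import networkx as nx

        net = self.network(epsilon)
        g = net.to_networkx()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        pos = nx.spring_layout(g, seed=seed)
        colors = ["tab:red" if n in net.tf_nodes else "tab:gray" for n in g.nodes]
        widths = [1.0 + 2.0 * d["mi"] for _, _, d in g.edges(data=True)]
        nx.draw_networkx(
            g, pos=pos, ax=ax, node_color=colors, node_size=60,
            width=widths, with_labels=False, edge_color="0.6",
        )
        ax.set_title(f"DPI eps={net.dpi_epsilon}  ({net.n_nodes} nodes, {net.n_edges} edges)")
        ax.set_axis_off()
        return ax
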