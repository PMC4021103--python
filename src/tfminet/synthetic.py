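"""Synthetic expression matrices with planted regulatory architecture.

The generator emulates the statistical skeleton of a compendium of
normalised microarray intensities: continuous log-scale values,
TF hubs driving target sets through noisy monotone (possibly
saturating) links, groups of near-redundant TF paralogs, TF -> TF ->
target cascades (which create exactly the triangles DPI is meant to
break), and independent background genes.  Alongside the matrix it
emits the ground truth — planted direct edges, module memberships and
mediated (indirect) pairs — plus companion evidence and time-course
fixtures, so every downstream stage of the pipeline can be scored
without external data.

Gene identifiers follow an AGI-like scheme (``SYN1G00010``) so that
annotation code paths are exercised by synthetic runs too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import round_half_up_int
from .analysis import TimeCourseStates
from .io import (
    Annotation,
    EvidenceSet,
    EVIDENCE_SOURCES,
    ExpressionMatrix,
    TFList,
    ValidationError,
)

LINKS = ("linear", "sigmoid", "mixed")


@dataclass(frozen=True)
class GrnSpec:
    """Architecture of a planted gene regulatory network.

    Defaults describe a small benchmark: 10 TF hubs with 5 targets
    each, two 3-member paralog groups, three two-step cascades, 50
    background genes, 200 samples and additive Gaussian noise of 0.3
    on a unit-variance signal (log-intensity units).
    """

    n_tf_hubs: int = 10
    targets_per_hub: int = 5
    n_paralog_groups: int = 2
    paralog_group_size: int = 3
    n_cascades: int = 3
    n_background: int = 50
    n_samples: int = 200
    link: str = "mixed"
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for f in fields(self):
            if f.name in ("link", "noise_sd", "seed"):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{f.name} must be a non-negative integer, got {v!r}")
        if self.n_samples < 20:
            raise ValidationError(f"n_samples must be >= 20, got {self.n_samples}")
        if self.link not in LINKS:
            raise ValidationError(f"link must be one of {LINKS}, got {self.link!r}")
        if not self.noise_sd > 0:
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.n_paralog_groups > 0 and self.paralog_group_size < 1:
            raise ValidationError("paralog_group_size must be >= 1 when groups are requested")

    @property
    def n_genes(self) -> int:
        return (
            self.n_tf_hubs * (1 + self.targets_per_hub)
            + self.n_paralog_groups * self.paralog_group_size
            + 3 * self.n_cascades
            + self.n_background
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure accompanying a generated matrix.

    ``direct_edges`` are ordered (regulator, target) pairs with a real
    generative mechanism; ``indirect_pairs`` are unordered pairs linked
    only through a mediator (stored as sorted tuples) — conditionally
    independent given that mediator by construction; ``module_members``
    groups genes by planted module; ``tf_ids`` lists every gene playing
    a TF role (hubs, paralogs, cascade TFs); ``symbols`` carries the
    human-readable role labels used for the synthetic annotation.
    """

    direct_edges: frozenset[tuple[str, str]]
    indirect_pairs: frozenset[tuple[str, str]]
    module_members: Mapping[str, frozenset[str]]
    tf_ids: frozenset[str]
    symbols: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        undirected_direct = {tuple(sorted(p)) for p in self.direct_edges}
        clash = undirected_direct & set(self.indirect_pairs)
        if clash:
            raise ValidationError(f"pairs both direct and indirect: {sorted(clash)[:5]}")

    @property
    def direct_pairs_unordered(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(p)) for p in self.direct_edges)


def _gene_id(k: int) -> str:
    """AGI-like identifier: chromosome cycles 1..5, position k*10."""
    return f"SYN{k % 5 + 1}G{(k + 1) * 10:05d}"


def generate_grn(spec: GrnSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw an expression matrix with the planted architecture of ``spec``.

    Hub and latent profiles are i.i.d. standard normal per sample.
    Each target is ``link(parent) + N(0, noise_sd)``; the sigmoid link
    is ``tanh`` with unit gain (saturating yet monotone, so the
    dependence is nonlinear but rank-preserving); ``mixed`` alternates
    linear and sigmoid per planted edge.  Cascades chain
    TF1 -> TF2 -> target with no direct TF1 -> target mechanism, and
    record (TF1, target) as an indirect pair.  Identical specs (same
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    rows: list[np.ndarray] = []
    ids: list[str] = []
    symbols: dict[str, str] = {}
    direct: set[tuple[str, str]] = set()
    indirect: set[tuple[str, str]] = set()
    modules: dict[str, set[str]] = {}
    tf_ids: set[str] = set()

    link_counter = 0

    def apply_link(x: np.ndarray) -> np.ndarray:
        nonlocal link_counter
        kind = spec.link
        if kind == "mixed":
            kind = "linear" if link_counter % 2 == 0 else "sigmoid"
        link_counter += 1
        return x if kind == "linear" else np.tanh(x)

    def add_row(symbol: str, values: np.ndarray) -> str:
        gid = _gene_id(len(ids))
        ids.append(gid)
        rows.append(values)
        symbols[gid] = symbol
        return gid

    for h in range(spec.n_tf_hubs):
        hub_profile = rng.standard_normal(n)
        hub = add_row(f"HUB{h + 1}", hub_profile)
        tf_ids.add(hub)
        members = {hub}
        for t in range(spec.targets_per_hub):
            profile = apply_link(hub_profile) + spec.noise_sd * rng.standard_normal(n)
            tgt = add_row(f"HUB{h + 1}T{t + 1}", profile)
            direct.add((hub, tgt))
            members.add(tgt)
        modules[f"hub_{h + 1}"] = members

    for g in range(spec.n_paralog_groups):
        latent = rng.standard_normal(n)
        members = set()
        for m in range(spec.paralog_group_size):
            profile = latent + spec.noise_sd * rng.standard_normal(n)
            par = add_row(f"PG{g + 1}M{m + 1}", profile)
            tf_ids.add(par)
            members.add(par)
        modules[f"paralog_group_{g + 1}"] = members

    for c in range(spec.n_cascades):
        p1 = rng.standard_normal(n)
        p2 = apply_link(p1) + spec.noise_sd * rng.standard_normal(n)
        p3 = apply_link(p2) + spec.noise_sd * rng.standard_normal(n)
        tf1 = add_row(f"CAS{c + 1}TF1", p1)
        tf2 = add_row(f"CAS{c + 1}TF2", p2)
        tgt = add_row(f"CAS{c + 1}TG", p3)
        tf_ids.update((tf1, tf2))
        direct.add((tf1, tf2))
        direct.add((tf2, tgt))
        indirect.add(tuple(sorted((tf1, tgt))))
        modules[f"cascade_{c + 1}"] = {tf1, tf2, tgt}

    for b in range(spec.n_background):
        add_row(f"BG{b + 1}", rng.standard_normal(n))

    matrix = ExpressionMatrix(
        np.vstack(rows) if rows else np.empty((0, n)),
        ids,
        [f"S{j + 1:04d}" for j in range(n)],
    )
    truth = SyntheticTruth(
        direct_edges=frozenset(direct),
        indirect_pairs=frozenset(indirect),
        module_members={k: frozenset(v) for k, v in modules.items()},
        tf_ids=frozenset(tf_ids),
        symbols=symbols,
    )
    return matrix, truth


def synthetic_annotation(truth: SyntheticTruth) -> Annotation:
    """One-to-one probeset/locus annotation with role symbols."""
    return Annotation(
        probeset_to_loci={g: (g,) for g in truth.symbols},
        locus_to_symbol=dict(truth.symbols),
    )


def generate_evidence(
    truth: SyntheticTruth, detected_fraction: float, seed: int = 0
) -> EvidenceSet:
    """Mark a fraction of the planted TFs as experimentally detected.

    Exactly ``round(detected_fraction * |TF set|)`` TFs (half-up) are
    sampled without replacement; each detected TF receives a non-empty
    random subset of the evidence-source vocabulary.
    """
    if not 0.0 <= detected_fraction <= 1.0:
        raise ValidationError(f"detected_fraction {detected_fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    tf_sorted = sorted(truth.tf_ids)
    n_detect = round_half_up_int(detected_fraction * len(tf_sorted))
    chosen = rng.choice(tf_sorted, size=n_detect, replace=False) if n_detect else []
    genes: dict[str, frozenset[str]] = {}
    for g in sorted(chosen):
        labels = {lbl for lbl in EVIDENCE_SOURCES if rng.random() < 0.5}
        if not labels:
            labels = {EVIDENCE_SOURCES[rng.integers(len(EVIDENCE_SOURCES))]}
        genes[g] = frozenset(labels)
    return EvidenceSet(genes)


def generate_timecourse(
    genes: Sequence[str],
    n_timepoints: int,
    switch_fraction: float,
    seed: int = 0,
    timepoint_labels: Sequence[str] | None = None,
) -> TimeCourseStates:
    """Per-timepoint up/down states with a planted fraction of switchers.

    ``switch_fraction`` of the genes (half-up count) change sign
    exactly once at a random interior timepoint; the rest keep a
    constant state.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene list is empty")
    if n_timepoints < 2:
        raise ValidationError(f"n_timepoints must be >= 2, got {n_timepoints}")
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValidationError(f"switch_fraction {switch_fraction} outside [0, 1]")
    if timepoint_labels is None:
        timepoint_labels = tuple(f"t{i + 1}" for i in range(n_timepoints))
    elif len(timepoint_labels) != n_timepoints:
        raise ValidationError("timepoint_labels length must equal n_timepoints")
    rng = np.random.default_rng(seed)
    ordered = sorted(genes)
    n_switch = round_half_up_int(switch_fraction * len(ordered))
    switchers = set(rng.choice(ordered, size=n_switch, replace=False)) if n_switch else set()
    states: dict[str, tuple[str, ...]] = {}
    for g in ordered:
        first = "down" if rng.random() < 0.5 else "up"
        if g in switchers:
            cut = int(rng.integers(1, n_timepoints))
            second = "up" if first == "down" else "down"
            states[g] = tuple([first] * cut + [second] * (n_timepoints - cut))
        else:
            states[g] = tuple([first] * n_timepoints)
    return TimeCourseStates(states=states, timepoints=tuple(timepoint_labels))


# ---------------------------------------------------------------------------
# writers (tab-delimited companions)
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path) -> None:
    """Edge list: regulator, target, kind (direct / indirect-unordered)."""
    with Path(path).open("w") as fh:
        fh.write("regulator\ttarget\tkind\n")
        for a, b in sorted(truth.direct_edges):
            fh.write(f"{a}\t{b}\tdirect\n")
        for a, b in sorted(truth.indirect_pairs):
            fh.write(f"{a}\t{b}\tindirect\n")


def write_modules(truth: SyntheticTruth, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("module\tgene\n")
        for mod in sorted(truth.module_members):
            for g in sorted(truth.module_members[mod]):
                fh.write(f"{mod}\t{g}\n")


def write_evidence(ev: EvidenceSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tsources\n")
        for g in sorted(ev.genes):
            fh.write(f"{g}\t{';'.join(sorted(ev.genes[g]))}\n")


def write_timecourse(tc: TimeCourseStates, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(tc.timepoints) + "\n")
        for g in sorted(tc.states):
            fh.write(f"{g}\t" + "\t".join(tc.states[g]) + "\n")


def truth_tf_list(truth: SyntheticTruth) -> TFList:
    return TFList(frozenset(truth.tf_ids))
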