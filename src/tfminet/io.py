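"""Expression matrices, TF lists, annotation and evidence tables.

All on-disk formats are plain tab-delimited text:

* expression matrix — first column gene/probeset ID, header row of
  sample IDs, one gene per row, log-scale intensities;
* TF list — one ID per line, ``#`` comments allowed;
* annotation — columns ``probeset``, ``locus``, ``symbol`` (symbol may
  be empty; a probeset may repeat with several loci);
* evidence lists — one ID per line, one file per evidence source.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class ParseError(ValueError):
    """Malformed input file; the message carries file coordinates."""


class ValidationError(ValueError):
    """Input violates a structural precondition."""


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes x samples matrix of finite log-scale intensities.

    Parameters
    ----------
    values : (G, N) array of float
    gene_ids, sample_ids : sequences of unique identifiers

    The matrix is the substrate for network inference; for that use it
    must have at least 2 genes and at least 20 samples (enforced by the
    inference entry points, not here, so that tiny matrices remain
    constructible for IO round-trips).
    """

    def __init__(self, values, gene_ids, sample_ids):
        values = np.asarray(values, dtype=float)
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(gene_ids)} genes "
                f"x {len(sample_ids)} samples"
            )
        for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene '{gene_ids[i]}', sample '{sample_ids[j]}'"
            )
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self._row_index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic container protocol ------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene ID '{gene_id}'") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row_index

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving the matrix's own gene order."""
        keep = set(gene_ids)
        missing = keep - set(self.gene_ids)
        if missing:
            raise ValidationError(f"gene IDs not in matrix: {sorted(missing)[:5]}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return type(self)(self.values[idx], [self.gene_ids[i] for i in idx], self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


class RankedMatrix(ExpressionMatrix):
    """Row-wise copula-transformed matrix: every row lies in (0, 1).

    A row without ties is a permutation of ``(k - 0.5)/N, k = 1..N``;
    tied values share the mean of the ranks they span.
    """

    def __init__(self, values, gene_ids, sample_ids):
        super().__init__(values, gene_ids, sample_ids)
        if self.values.size and (self.values.min() <= 0.0 or self.values.max() >= 1.0):
            raise ValidationError("ranked values must lie strictly inside (0, 1)")


def load_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (genes x samples).

    Raises :class:`ParseError` naming the offending gene/sample
    coordinate for empty or non-numeric cells, and the offending ID for
    duplicated gene rows or sample columns.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
    columns = header.split("\t")[1:]
    dupes = _duplicates(columns)
    if dupes:
        raise ParseError(f"{path}: duplicate sample columns: {sorted(dupes)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = columns  # undo pandas' mangling of duplicate names
    dupes = _duplicates(list(raw.index))
    if dupes:
        raise ParseError(f"{path}: duplicate gene rows: {sorted(dupes)}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = (raw == "") | numeric.isna().to_numpy()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[i, j]
        what = "empty cell" if cell == "" else f"non-numeric cell '{cell}'"
        raise ParseError(
            f"{path}: {what} at gene '{raw.index[i]}', sample '{columns[j]}'"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(m: ExpressionMatrix, path, float_fmt: str = "%.6f") -> None:
    m.to_dataframe().to_csv(path, sep="\t", float_format=float_fmt, index_label="gene")


def rank_transform(m: ExpressionMatrix) -> RankedMatrix:
    """Copula (rank) transform applied independently to each row.

    Each row's values are replaced by ``(rank - 0.5) / N`` with mean
    ranks for ties, mapping into the open interval (0, 1).  The output
    is invariant under strictly increasing per-row transforms, which is
    what makes the downstream kernel MI estimate insensitive to
    monotone normalisation distortions.

    Constant rows are rejected: mutual information against a
    degenerate (single-atom) variable is not informative and the rank
    map would collapse to a single value.
    """
    n = m.n_samples
    out = np.empty_like(m.values)
    for i, row in enumerate(m.values):
        if np.ptp(row) == 0.0:
            raise ValidationError(
                f"constant row '{m.gene_ids[i]}': rank transform undefined; "
                "drop the gene before inference"
            )
        out[i] = (rankdata(row) - 0.5) / n
    return RankedMatrix(out, list(m.gene_ids), list(m.sample_ids))


# ---------------------------------------------------------------------------
# TF lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFList:
    """Set of gene/probeset IDs designated as transcription factors."""

    ids: frozenset[str]

    def __post_init__(self):
        if not self.ids:
            raise ValidationError("TF list is empty")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ids

    def __iter__(self):
        return iter(sorted(self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def intersection(self, gene_ids: Iterable[str]) -> frozenset[str]:
        return self.ids & frozenset(gene_ids)


def build_tf_list(sources: Iterable[Iterable[str]], ontology_ids: Iterable[str] = ()) -> TFList:
    """Union of several TF databases plus ontology-derived IDs.

    Mirrors the practice of merging curated TF databases (which
    disagree on family boundaries, e.g. whether Aux/IAA proteins
    count) and topping up with genes carrying a sequence-specific
    DNA-binding transcription-factor-activity ontology annotation.
    """
    sources = [frozenset(s) for s in sources]
    if not sources:
        raise ValidationError("at least one TF source is required")
    ids = frozenset().union(*sources, frozenset(ontology_ids))
    if not ids:
        raise ValidationError("all TF sources are empty")
    return TFList(ids)


def load_tf_list(path) -> TFList:
    ids = set()
    with Path(path).open() as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    if not ids:
        raise ParseError(f"{path}: no TF IDs found")
    return TFList(frozenset(ids))


def write_tf_list(tfs: TFList, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(tfs.ids)))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Annotation:
    """Probeset -> locus mapping with optional locus -> symbol labels.

    A probeset may map to several loci (cross-hybridising probes); all
    mappings are kept and join with ';' in exported tables.  Lookups of
    unknown probesets fail loudly -- silently dropping rows is how
    annotation bugs hide.
    """

    probeset_to_loci: Mapping[str, tuple[str, ...]]
    locus_to_symbol: Mapping[str, str] = field(default_factory=dict)

    def loci(self, probeset: str) -> tuple[str, ...]:
        try:
            return self.probeset_to_loci[probeset]
        except KeyError:
            raise KeyError(f"probeset '{probeset}' not in annotation") from None

    def symbol(self, locus: str) -> str | None:
        return self.locus_to_symbol.get(locus)

    def label(self, probeset: str) -> str:
        """Best human-readable label: symbol(s) if known, else loci."""
        loci = self.loci(probeset)
        symbols = [self.locus_to_symbol.get(l) or l for l in loci]
        return ";".join(symbols)

    def __contains__(self, probeset: str) -> bool:
        return probeset in self.probeset_to_loci


def load_annotation(path) -> Annotation:
    """Read a tab-delimited table with columns probeset, locus, symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probeset", "locus"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: annotation needs columns {sorted(required)}")
    p2l: dict[str, list[str]] = {}
    l2s: dict[str, str] = {}
    for row in df.itertuples(index=False):
        p2l.setdefault(row.probeset, [])
        if row.locus and row.locus not in p2l[row.probeset]:
            p2l[row.probeset].append(row.locus)
        symbol = getattr(row, "symbol", "")
        if symbol:
            l2s[row.locus] = symbol
    bad = [p for p, loci in p2l.items() if not loci]
    if bad:
        raise ParseError(f"{path}: probesets without a locus: {sorted(bad)[:5]}")
    return Annotation({p: tuple(l) for p, l in p2l.items()}, l2s)


def write_annotation(ann: Annotation, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probeset\tlocus\tsymbol\n")
        for p in sorted(ann.probeset_to_loci):
            for locus in ann.probeset_to_loci[p]:
                fh.write(f"{p}\t{locus}\t{ann.locus_to_symbol.get(locus, '')}\n")


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

#: canonical vocabulary of experimental-support sources
EVIDENCE_SOURCES = ("rt_pcr", "proteomics", "ontology", "rna_seq")


@dataclass(frozen=True)
class EvidenceSet:
    """Per-gene experimental-support labels (e.g. which screens saw it)."""

    genes: Mapping[str, frozenset[str]]
    vocabulary: tuple[str, ...] = EVIDENCE_SOURCES

    def __post_init__(self):
        vocab = set(self.vocabulary)
        for g, labels in self.genes.items():
            extra = set(labels) - vocab
            if extra:
                raise ValidationError(
                    f"gene '{g}' carries labels outside the vocabulary: {sorted(extra)}"
                )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def labels(self, gene_id: str) -> frozenset[str]:
        return self.genes.get(gene_id, frozenset())


def build_evidence_set(lists: Mapping[str, Iterable[str]]) -> EvidenceSet:
    """Combine one ID list per evidence source into a per-gene label map."""
    if not lists:
        raise ValidationError("at least one labeled evidence list is required")
    genes: dict[str, set[str]] = {}
    for label, ids in lists.items():
        for g in ids:
            genes.setdefault(g, set()).add(label)
    return EvidenceSet({g: frozenset(v) for g, v in genes.items()}, tuple(lists))


def load_evidence_lists(paths: Mapping[str, object]) -> EvidenceSet:
    """Build an evidence set from one file per source (one ID per line)."""
    lists = {}
    for label, path in paths.items():
        with Path(path).open() as fh:
            lists[label] = {t for t in (l.split("#", 1)[0].strip() for l in fh) if t}
    return build_evidence_set(lists)


def _duplicates(items: list[str]) -> set[str]:
    seen, dupes = set(), set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes
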