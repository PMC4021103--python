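"""Gaussian-kernel mutual information and permutation-null calibration.

The estimator operates on copula-transformed (rank) data in (0, 1):

    I(X;Y) ~= (1/N) * sum_i ln[ f2(x_i, y_i) / (f1(x_i) * f1(y_i)) ]

with f1 and f2 Gaussian kernel density estimates of the marginals and
the joint, sharing a single bandwidth ``h`` in rank space.  Because the
inputs are ranks, the estimate is invariant to any strictly monotone
transform of the raw expression values.

Significance is calibrated from a permutation null: MI is computed for
many pairs of independently shuffled rank vectors, and the upper tail
of the resulting null distribution is summarised by a least-squares fit

    ln p = a + b * MI        (b < 0)

which is then *extrapolated* far beyond the permutation range to
express edge significance as p-value decades (1e-20 ... 1e-140).  The
extrapolation is an explicit modelling choice, inherited from the
information-theoretic network-inference tradition this package follows;
it is surfaced in :class:`ThresholdCalibration` rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import RankedMatrix, TFList, ValidationError

#: default constant of the bandwidth rule h = c * N**(-1/6)
DEFAULT_BANDWIDTH_CONST = 0.25

#: smallest usable sample count for kernel MI inference
MIN_SAMPLES = 20

#: reporting clamps for p-value decades
MAX_DECADE = -20
MIN_DECADE = -140


@dataclass(frozen=True)
class KernelConfig:
    """Kernel bandwidth (rank-space units) tied to a sample count."""

    h: float
    n_samples: int

    def __post_init__(self):
        if not self.h > 0:
            raise ValidationError("bandwidth h must be positive")
        if self.n_samples < MIN_SAMPLES:
            raise ValidationError(
                f"n_samples={self.n_samples} below the minimum of {MIN_SAMPLES}"
            )


def default_bandwidth(n_samples: int, c: float = DEFAULT_BANDWIDTH_CONST) -> KernelConfig:
    """Deterministic bandwidth rule ``h = c * N**(-1/6)``.

    A Silverman-type rate for a bivariate density estimate, applied in
    rank space where the marginals are uniform; ``c`` defaults to 0.25.
    The bandwidth shrinks as the sample count grows.
    """
    if n_samples < MIN_SAMPLES:
        raise ValidationError(
            f"kernel MI needs at least {MIN_SAMPLES} samples, got {n_samples}"
        )
    return KernelConfig(h=c * float(n_samples) ** (-1.0 / 6.0), n_samples=n_samples)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


def _kernel_matrix(v: np.ndarray, h: float) -> np.ndarray:
    d = v[:, None] - v[None, :]
    return np.exp(d * d / (-2.0 * h * h))


def _mi_from_kernels(kx: np.ndarray, ky: np.ndarray, h: float) -> float:
    # marginal and joint KDE evaluated at the data points; the kernel
    # normalisation constants cancel inside the log except for a single
    # additive term, but keeping them explicit keeps the code readable.
    fx = kx.mean(axis=1) / (math.sqrt(2.0 * math.pi) * h)
    fy = ky.mean(axis=1) / (math.sqrt(2.0 * math.pi) * h)
    f2 = (kx * ky).mean(axis=1) / (2.0 * math.pi * h * h)
    mi = float(np.mean(np.log(f2 / (fx * fy))))
    return max(0.0, mi)


def kernel_mi(x: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> float:
    """Mutual information (nats) between two rank vectors in (0, 1).

    Symmetric in its arguments and clamped at zero from below.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"rank vectors must share one length, got {x.shape} / {y.shape}")
    if len(x) != cfg.n_samples:
        raise ValidationError(f"vectors of length {len(x)} but config expects {cfg.n_samples}")
    for name, v in (("x", x), ("y", y)):
        if v.min() <= 0.0 or v.max() >= 1.0:
            raise ValidationError(f"{name} must lie strictly inside (0, 1); rank-transform first")
    return _mi_from_kernels(_kernel_matrix(x, cfg.h), _kernel_matrix(y, cfg.h), cfg.h)


# ---------------------------------------------------------------------------
# permutation-null calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdCalibration:
    """Fitted null tail ``ln p = a + b * MI`` at a given sample count.

    ``mi_at(p)`` inverts the fit to the MI threshold for a target
    p-value; ``p_at(mi)`` evaluates it.  The fit is anchored on the
    upper tail of the permutation null and extrapolated to the extreme
    decades used for reporting.
    """

    intercept: float
    slope: float
    n_samples: int
    n_permutations: int
    seed: int
    tail_fraction: float = 0.1
    null_sample: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.slope < 0:
            raise ValidationError("calibration slope must be negative")

    def p_at(self, mi: float) -> float:
        if mi < 0:
            raise ValidationError("MI must be non-negative")
        return min(1.0, math.exp(self.intercept + self.slope * mi))

    def mi_at(self, p: float) -> float:
        if not 0.0 < p <= 1.0:
            raise ValidationError("p must lie in (0, 1]")
        return (math.log(p) - self.intercept) / self.slope


def null_mi_sample(
    n_samples: int, n_draws: int, cfg: KernelConfig, rng: np.random.Generator
) -> np.ndarray:
    """MI values for pairs of independently permuted rank vectors."""
    grid = (np.arange(1, n_samples + 1) - 0.5) / n_samples
    out = np.empty(n_draws)
    for i in range(n_draws):
        x = rng.permutation(grid)
        y = rng.permutation(grid)
        out[i] = _mi_from_kernels(_kernel_matrix(x, cfg.h), _kernel_matrix(y, cfg.h), cfg.h)
    return out


def calibrate_threshold(
    n_samples: int,
    n_permutations: int,
    cfg: KernelConfig | None = None,
    seed: int = 0,
    tail_fraction: float = 0.1,
) -> ThresholdCalibration:
    """Fit the MI <-> p-value map from a permutation null.

    Draws ``n_permutations`` null MI values from independently shuffled
    rank vectors of length ``n_samples``, assigns each sorted value its
    empirical tail probability, and fits ``ln p = a + b * MI`` by least
    squares over the top ``tail_fraction`` of the null.  Identical
    seeds give identical coefficients.
    """
    if n_permutations < 1000:
        raise ValidationError("need at least 1000 permutations for a stable tail fit")
    if cfg is None:
        cfg = default_bandwidth(n_samples)
    rng = np.random.default_rng(seed)
    null = np.sort(null_mi_sample(n_samples, n_permutations, cfg, rng))[::-1]
    m = max(20, int(tail_fraction * n_permutations))
    tail_mi = null[:m]
    tail_logp = np.log(np.arange(1, m + 1) / n_permutations)
    slope, intercept = np.polyfit(tail_mi, tail_logp, 1)
    if slope >= 0:
        raise ValidationError(
            "degenerate null-tail fit (non-negative slope); "
            "increase n_permutations or check the input ranks"
        )
    return ThresholdCalibration(
        intercept=float(intercept),
        slope=float(slope),
        n_samples=n_samples,
        n_permutations=n_permutations,
        seed=seed,
        tail_fraction=tail_fraction,
        null_sample=null[::-1].copy(),
    )


def p_decade(
    mi: float,
    cal: ThresholdCalibration,
    max_decade: int = MAX_DECADE,
    min_decade: int = MIN_DECADE,
) -> int | None:
    """Power-of-ten significance bucket for an MI value.

    Returns the tightest multiple-of-10 exponent ``e`` with
    ``p(mi) <= 10**e``, clamped to ``[min_decade, max_decade]``.
    Values whose p exceeds ``10**max_decade`` are not significant and
    map to ``None``.
    """
    if mi < 0:
        raise ValidationError("MI must be non-negative")
    p = cal.p_at(mi)
    if p > 10.0**max_decade:
        return None
    if p == 0.0:
        return min_decade
    # small tolerance so that mi_at(1e-30) maps to -30 despite float noise
    e = 10 * math.ceil(math.log10(p) / 10.0 - 1e-9)
    return max(min_decade, min(max_decade, e))


# ---------------------------------------------------------------------------
# TF-anchored edge inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class MIEdge:
    """Undirected interaction between two genes.

    Endpoints are stored lexicographically (``a < b``); ``p_decade`` is
    the integer exponent of the reported p-value decade (e.g. -30 for
    1e-30), or ``None`` when significance has not been assigned (as
    after reading a raw adjacency file).
    """

    a: str
    b: str
    mi: float
    p_decade: int | None = None

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError(f"self-loop on '{self.a}'")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)
        if self.mi < 0:
            raise ValidationError("MI must be non-negative")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    def other(self, gene_id: str) -> str:
        if gene_id == self.a:
            return self.b
        if gene_id == self.b:
            return self.a
        raise KeyError(f"'{gene_id}' is not an endpoint of {self.pair}")


def make_edge(a: str, b: str, mi: float, p_decade: int | None = None) -> MIEdge:
    """Canonical edge constructor (endpoints sorted)."""
    if a > b:
        a, b = b, a
    return MIEdge(a, b, mi, p_decade)


# above this many matrix elements the per-TF kernel cache is skipped to
# bound memory; pairs are then computed one at a time
_CACHE_ELEMENT_LIMIT = 150_000_000


def infer_edges(
    m: RankedMatrix,
    tfs: TFList,
    cal: ThresholdCalibration,
    cfg: KernelConfig | None = None,
    p_cutoff_decade: int = MAX_DECADE,
) -> set[MIEdge]:
    """TF-anchored candidate edges above a significance cutoff.

    Evaluates exactly the unordered gene pairs with at least one TF
    member (TF-TF pairs and TF-nonTF pairs; nonTF-nonTF pairs are never
    scored), keeps those whose p-value decade is at least as extreme as
    ``p_cutoff_decade``, and returns them as canonical edges.
    """
    if cfg is None:
        cfg = default_bandwidth(m.n_samples)
    if cfg.n_samples != m.n_samples:
        raise ValidationError("kernel config sample count does not match the matrix")
    tf_in = sorted(tfs.intersection(m.gene_ids))
    if not tf_in:
        raise ValidationError("no TF from the list is present in the matrix")
    others = sorted(set(m.gene_ids) - set(tf_in))
    h = cfg.h

    use_cache = len(tf_in) * m.n_samples**2 <= _CACHE_ELEMENT_LIMIT
    kmat: dict[str, np.ndarray] = {}

    def K(g: str) -> np.ndarray:
        if not use_cache:
            return _kernel_matrix(m.row(g), h)
        if g not in kmat:
            kmat[g] = _kernel_matrix(m.row(g), h)
        return kmat[g]

    edges: set[MIEdge] = set()

    def consider(a: str, b: str, ka: np.ndarray, kb: np.ndarray) -> None:
        mi = _mi_from_kernels(ka, kb, h)
        dec = p_decade(mi, cal)
        if dec is not None and dec <= p_cutoff_decade:
            edges.add(make_edge(a, b, mi, dec))

    for i, t1 in enumerate(tf_in):
        k1 = K(t1)
        for t2 in tf_in[i + 1 :]:
            consider(t1, t2, k1, K(t2))
    for g in others:
        kg = _kernel_matrix(m.row(g), h)
        for t in tf_in:
            consider(t, g, K(t), kg)
    return edges
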