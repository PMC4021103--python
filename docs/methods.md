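# Methods

## Scope and model

`tfminet` infers undirected candidate transcriptional interactions
from a normalised expression matrix by (1) scoring every TF-anchored
gene pair with a kernel estimate of mutual information on
rank-transformed profiles, (2) converting MI to a significance decade
via a permutation-null calibration, and (3) removing likely-indirect
edges with a tolerant Data Processing Inequality (DPI) rule.  The
statistical model is deliberately minimal: no directionality, no
conditional independence testing beyond triangles, no dynamics.  An
edge means "these two profiles share information that survives the
null calibration and is not better explained through a third gene".

Assumptions the user buys into:

- samples are exchangeable draws from a single underlying regulatory
  regime (the method sees a compendium, not a time series; a
  time-course overlay is a *post hoc* annotation, not part of the
  likelihood);
- dependence of interest is monotone enough that rank-space MI finds
  it (the copula transform discards marginal shape on purpose);
- TFs are known in advance; pairs without a TF are never scored, so
  the output is a TF-anchored network, not a full gene-gene graph.

## Estimator

Profiles are ranked row-wise to `(k − ½)/N` with mean ranks for ties.
MI is estimated as the sample average of the log density ratio
`ln f₂/(f₁·f₁)` under Gaussian kernel density estimates sharing one
bandwidth `h`, clamped at 0 from below.  The estimator includes the
self-term of the KDE and applies no boundary correction on (0, 1);
both introduce a mild bias (order +0.01 nats near independence, up to
roughly −0.1 nats at very strong dependence, where smoothing flattens
the concentrated joint density).  The acceptance checks quantify this
against the bivariate-normal closed form −½·ln(1−ρ²): at N = 2000 the
worst deviation across ρ ∈ {0, 0.3, 0.6, 0.9} stays within ±0.15 nats.
Downstream decisions are threshold- and order-based, so a smooth,
monotone bias of this size does not change which edges rank above
which.

### Bandwidth

`h = c·N^(−1/6)` rank-space units, default `c = 0.25`.  The rate is
the standard bivariate-KDE rate; the constant was fixed once for rank
(near-uniform) marginals.  Deterministic by design — two runs on the
same matrix always use the same kernel.  A guard refuses N < 20:
below that, kernel density MI is mostly noise.

## Null calibration and p-value decades

The null is MI between pairs of independently permuted rank grids of
length N — exactly the statistic's distribution under no association.
With `n_permutations ≥ 1000` draws (default 2000), the top decile
(at least 20 points) is fitted by least squares as `ln p = a + b·MI`.
Points carry empirical tail probabilities k/n, so the fit anchors the
region p ∈ (0, 0.1]; thresholds for p down to ~1/n are interpolation,
everything beyond — including all reported decades — is an explicit
exponential-tail extrapolation.  That extrapolation is a modelling
commitment inherited from the MI-network tradition this package
follows, and it is surfaced (coefficients in every provenance file and
summary) rather than hidden.  A non-negative fitted slope aborts with
advice to add permutations.

Edge significance is reported as decades: the tightest multiple-of-10
exponent `e` with `p ≤ 10^e`, clamped to [−140, −20].  p-values above
1e-20 are "not significant" and the pair is dropped.  Both clamps are
configurable constants.  The coverage of the fitted map is checked on
a fresh null sample at p ∈ {0.05, 0.01, 1e-3} (inside and just beyond
the fitted region); agreement is within a few hundredths, limited by
the mild curvature of the true tail against the fitted straight line.

## DPI pruning

Edge (A,B) is removed iff some common neighbour C *in the input graph*
satisfies `MI(A,B) < (1−ε)·min(MI(A,C), MI(C,B))`, with C restricted
to the hub (TF) list when hub restriction is on.  Implementation
choices that matter:

- **two-pass semantics** — all removal decisions are evaluated on the
  input graph, then applied at once.  This makes the output
  independent of edge order and yields the nesting law
  `output(ε₁) ⊆ output(ε₂)` for ε₁ ≤ ε₂ and idempotence at ε = 0;
- **strict inequality** — exactly tied MI values never trigger
  removal, so a perfectly symmetric triangle survives even at ε = 0.
  Ties are resolved by physics (keep), not by ordering heuristics;
- **denominator dialect** — the tolerance compares against the *min*
  of the flanking edges, the natural reading of "within ε of the
  weaker flank".  Comparing against the max or each flank separately
  are conceivable dialects; min is the implemented and tested one;
- **hub restriction** — used when the complete matrix is pruned
  (`full` mode), so TF–TF edges cannot be explained away by a non-TF
  intermediary; the TF-only run prunes unrestricted.

`dpi_oracle` re-implements the same contract by explicit triangle
enumeration over all node triples and serves as an independent
cross-check (they agree on randomized graphs across ε and hub modes).

## Synthetic benchmark

The generator emulates the statistical skeleton of a curated
expression compendium: continuous log-scale values; TF hubs whose
unit-variance profiles drive target sets through `target =
link(hub) + N(0, noise_sd)`; paralog groups as noisy copies of one
latent profile (correlated TFs with no planted regulatory edge among
them); cascades TF1→TF2→target that create exactly the
triangle-with-weak-diagonal pattern DPI exists to break, with
(TF1, target) recorded as an indirect pair (conditionally independent
given TF2 by construction); and i.i.d. background genes.  The sigmoid
link is `tanh` with unit gain — saturating yet monotone, so
dependencies are nonlinear but rank-preserved; `mixed` alternates
linear and sigmoid per planted edge.

Defaults (10 hubs × 5 targets, two 3-member paralog groups, 3
cascades, 50 background genes, N = 200, noise_sd = 0.3) describe a
benchmark small enough to run in seconds yet hard enough that
significance calibration and pruning both do real work: at N = 200 the
extrapolated 1e-20 threshold sits near MI ≈ 0.33, planted edges score
≈ 0.6–0.9, and cascade diagonals ≈ 0.45–0.55 — significant, hence
only removable by DPI, not by the p-value cutoff.

What the generator does *not* emulate — and therefore what passing
recovery tests do not show about real data: probe-level noise and
cross-hybridisation, normalisation artifacts, batch and lab effects,
heavy-tailed or bimodal expression, feedback loops, combinatorial
regulation, and the sheer pair count of a 22k-gene compendium (where
the multiple-testing burden, not estimator variance, dominates).
Recovery at precision/recall ≈ 1.0 on the benchmark certifies the
pipeline's internal consistency, not field performance.

Fractional counts (evidence fractions, switching-gene fractions) use
one rounding rule everywhere: half-up, implemented over decimal
arithmetic so printed percentages like 92.75 → 92.8 do not depend on
binary representation.  Percentages in reports are *derived* from
stored integer counts, never stored themselves.

## Degenerate inputs and errors

Constant rows are rejected at rank transform (MI against a one-atom
variable is degenerate).  Matrices with missing, non-finite or
duplicate entries fail at load with the offending coordinates.  Seed
lists containing genes absent from the network are reported in
provenance rather than dropped.  Empty candidate edge sets (pure-noise
input) produce an empty network, not an error.  Probesets mapping to
several loci keep all mappings; exported tables join them with ';'.

## Reproducibility

Every stochastic step (generator, permutation null, evidence and
time-course sampling) takes an explicit seed through
`numpy.random.default_rng`; pair enumeration, neighbor sets and all
writers sort lexicographically, and MI prints at 6 decimals, so a
rerun with the same configuration is byte-identical.  Problem sizes in
the shipped checks — N = 200 / 2000 permutations for calibration,
N = 2000 for the closed-form comparison, 119-gene benchmark — were
chosen as the smallest sizes at which the statistical claims are
stable across seeds.

## Known limitations

- Absolute MI values are estimator- and bandwidth-specific; compare
  rankings, not raw nats, across datasets or tools.
- The exponential tail extrapolation to 1e-140 is unverifiable by
  simulation at any feasible permutation count; decades that extreme
  are best read as ranks.
- The TF-anchored pair enumeration is O(T·G·N²); at compendium scale
  (thousands of TFs × tens of thousands of genes) this wants chunking
  or parallelism that this implementation intentionally keeps out of
  scope.
- Hub-restricted DPI protects TF–TF edges by fiat; if the TF list is
  incomplete, interactions mediated by an unlisted TF will survive
  pruning as apparent direct edges.
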