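# Methods

## Model

Surprisal analysis expresses the natural-log expression of gene *i* at
condition *T* as a finite sum of constraint terms,

    ln X_i(T) = Σ_{α=0}^{t−1} G_iα λ_α(T),

where t is the number of conditions (time stamps, disease stages, or
patients). The α = 0 term is the steady state — the maximal-entropy
expression distribution free of the constraints — and α ≥ 1 are deviation
patterns. `G_iα` is the time-independent participation of gene *i* in
pattern α; `λ_α(T)` is the Lagrange multiplier weighting pattern α at
condition *T*. The assumptions are those of the maximum-entropy framework:
a small number of constraints suffices, expression signals are positive,
and the log scale is the natural one for fold changes.

## Fitting by SVD

With Y the m×t log matrix (m ≥ t), the decomposition is the SVD
Y = U Σ Vᵀ with `G = U` (orthonormal columns) and `λ = Σ Vᵀ`
(rows orthogonal, squared-singular-value norms). All t patterns are
retained — zero singular values yield zero patterns — so the multiplier
matrix is always t×t; an effective-rank report counts patterns above
1e-10 × ω₀.

Two routes are implemented and tested against each other:

- **full_svd** — direct SVD of the rectangular matrix
  (`numpy.linalg.svd`);
- **small_matrix** — eigendecomposition of the t×t Gram matrix YᵀY
  (`numpy.linalg.eigh`) followed by back-projection `G_α = Y v_α / ω_α`.
  Since the rank is at most t, the small eigenproblem carries all the
  information; this is the route of choice for very large m.

Numerical notes. The Gram route squares the condition number, so
eigenvalues at the numerical noise floor (below 64 ε × the largest) are
reported as exact zeros; columns of G belonging to zero singular values
are filled by a deterministic Gram–Schmidt completion so G always has
orthonormal columns (they carry zero weight in every reconstruction).
Exactly tied singular values span a non-identifiable subspace; tied
patterns are ordered by the first condition's multiplier value for
determinism.

**Sign convention.** An SVD fixes each pattern only up to a joint sign
flip of (G column, λ row). We fix: for α = 0, the G column sums negative —
the steady-state convention under which the most stable transcripts carry
the lowest `G_i0` while `G_i0 λ_0(T)` still reproduces the positive log
expression; for α ≥ 1, the λ entry of largest magnitude is positive, ties
broken toward the earliest condition. Both fitting routes then agree to
~1e-8 elementwise. Whether ω is folded into λ (our choice) or into G is a
pure convention; reconstructions are identical.

**No mean-centering.** Centering the log matrix before the SVD would
remove precisely the steady-state term; the α = 0 pattern *is* the
uncentered dominant component.

## Stability diagnostics

- `steady_state_residual`: per gene, max over conditions of
  |ln X_i(T) − G_i0 λ_0(T)| = max_T |Σ_{α≥1} G_iα λ_α(T)| — the
  log-fold-change magnitude unexplained by the steady state. Stable genes
  have small residuals.
- `stability_scatter`: the per-gene (G_i0, G_i1) points; stable genes sit
  at large |G_i0| and G_i1 ≈ 0.

## Expression input

The CSV contract is a header of unique condition names followed by one
row per unique gene. Values ≤ 0 or missing are floored at a configurable
positive constant (default 1.0 signal unit, logged count): chip signals
near zero are noise and the log transform requires positivity. Per-array
global scaling to a common target mean intensity is provided but opt-in
(deposited matrices are often already scaled); the plain arithmetic mean
is used, with a 2%-trimmed variant behind a flag. Gene order is preserved
as read; nothing is silently re-sorted.

## Gene profiling

Per pattern, weights are sorted non-increasing (gene-name tiebreak, so
profiles are deterministic). Selections are by strict value bounds (upper
bound for the high tail, lower for the low tail; inclusive variants behind
a flag) or by extremes: "most stable" = most-negative `G_i0` (not largest
magnitude — the convention places stable transcripts at the bottom of the
steady-state profile), "most contributing, up-regulated" = most-positive
`G_iα`, plus a magnitude mode for robustness checks. Whether "up-regulated"
should additionally require an expression increase is left to the caller:
both the sign filter and the bound filter are available, neither is
hard-wired. Selections carry their parameters so any downstream heatmap is
reproducible.

## Connectivity (STRING)

The parser consumes the STRING protein-links flat file (whitespace-
separated, header-addressed columns, integer combined scores 0–999) and a
two-column gene↔protein map; scores become probabilities via raw/1000. The
evidence-channel combination formula is *not* re-implemented — combined
scores are consumed as published. Conflicting duplicate scores keep the
maximum (higher confidence when more evidence supports a link), with a
warning. Pairs absent from STRING are **missing, not zero** — carried as
NaN, serialized as `NA`, rendered as white cells, excluded from
correlations; the diagonal is always missing (no self-links).

## Heatmap comparison

The theoretical heatmap for pattern α has ij element `G_iα G_jα` — signed,
not absolute: sign encodes correlation vs anti-correlation within the
pattern, and the rendering uses a diverging scale symmetric about zero.
Paired heatmaps share one ordered gene axis exactly; connectivity is
re-indexed to the theoretical order. For combined selections the axis is
the stable block first (ascending G_i0), then the deviating block — the
block structure of the side-by-side comparison maps. The correlation
between paired maps is Spearman rank over mutually non-missing
upper-triangle cells (products and probabilities live on incomparable
scales; at least 3 cells required), reported with the cell count. This
correlation is deliberately simple plumbing — a single summary number,
not a calibrated statistical criterion.

## Synthetic data

The generator emulates a transformation time course at the scale of a
four-stage keratinocyte study: log matrix
`G_0 λ_0(T) + G_1 λ_1(T) + ε`, exponentiated to positive signals.

- `λ_0` is nearly constant (±1%) at a level giving mean log expression
  ≈ 6 (signal ≈ 400, a typical scaled chip intensity): the balanced state
  persists through the course.
- `λ_1` is a centered monotone ramp (−1 → +1 scaled): progressive
  transformation. Centering makes λ_1 orthogonal to λ_0, so the planted
  pair is itself a valid decomposition (the model requires orthogonal λ
  rows); an uncentered ramp would leak most of its norm into the
  steady-state direction and the planted pattern would not be the model's
  α = 1 pattern.
- Planted G columns are exactly orthonormal; stable genes carry the
  largest steady-state weights, deviating genes (half up-, half
  down-regulated) carry the whole deviation column, everyone else is
  background.
- Noise is i.i.d. Gaussian in log space (multiplicative on the signal
  scale — expression noise is scale-proportional and positivity is
  preserved).

Defaults, chosen as a realistic study condition: m = 2000 genes, t = 4
stages, 100 stable + 100 deviating genes (the selection sizes used in
practice), noise sd 0.05 log units, deviation amplitude 1.5 log units for
the typical (RMS) deviating gene at the extreme stages — about a 4.5-fold
swing, a strong but realistic transformation effect. Seeds are mandatory
and recorded.

The links fixture writes the STRING dialect with both record directions:
stable–stable pairs get a high score at the requested density, all other
pairs a low score at a tenth of that density ("sparse low scores"). Scores
within a group are constant — adequate for testing parsing, matrix
construction and block-level correlation, but *not* a model of STRING's
score distribution.

What the generator does not emulate: probe-level artifacts, detection
calls, batch effects, heavy-tailed biological noise, correlated noise
across genes, more than one deviation pattern. Passing tests therefore
demonstrate correctness of the machinery and recoverability under clean
planted structure, not performance on real chips.

## Problem sizes

Tests and the acceptance script run at m up to 5000 and t up to 12 for
reconstruction, 100 random instances for route equivalence, 1000 random
profiles for selection oracles, and the 2000×4 planted scale for recovery;
the whole suite completes in a few seconds on one CPU.

## Known limitations

- No error bars on G and λ, and no calibrated correlation criterion for
  heatmap pairs — the Spearman number is descriptive plumbing.
- Model selection (how many patterns are real) is by the effective-rank
  threshold only.
- The live STRING API is not queried; analyses run from downloaded links
  files.
- MAS5/RMA summarization and detection calls are out of scope; the package
  starts from a signal matrix.
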