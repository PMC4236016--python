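# surprisal-analysis

Maximum-entropy (surprisal) analysis of gene-expression time/stage series,
with gene profiling, STRING functional-connectivity retrieval, and paired
theoretical/experimental heatmap comparison.

## The problem and the model

Bulk expression studies of progressive cellular processes — viral
transformation of keratinocytes, stepwise fibroblast transformation, tumor
progression in patients — measure thousands of transcripts at a handful of
stages. Surprisal analysis treats the cell as a thermodynamic-like system:
the observed expression distribution is the maximal-entropy (balanced,
*steady-state*) distribution, deviated from by a small number of
constraints, the *transcription patterns*. For gene *i* at condition *T*:

```
ln X_i(T) = Σ_α  G_iα · λ_α(T)
```

- `X_i(T)` — measured expression signal;
- `G_iα` — time-independent extent of participation of gene *i* in
  pattern α (unit-norm columns);
- `λ_α(T)` — Lagrange multiplier: the weight of pattern α at stage *T*;
- α = 0 is the steady state; α ≥ 1 are the deviation patterns that hold
  the system away from balance.

The fit is a singular value decomposition of the m×t natural-log
expression matrix, either directly or via the t×t Gram matrix ("small
matrix" route — the rank is at most the number of conditions, so the small
eigenproblem suffices for tens of thousands of genes). By convention the
steady-state weights `G_i0` are negative: the transcripts most
contributing to the steady state carry the *lowest* `G_i0` and are the
most stable — their expression is reproduced by the steady-state term
alone.

The downstream question is structural: do the genes the model calls most
stable form a densely connected functional module? The package builds the
theoretical connectivity heatmap with ij element `G_iα·G_jα` and pairs it,
on an identical gene axis, with the STRING database combined-score matrix
(benchmarked probabilities of functional association, raw 0–999 scores
normalized to [0, 1]), exposing a rank correlation over the mutually
informative cells.

## Worked example

`examples/` holds one narrative script per capability. From
`examples/01_decompose_expression.py` (a 6-gene, four-stage toy matrix
with stages K, E, L, BP):

```
6 genes x 4 stages: 4x4 Lagrange-multiplier matrix

lambda_alpha(T)  (rows = patterns, columns = stages K, E, L, BP):
[[-15.997 -16.267 -16.52  -16.747]
 [  1.18    0.445  -0.424  -1.141]
 [ -0.035   0.047   0.01   -0.022]
 [  0.     -0.011   0.023  -0.013]]

singular values omega: [3.277e+01 1.753e+00 6.355e-02 2.863e-02]
```

Four stages give exactly four patterns. The steady state (row 0) is an
order of magnitude heavier than the first deviation pattern and nearly
constant across stages; its product with the negative `G_i0` reproduces
the positive log expression. Pattern 1 swings monotonically from +1.18 to
−1.14 — the transformation signature — and patterns 2–3 are noise-level.

From `examples/03_connectivity_heatmaps.py`, on a 2000-gene synthetic
dataset with planted structure and a matching STRING-dialect fixture:

```
heatmap axis: 197 genes (stable block first)
rank correlation theoretical vs STRING: +0.720 over 5085 mutually informative cells
```

The positive correlation is the package's quantitative version of the
observation that the most stable transcripts are also the most
functionally connected.

## Command line

A thin CLI mirrors the library stages:

```sh
surprisal simulate  --out data/ --seed 1                 # planted dataset + links fixture
surprisal decompose --input data/expression.csv --method small_matrix --out dec/
surprisal profile   --decomposition dec/ --pattern 0 --bottom 100 --out prof/
surprisal connect   --links data/links.txt --id-map data/id_map.tsv \
                    --genes prof/bottom100_pattern0.txt --out conn/
surprisal heatmap   --decomposition dec/ --pattern 0 \
                    --selection prof/bottom100_pattern0.txt \
                    --connectivity conn/connectivity.tsv --out maps/
surprisal run       --simulate --seed 1 --out full/      # all stages + manifest
```

Every stage writes plain TSV/CSV/JSON so any later stage can be re-entered
from saved intermediates.

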