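# ssdfs — Social Ski-Driver feature selection with ABHC local search

`ssdfs` is a wrapper feature-selection toolkit for binary classification of
high-dimensional feature tables, built for the two-stage breast-mass
classification setting: deep features are extracted from mammogram patches
(benign vs. malignant) and a meta-heuristic then selects the feature subset
that a K-nearest-neighbours classifier does best with.

## The method

A candidate solution is a binary mask `LB ∈ {0,1}^d` over the feature
columns, scored by the wrapper fitness (minimized)

    Fitness(LB) = w·α + (1 − w)·|s|/|d|

where `α` is the hold-out error of a KNN trained on the selected columns,
`|s|` the number of selected features, `|d|` the total, and `w ∈ [0,1]`
weights error against subset size (default `w = 0.2`).

The **Social Ski-Driver (SSD)** optimizer evolves a population of agents.
Each agent `k` carries a binary location `L_k` and a real velocity `V_k`,
updated by sine/cosine-weighted attraction toward its personal best `PB_k`
and the mean of the top-3 solutions found so far, `MGB = (L_x+L_y+L_z)/3`:

    V_k ← h·sin(r₁)(PB_k − L_k) + sin(r₂)(MGB − L_k)   with prob. 1/2
    V_k ← h·cos(r₁)(PB_k − L_k) + cos(r₂)(MGB − L_k)   otherwise

with fresh uniforms `r₁, r₂` per dimension and an exploration weight `h`
decayed geometrically each iteration (`h ← r·h`, defaults `h₀ = 100`,
`r = 0.9`). The real velocity is mapped back to bits by the V-shaped
transfer function `V(x) = |x|/√(1+x²)`: bit `j` flips with probability
`V(V_kj)`.

Every iteration, every agent is refined by **Adaptive Beta Hill Climbing
(ABHC)**: for `z = 1..MT`, a neighbour is drawn within a shrinking radius
`N(z) = 1 − (z/MT)^{1/c}`, mixed coordinate-wise with the incumbent using a
growing keep-probability `Beta(z) = Mi + (Ma − Mi)·z/MT`, binarized, and
accepted only on a strict fitness improvement. Bookkeeping is elitist, so
the best fitness trace is non-increasing and every run is bit-reproducible
from its seed.

The package also ships:

* a synthetic-data generator (tables with known informative / redundant /
  noise columns, plus toy blob images) so everything is testable offline,
* an exhaustive-oracle enumerator (`d ≤ 16`) for verifying the optimizer,
* a repeat-run evaluation protocol (mean ± sample SD, Mann–Whitney U with
  exact small-sample p-values, ground-truth recovery scoring),
* an optional attention-aided VGG16-style deep-feature extractor implemented
  in numpy (frozen conv backbone, 1×1 locally connected attention,
  attention-weighted global average pooling, 128-d bottleneck).

## Worked example

```sh
$ ssdfs simulate --n 200 --informative 4 --redundant 2 --noise 10 --sep 3 --seed 1 -o tbl.csv
wrote tbl.csv (200x16) and tbl.truth.json

$ ssdfs select tbl.csv --population-size 10 --max-iterations 30 --seed 7 -o result.json
best fitness 0.055000 with 1 features -> result.json

$ ssdfs evaluate tbl.csv --truth tbl.truth.json --runs 5 --population-size 10 --max-iterations 30 -o report.json
| Simulation | Accuracy (%) | Precision (%) | Recall (%) | #FS |
|---|---|---|---|---|
| 1 | 97.50 | 95.24 | 100.00 | 1 |
| 2 | 97.50 | 95.24 | 100.00 | 1 |
| 3 | 97.50 | 95.24 | 100.00 | 1 |
| 4 | 97.50 | 95.24 | 100.00 | 1 |
| 5 | 97.50 | 95.24 | 100.00 | 1 |
| Mean ± SD | 97.50 ± 0.00 | 95.24 ± 0.00 | 100.00 ± 0.00 | 1 ± 0 |
mean informative recall: 0.250
```

Reading the numbers: the generated table has 16 columns of which 4 are
informative (class means 3 SD apart). With `w = 0.2` the size term costs
`0.8/16 = 0.05` per kept column, so the optimizer converges on a single
informative column (index 4, a redundant copy of an informative one) whose
hold-out accuracy is 97.5% — fitness `0.2·0.025 + 0.8·1/16 = 0.055`. All
five seeds find the same optimum, hence SD 0. The recovery line reports
that this one column covers 1 of the 4 planted signal sources.

The same pipeline is available as a library (`ssdfs.run_ssd`,
`ssdfs.repeat_experiment`, `ssdfs.exhaustive_oracle`, ...), and
`ssdfs extract` turns a directory of PNG patches into a feature table via
the attention-aided extractor.

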