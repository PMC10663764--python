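# nmanova

ANOVA-like significance testing of a grouping of objects when all you have
is a matrix of pairwise **dissimilarities** — possibly asymmetric, with a
nonzero diagonal, or with missing entries (no metric axiom is assumed).

Given an `N x N` dissimilarity matrix and a partition of the objects into
`g >= 2` groups, the test compares each between-group block mean against a
*proportionally sampled* reference mean drawn from the within-group blocks
of the remaining groups. The resulting statistic

```
F = (SNMB / g) / SNMW        ~  F(g^2 - g, g - 1)  under the null
```

is referred to the upper tail of that F distribution. Because the
reference means are random, the procedure is replicated (default 10 000
times) and the headline p value is the mean of the per-replicate p values.

## Python API

```python
import numpy as np
from nmanova import DissimilarityMatrix, Partition, SamplingOptions, nm_anova

m = DissimilarityMatrix(np.random.rand(30, 30))           # NaN = missing
part = Partition(["a"] * 10 + ["b"] * 10 + ["c"] * 10, ids=m.ids)
res = nm_anova(m, part, SamplingOptions(n_samplings=10_000, seed=1))
print(res.mean_p, res.mean_f, res.df1, res.df2)
```

Dissimilarity constructors for common raw inputs live in
`nmanova.constructors`: `invert_bit_scores` (similarity scores),
`correlation_dissimilarity` (directional sensitivity profiles),
`kl_divergence_matrix` (count profiles; `variant="js"` for the symmetric
Jensen-Shannon form). Simulation and calibration experiments (block-matrix
generation, sensitivity sweeps, convergence curves, null-uniformity
calibration, partition search, randomized distribution grids) are in
`nmanova.simulate`, driven by `ScenarioConfig` (JSON/YAML loadable).

## Command line

```bash
# test a partition: wide TSV matrix (ids in first row/column) + 2-column labels
nmanova test --matrix matrix.tsv --labels labels.tsv \
             --samplings 10000 --seed 1 --out result.json --json

# long/edge-list input (source, target, value; absent pairs = missing)
nmanova test --matrix edges.tsv --format long --labels labels.tsv

# run a scenario config (sensitivity sweep, convergence, grid)
nmanova simulate --config sweep.json --out sweep.tsv

# null-uniformity calibration
nmanova calibrate --config null.json --out calib.tsv

# build a dissimilarity matrix from a feature table
nmanova build-dissim --method kl --input counts.tsv --out kl.tsv
```

Exit status is 0 on success and 2 on any input error.

Example scenario config (JSON or YAML):

```json
{
  "kind": "null-calibration",
  "group_sizes": [10, 10, 10],
  "within": ["normal", 0, 1],
  "between": ["normal", 0, 1],
  "n_replicates": 2000,
  "n_samplings": 1,
  "seed": 0
}
```

## Notes on the g = 2 and degenerate cases

With two groups the exclusion rule (reference samples must avoid both
groups of the pair) leaves no donor pool; by default the sampler falls
back to all within entries and flags the result
(`SamplingOptions(fallback_pool="error")` raises instead). A constant
matrix has no within dispersion and is rejected; zero within dispersion
with nonzero between signal yields `F = inf`, `p = 0` and a degenerate
flag.

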