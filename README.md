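# coca-rank — knowledge-guided coordinative component analysis

Ranking genes by differential expression alone ignores that pathway members
act together.  Given a genes × samples expression matrix **X** and a partial
list of pathway members ("knowledge genes"), coordinative component analysis
(COCA) finds a unit direction **w** in sample space that maximizes the ratio
of knowledge-gene to background-gene projection amplitudes

```
J_p(w) = ( Σ_{j∈P} |x_j·w|^p )^{1/p}  /  ( Σ_{j∈B} |x_j·w|^p )^{1/p} ,   p = 1 by default,
```

with P the knowledge genes and B a background sample.  Every gene then
receives a participation value `a_j = x_j·w`; genes with large |a_j| are
coordinated with the pathway and ranked high — including pathway members
missing from the knowledge list.  The objective has no convenient analytic
gradient, so it is maximized by simultaneous-perturbation stochastic ascent
(two objective evaluations per step, random ±1 perturbations).  Because a
small knowledge set against thousands of background genes overfits, the
background is bootstrap-resampled to the knowledge set's size: per replicate
a direction is fitted, its sign fixed so knowledge genes project positively
on average, and the full matrix is projected; the bagged (mean) participation
vector is what gets ranked, by absolute value.

The package is aimed at transcriptomics analysts who have a curated gene set
(pathway, complex, signature) and want a condition-specific, expression-driven
ranking of candidate members.  It ships

* `CocaRanker` / `DifferentialCocaRanker` — sklearn-style estimators
  (`fit(X, y)` with rows = genes, `y = 1` marking knowledge genes;
  `ranking_`, `participation_`, `directions_` after fitting);
* baseline rankers used for comparison: variance, fold-change, SAM-style
  moderated t, knowledge-guided PCA;
* simulators for the linear latent model `X = A·T + E` (one- and
  two-condition designs with controlled SNR in dB) and an accuracy-vs-SNR
  benchmark harness;
* ROC/AUC evaluation and plain-text IO (TSV/CSV/GCT matrices, gene lists,
  GMT), plus a `coca` command-line interface.

## Worked example

```python
import numpy as np
from coca import CocaRanker, detection_accuracy, one_condition_design, simulate_one_condition

design = one_condition_design(n_genes=2000, snr_db=6.0)   # 5 latent processes, 8 samples
x, truth = simulate_one_condition(design, np.random.default_rng(0))
y = np.isin(x.gene_ids, sorted(truth.knowledge_genes)).astype(int)  # 50 knowledge genes

ranker = CocaRanker(n_boot=20, max_iter=300, restarts=2, random_state=1)
ranker.fit(x.values, y, gene_ids=x.gene_ids)

acc = detection_accuracy(ranker.ranking_, truth.ground_truth_genes)
print(f"top-200 detection accuracy: {acc:.3f}")
print(f"mean objective across replicates: {ranker.objectives_.mean():.2f}")
print("top 5 genes:", ", ".join(ranker.ranking_[:5]))
```

prints

```
top-200 detection accuracy: 0.880
mean objective across replicates: 4.75
top 5 genes: g0303, g0238, g0284, g0219, g0270
```

Reading the numbers: the simulation plants 200 "ground truth" genes driven by
one latent process and reveals only 50 of them to the ranker; 88% of all 200
appear in the top 200 of the returned ranking at 6 dB SNR.  The bagged
objective ≈ 4.8 means knowledge genes project almost five times more strongly
along the learned direction than resampled background genes.  The same
workflow is available from the shell:

```
coca simulate --design one --snr-db 6 --n-genes 2000 --seed 0 --out sim/
coca rank --expr sim/expression.tsv --geneset sim/knowledge.txt --n-boot 20 --seed 1 --out run/
coca evaluate --ranking run/ranking.tsv --positives sim/ground_truth.txt \
     --knowledge sim/knowledge.txt --out run/eval
```

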