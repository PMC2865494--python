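# Methods

## Model

Expression is modeled as a linear mixture of a small number of latent
biological processes, `X = A·T + E`: `X ∈ ℝ^{N×M}` (genes × samples,
log-like additive scale), `A ∈ ℝ^{N×L}` per-gene participation strengths,
`T ∈ ℝ^{L×M}` latent process activities, `E` i.i.d. Gaussian noise.  COCA
does not decompose X; it extracts a single column of A for the process of
interest by a linear filter `a = X·w` and asks that the filter make the
known pathway members stand out.

The fitted quantity is the coordinative direction `w ∈ ℝ^M`, `‖w‖₂ = 1`,
maximizing the masked ratio

```
J_p(w) = (Σ_{j∈P} u_j |x_j·w|^p)^{1/p} / ((Σ_{j∈B} v_j |x_j·w|^p)^{1/p} + ε)
```

with P the knowledge genes, B the (bootstrap-resampled) background, and
u, v non-negative weights (background weights are integer multiplicities of
with-replacement draws).  `p = 1` is the default: the amplitude form is less
sensitive to outlying samples than the energy form `p = 2`; both are exposed.
Numerator and denominator are homogeneous of degree 1 in w, so J is
scale-invariant and the unit sphere is the canonical domain.

`ε = 1e-12 × (weighted mean |x_j·w| over P ∪ B, floored at 1e-300)` guards a
vanishing denominator.  Basing ε on all masked genes rather than only the
background keeps J finite even when every background projection is exactly
zero (a case that arises in noiseless fixtures) while preserving exact scale
invariance, since ε itself scales linearly with |w|.

Rows of X are mean-centered per gene before analysis (flag to disable;
optional unit-variance scaling, off by default).  Centering removes baseline
offsets so that projections measure covariation, not expression level.

## Optimizer

The absolute values inside J make analytic gradients awkward, so the
gradient is estimated by simultaneous perturbation: with a Rademacher vector
s and magnitude c, `g_k = [J(w + c·s) − J(w − c·s)] / (2 c s_k)` — two
objective evaluations per step regardless of M, and an unbiased estimate of
the gradient for smooth J.  Ascent uses standard gain schedules
`a_n = a0/(n+1+A)^0.602`, `c_n = c0/(n+1)^0.101` with `A = 0.1·max_iter`,
defaults `a0 = 0.1`, `c0 = 0.05`, `max_iter = 500`; the iterate is
renormalized to the unit sphere every step.  A restart stops early after
`patience = 20` consecutive checks with relative improvement below
`tol = 1e-6`.  The stochasticity of the gradient doubles as a device for
escaping shallow local maxima.

Restart 0 starts from the normalized mean profile of the knowledge genes —
the natural warm start, since the knowledge centroid estimates the latent
activity of the target process — and the remaining `restarts − 1` (default
3) start from random unit vectors to cover multimodality.  Each restart runs
on its own deterministic random substream; the reported direction is the
best objective value seen across all restarts and iterations, never silently
the last iterate.  If every evaluated objective is zero (e.g. an all-zero
matrix) the initial direction is returned flagged degenerate, with a warning.

## Bagging and ranking

A knowledge set of tens-to-hundreds of genes against thousands of background
genes is an imbalanced comparison that overfits M-dimensional directions.
Each of B bootstrap replicates therefore draws, with replacement, a
background multiset of the knowledge set's size (configurable) from the
background pool; the direction is fitted on knowledge + sampled rows only.
The sign ambiguity inherent to any linear component is resolved by flipping
w when the mean knowledge-gene participation is negative (idempotent; a
zero mean keeps the sign and warns).  The *full* matrix is then projected so
every gene — including genes in neither mask — receives a participation
value.  Replicate b runs on the substream keyed `(master_seed, b)`, so
results are independent of replicate order and of gene row order (background
draws are made over the id-sorted pool).  The bagged participation is the
replicate mean (median available); genes are ranked by its absolute value,
descending, ties broken by gene id ascending.  `B = 100` with a 5,000-gene
background pool — the scale used for real time-course data — runs in well
under a minute on one CPU.

### Two-condition analysis

For paired condition designs, `DifferentialCocaRanker` fits one bagged COCA
model per condition with the same knowledge genes and scores each gene by
the change in participation.  Because w is unit-norm, the raw participation
scale of each condition depends on the realized latent amplitude along the
learned direction; each condition's bagged vector is therefore normalized by
its mean knowledge-gene participation (positive after sign correction)
before differencing.  Knowledge genes, whose involvement is unchanged by
construction, cancel under this normalization; genes whose process
involvement was switched off do not.  Simple sample-wise concatenation of
the two conditions (then ranking by |a|) is possible with plain
`CocaRanker`, but under the linear model it ranks by overall participation
rather than by change, so the differential estimator is the default route
for change detection.

## Simulators

Both designs instantiate `X = A·T + E` with `L = 5` processes.  Decisions
where the model family leaves freedom:

* **Loadings.**  Each process regulates a contiguous block of `N/L` genes;
  blocks overlap by 10% of their length (configurable) so some genes serve
  two processes.  Nonzero loadings are half-normal `|N(0,1)|`: participation
  is a non-negative strength ("how involved is gene j").  Non-negative
  loadings also make pathway members positively co-regulated, which is what
  the knowledge-mean sign correction relies on; with symmetric signed
  loadings the knowledge mean would hover near zero and replicate signs
  would be arbitrary.
* **Activities.**  `t ~ N(0,1)` i.i.d., signed.
* **Noise.**  i.i.d. Gaussian with variance set so
  `10·log₁₀(Var(signal)/Var(noise))` equals the requested SNR in dB,
  variances taken over all matrix entries.  Realized SNR is checked to
  0.2 dB from the stored signal/noise parts.  `snr_db = None`/`inf` disables
  noise exactly.
* **One-condition design** (defaults N = 5000, M = 8): ground truth = the
  200 genes with the largest |loading| on process 1; knowledge = 50 drawn
  uniformly from the ground truth; the task is recovering the remaining 150.
* **Two-condition design** (defaults N = 10000, M = 20 per condition):
  100 random nonzero process-1 participations are set to zero in condition
  2 — those genes are the ground truth; knowledge = 50 genes from the
  unchanged process-1 support, never overlapping the ground truth.  The
  latent activities are shared between conditions, making the eliminated
  participations the only systematic difference (fresh activities per
  condition would change every gene's distribution and leave per-gene
  statistics like fold change no signal to detect); noise is drawn
  independently per condition.

Detection accuracy is the fraction of ground-truth genes in the top-|truth|
ranked positions; a random ranking scores |truth|/N in expectation.  The
benchmark harness (`snr_sweep`) simulates fresh data per (SNR, repetition)
cell, runs each method on the identical dataset, and emits a long-format
accuracy table.

What the simulations do *not* emulate: array-specific noise (spatial
effects, dye bias, intensity-dependent variance), probe-level artifacts,
correlated noise between genes, non-Gaussian heavy tails, and time-course
autocorrelation.  Passing benchmarks therefore demonstrates correct behavior
under the linear model, not performance on any particular platform's data.

## Benchmark scale and reproducibility

The shipped benchmark configurations use reduced problem sizes — 2,000 genes
(one-condition) and 3,000 genes (two-condition), 20 repetitions per SNR
cell, `B = 20`, optimizer effort `max_iter = 300`, `restarts = 2` — chosen
as the package's own desk-scale defaults; full-scale runs are a parameter
change.  All randomness flows from integer seeds through `SeedSequence`
substreams, so every table, ranking and trace is exactly reproducible;
`run`-level manifests record seed, configuration hash and library versions.

Observed behavior at these scales: knowledge-guided COCA clearly outranks
variance ranking (one condition) and fold-change/SAM (two conditions) at
SNR ≥ 0 dB, and all methods degrade toward the random-guess accuracy as SNR
falls.  At −10 dB the two-condition differential COCA and both per-gene
baselines sit at or near random guessing, while one-condition COCA (and,
mildly, variance ranking) retain a measurable edge over random: the
knowledge-centroid warm start averages noise across 50 genes and so still
carries latent-direction information at noise levels where a cold start
would not.  The acceptance script reports the measured values; nothing is
asserted about convergence that the code does not compute.

## Evaluation and IO

ROC curves and AUC use scikit-learn (`roc_curve` with all thresholds kept;
`roc_auc_score`), with AUC equal to the tie-corrected Mann-Whitney
concordance (tied positive-negative pairs count ½) — verified against an
independent all-pairs oracle in the tests.  The `evaluate` interface can
exclude the knowledge genes from scoring (default in the CLI), since genes
used as guidance are trivially ranked high; this is an interpretation
choice, documented here rather than hidden.

Gene identifiers are matched by exact string equality; no alias or synonym
resolution is attempted (a documented limitation — curate identifiers to the
expression platform before running).  Expression tables round-trip at full
double precision (`%.17g` on write, round-trip float parsing on read).

## Known limitations

* The SAM comparator uses the median of the per-gene standard errors as its
  stabilizing constant `s0`, not the original percentile search; it is a
  comparator, labeled "SAM-style", not a SAM reimplementation.
* The sign-correction rule assumes knowledge genes are predominantly
  positively coordinated; for a gene set with strongly anti-correlated
  members the bagged mean can attenuate.  The rule is isolated behind
  `correct_ambiguity` and swappable.
* One coordinative component per run; extracting several processes means
  several runs with different knowledge sets.
* No uncertainty quantification on ranks beyond the across-replicate
  standard deviation column.
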