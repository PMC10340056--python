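# Methods

This note records the models implemented in `histotune`, the choices made
where the underlying procedures are underdetermined, and what the
synthetic benchmark does and does not establish.

## Optimizers

Both metaheuristics minimize a scalar fitness over a box; all randomness
flows through one `numpy.random.Generator` per run, so a seed fully
determines the trajectory (single-threaded determinism). Box constraints
are enforced by componentwise clipping after every proposed move — the
simplest contract, and one tests can rely on exactly.

### Al-Biruni Earth Radius (BER)

Population of `population_size` agents; the first
`round(exploration_fraction · population_size)` agents (clamped so both
groups are non-empty) form the exploration group, the rest the
exploitation group. Default `exploration_fraction = 0.5`; adaptive group
resizing is deliberately out of scope.

Per iteration:

- **Exploration**: `S ← S + D ⊙ (2r₂ − 1)` with `D = r₁ ⊙ (S − 1)`.
  The `− 1` is applied elementwise (subtracting the all-ones vector); the
  alternative readings of that constant are not recoverable from the
  formula's usual statements, and the literal reading is used.
- **Exploitation**, fair coin per agent per iteration:
  - toward the leader: `S ← r₂ ⊙ (S + r₃ ⊙ (L − S))`, where `L` is the
    best-ever solution;
  - around the best: `S ← r (S* + k)`, `k = z + 2t²/N²`, `r` the
    Earth-radius factor `h·cos x/(1 − cos x)` with `h ~ U[0,2]` and `x`
    uniform on (0°, 180°), resampled while `|1 − cos x| < 1e−12` to guard
    the division. The coin is needed because the two exploitation
    strategies come with no stated selection rule.
- **Greedy acceptance** everywhere: a candidate replaces its agent only if
  strictly fitter. Elitism keeps the best-ever solution, so the reported
  best-fitness history is non-increasing for every fitness and seed.
- **Stagnation → mutation**: if the best fitness improves by less than
  `stagnation_tol` (default 1e−9, operationalizing "no dramatic
  improvement") for `stagnation_window` (default 3) consecutive
  iterations, every exploration agent is replaced by
  `S_j ← k z² − h cos x/(1 − cos x)` with fresh `z, h, x` per dimension
  (`k` reuses that dimension's `z`), and the counter resets. Mutation
  replaces rather than perturbs: the operator is position-independent by
  its formula. With a constant fitness it therefore fires exactly at
  iterations 3, 6, 9, …

`r₁, r₂, r₃` are vectors of i.i.d. U(0,1) entries redrawn per update. The
draw order (exploration: `r₁` then `r₂`; exploitation: coin, then either
`r₂`/`r₃` or `z, h, x`) is part of the contract and is pinned by
scalar-transcription tests at 1e−12.

### Coati Optimization (COA)

`population_size ≥ 2` so both halves are non-empty. Per iteration `t`
(1-based):

- **Hunting phase**: agents `1..⌊N/2⌋` climb toward the best-ever solution
  with per-dimension `r ~ U(0,1)` and `I` uniform on {1, 2} (`I`'s
  definition is garbled in common statements of the algorithm; the random
  {1, 2} choice follows the original COA source). A "grounded iguana" is
  then sampled uniformly in the box and evaluated once; agents
  `⌊N/2⌋+1..N` approach it if it is strictly fitter than they are,
  otherwise retreat.
- **Escape phase**: every agent moves by
  `x_j + (1 − 2r)(lb_j/t + r(ub_j/t − lb_j/t))`, one `r` per dimension
  used in both places. The `1/t` shrink gives progressively local moves;
  at `t = 1` the local box equals the global box.
- Acceptance is strictly greedy (ties keep the incumbent), and proposals
  are clipped to the **global** box — the local bounds only shape the
  proposal. The best (iguana) is refreshed after every acceptance, not
  once per phase.

### What the sphere benchmark shows

Convergence is verified on `f(x) = Σx²`, d = 5, bounds [−5, 5], population
20, 200 iterations, 20 seeds: both optimizers reach ≤ 1% of the initial
population's best in at least 18 of 20 seeds (in practice they reach
~1e−50). The sphere is unimodal; this establishes correct mechanics and
convergence pressure, not performance on deceptive landscapes.

## Neural components

No deep-learning framework is used: layers are numpy with hand-written
backward passes, each checked against central finite differences (run in
float64 for the checks; training runs in float32). Convolutions are
stride-1 with im2col for channel-mixing kernels and a shift-and-add scheme
for depthwise kernels; the reference depthwise operation (valid padding)
is additionally pinned to a four-nested-loop oracle.

- **Extractor unit**: 1×1 conv → channel shuffle → depthwise 3×3 (same
  padding) → 1×1 conv → ECA, with ReLU after each pointwise conv and a
  2×2/2 max pool closing each stage. One ECA module is embedded per unit
  (the alternative — a single module for the whole network — is weaker
  and less regular; per-unit placement follows standard ECA practice).
- **ECA** pools each channel globally, runs a length-k 1-D convolution
  (default k = 3, tunable, odd; zero padding, no bias) across the channel
  axis and rescales channels by the sigmoid of the result. All attention
  weights are strictly in (0, 1); zero conv weights scale the input by
  exactly 0.5.
- **Channel shuffle** is the (g, C/g)-reshape-transpose permutation;
  shuffling with g then C/g is the identity.
- **CRNN head**: 3×3 convs (ReLU, 2×2/2 max-pool, batch norm, dropout),
  then the feature map is read as a width-axis sequence — each image
  column is a timestep with channels×height features — into a single LSTM
  layer, a 64-unit fully connected layer, and softmax. The width-axis
  sequence is the natural bridge from a 2-D feature map to a recurrent
  layer when no explicit sequence axis exists in image data.
- **Loss**: label-smoothing cross-entropy with target
  `q = (1−ε)·onehot + ε/K`, ε default 0.1 and tunable in [0, 0.2); ε = 0
  recovers plain cross-entropy. Optimization is Adam with decoupled weight
  decay; the forget-gate bias of the LSTM starts at 1.

Desk-scale defaults: 32×32 RGB inputs, extractor stage widths (8, 16)
before the width multiplier, shuffle groups 2, CRNN conv width max(8,
last stage width), LSTM 32 units. Inputs are scaled to [−0.5, 0.5].
Checkpoints are `.npz` archives holding all parameters plus the
architecture config.

## Tuning

Optimizers run on the unit box; decoding is linear or log interpolation,
half-away-from-zero rounding for integers, and equal-width bins for
categoricals, so every coordinate is monotone in its physical value.
Out-of-box coordinates are clipped before decoding.

Default search spaces — the choice of which hyperparameters to tune is a
design decision, since published treatments rarely enumerate them:

| dimension | range | scale |
|---|---|---|
| extractor: ECA kernel | {3, 5, 7} | categorical |
| extractor: width multiplier | [0.25, 1.0] | linear |
| extractor: learning rate | [1e−4, 1e−1] | log |
| extractor: weight decay | [1e−6, 1e−3] | log |
| head: LSTM units | {16…128} | integer |
| head: dropout | [0, 0.6] | linear |
| head: batch size | {8, 16, 32} | categorical |
| head: label smoothing ε | [0, 0.2] | linear |

Trial fitness is the validation error percent after a 5-epoch training run
(a configurable surrogate budget); a failed run scores +inf with a
warning, so the search routes around it. The validation set is carved from
the training portion (default 80/20 of it), leaving the held-out portion
untouched until final evaluation. All trials share one model/training
seed derived from the run seed, so fitness differences reflect
hyperparameters rather than initialization noise. Tuning is sequential —
extractor first (BER), then head (COA) with the extractor's winners
frozen — mirroring the staged structure of the pipeline. A fitness
evaluation of the default hyperparameters under the same budget is always
logged, making tuned-versus-default comparisons auditable.

The global seed drives a `SeedSequence` that splits into independent
streams for splitting, tuning, model initialization and final training.

## Synthetic data

The generator emulates the coarse statistics of H&E-stained tissue tiles:
a per-class base color in the pink/purple palette, a Poisson number
(density × area) of dark elliptical "nuclei" with class-specific density
and eccentricity, a low-frequency sinusoidal texture with class-specific
frequency, and Gaussian pixel noise (sd 8). The five default classes are
named after the conventional lung/colon histology categories, with
carcinoma classes given denser, more eccentric nuclei. `difficulty ∈
[0, 1]` linearly interpolates each class's parameters toward the
across-class mean: at 0 the classes are separable by mean color alone (a
nearest-centroid baseline scores > 95%); at 1 they are indistinguishable.
Default study conditions for the end-to-end run: 64 images per class at
32×32, difficulty 0.2 — hard enough that tuning matters, easy enough that
a desk-scale model can learn it in minutes.

What the generator does **not** emulate: real nucleus morphology, stain
deconvolution physics, scanner artifacts, inter-patient variation, or
class imbalance. Passing the end-to-end tests therefore shows the
pipeline's mechanics (tuning improves a real trainable signal, reports are
correct) — not clinical-grade performance on real whole-slide tiles.

## Evaluation

Per-class "accuracy" is one-vs-rest accuracy `(TP+TN)/total` — the only
reading under which per-class accuracies can all sit near 100 while
differing from overall accuracy. Precision, recall and F1 are one-vs-rest
per class; 0/0 ratios are reported as 0 with an `undefined` flag rather
than dropped. AUC is one-vs-rest via the Mann–Whitney rank statistic with
midranks for ties; a class absent from the truth labels has undefined AUC
and is excluded from the AUC macro average only. Report CSVs use the
column order Class, Accuy, Precn, Recal, Fscore, AUCscore with a closing
Average row. The suite is pinned to an independent reference
implementation (scikit-learn) at 1e−9 on random inputs; scikit-learn is
never used in the computation path itself.

## Numerical and degenerate-input choices

- Angles with `|1 − cos x| < 1e−12` are resampled (Earth-radius factor) or
  rejected (direct calls) to guard the division.
- Non-finite fitness values become +inf with a warning; non-finite
  training loss aborts with a diagnostic naming the epoch and batch.
- Greedy acceptance uses strict inequality everywhere; ties keep the
  incumbent.
- Degenerate boxes (`lb = ub` in a dimension) pin that coordinate.
- Stratified splits round per class and keep at least one sample on each
  side; classes with fewer than two images are rejected.

## Known limitations

- The optimizers evaluate fitness serially; no parallel evaluation.
- Depthwise/standard convolutions are stride-1 only (downsampling is
  pooling); no dilation.
- The sphere benchmark and the synthetic end-to-end run bound what the
  tests demonstrate (see above); no claim is made about LC25000-scale
  accuracy, which would require GPU-scale training on the real images.
- JPEG round trips are lossy by design; PNG is the default and is
  pixel-exact.
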