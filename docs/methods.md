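# Methods

This note documents the models, statistics and design choices behind
`degensim`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The injury model

A trained feed-forward classifier is described by its named weight
tensors.  The **weight catalog** enumerates every inter-neuron connection
weight — convolutional kernels and dense weight matrices, counted
elementwise across all layers including the output head — in a
deterministic order (layer order, row-major within a tensor).  Biases
are excluded: they are per-neuron offsets, not connections between
neurons, so ablating them would not correspond to synaptic loss.  This
is a modelling choice, flagged for sensitivity analysis; the catalog
machinery would support including them.

An injury course is a monotone schedule of nominal fractions
`0 = f_0 < f_1 < … ≤ 1`.  At fraction `f` exactly
`round_half_away_from_zero(f·N)` of the `N` catalog entries are injured.
The rounding rule is chosen so that a fine cumulative schedule and a
single direct jump reach identical counts at every shared fraction
(telescoping of per-step counts).  Selection is uniform without
replacement from the currently uninjured pool, and cumulative: injury is
irreversible (attempting to lower the fraction raises an error).  The
default selection pool is **global** across layers — the simulated
atrophy process is unstructured, with no preference for any layer; a
per-layer stratified mode exists for layer-targeted injury experiments.

Injury modes:

- `ablate-zero` (default) — injured weights are set to exactly 0,
  severing the connection (simulated synaptic loss).
- `ablate-node` — the selection pool is the set of *units* (dense
  neurons, convolutional channels); ablating a unit zeroes every weight
  into and out of it, including the fan-out across a flatten boundary
  (simulated neuronal loss).  The injured fraction is interpreted over
  units.
- `randomize` — injured weights are set to fresh zero-mean Gaussian
  draws with the standard deviation of their layer's weights at
  catalog-build time (simulated synaptic dysregulation rather than
  loss).

Each replicate network injures with its own generator stream, derived
from the experiment base seed by a counter rule (`base + 100000 + r`),
so every replicate's course of degeneration is unique but exactly
reproducible, and adding RSA checkpoints to a schedule does not change
which weights are injured at a given fraction (one stream, consumed only
by selections).

Out of scope by design: retraining between injuries (plasticity),
magnitude- or sign-targeted ablation, and diffusive spread models.

## Behavioral readouts

Predictions are arg-max over softmax class scores, ties broken toward
the lowest class id (relevant only for heavily injured, near-constant
networks).  Chance accuracy for a uniform random guesser over `L`
labels is `Σ_l (count_l/total)·(1/L)`, which collapses algebraically to
`1/L`; it is computed in the collapsed form so the values for balanced
hierarchies (1% for 100 classes, 5% for 20 superclasses) are exact in
floating point.

The **within-superclass error rate** restricts to misclassified stimuli,
converts the predicted class to its superclass, and reports the fraction
matching the true superclass.  When there are no errors the statistic is
*undefined* (`None`), not 0 or 1: its denominator is the error set.
Two chance conventions are exposed: the marginal convention `1/S`
(probability of guessing the right superclass out of S), which is the
default, and the exact conditional-on-error expectation for a uniform
class guesser, `(k−1)/(C−1)` for balanced hierarchies (4/99 ≈ 4.04% at
the 100-class/20-superclass scale vs the 5% marginal value).  The two
differ; the marginal convention is used for curve references.

## Representational similarity

RDMs are built from post-activation outputs of the designated
penultimate layer (`dense_2`), dropout inactive.  `D[i,j] = 1 − Pearson
r(row_i, row_j)` over all stimulus pairs; the diagonal is 0 and entries
lie in [0, 2].  Zero-variance rows — dead layers are routine under heavy
injury — have no defined correlation; their dissimilarity to every other
row is set to 1 (the "uncorrelated" value) and the event is logged,
rather than erroring and killing late-stage curves.

Kendall's τ_A is `(concordant − discordant) / (n(n−1)/2)`: every
unordered pair is in the denominator, ties contribute zero to the
numerator only.  Two implementations are kept deliberately independent:
an O(n²) brute-force pair counter (the reference), and an O(n log n)
path using a lexicographic sort plus a merge-sort inversion counter
(numba-compiled), assembled via
`C − D = n0 − t_x − t_y + t_xy − 2·inversions`.  The fast path is used
above 10⁴ pairs; the suite checks the two agree to 10⁻¹² on random
tie-containing inputs, and cross-checks against a τ_A value derived from
scipy's τ_b numerator.

The **noise floor** is the mean signed τ_A between an RDM and scrambled
copies of itself.  Default scrambling permutes the upper-triangle
entries uniformly — a pure-noise reference destroying all structure
(the null sd of τ_A is ≈ `sqrt(4/(9·n_pairs))`, so 25 scrambles of a
1000-condition RDM average within 0.005 of zero); a joint row/column
permutation mode is available as the structure-preserving alternative.
The mean absolute τ_A is reported alongside.

### Superclass-level comparison

The superclass RDM block-averages the stimulus RDM: off-diagonal entry
(s, t) is the mean dissimilarity over cross pairs, the diagonal entry
(s, s) the mean over distinct within-superclass pairs.  Object-level
RDMs are compared on their strict upper triangle (their diagonal is
identically zero).  Superclass-level RDMs are compared **including the
diagonal**: with a small number of superclasses whose prototypes carry
no graded similarity structure (they are i.i.d. draws in the synthetic
generator), the cross-superclass block means are exchangeable and their
rank order is uninformative, whereas the within-vs-between contrast —
within-superclass means far below cross means — is precisely the coarse
representational organisation whose persistence the hierarchy analysis
measures.  Excluding the diagonal would make the superclass statistic
blind to that signal at desk scale.

## The synthetic dataset generator

The generator emulates the statistical structure the experiments need
from a CIFAR-100-like dataset — balanced classes nested in balanced
superclasses, within-superclass similarity exceeding between-superclass
similarity — with a three-level Gaussian model: superclass prototypes
`μ_s = 0.5 + blur(N(0, σ_sup²))`, class prototypes `μ_c = μ_s +
blur(N(0, σ_cls²))`, images `clip(μ_c + N(0, σ_noise²), 0, 1)`.  The
5×5 box blur (radius 2 px) gives prototypes local spatial correlation so
convolutional features are informative; pixel noise is unblurred.
Defaults: 5 superclasses × 4 classes, 16×16 single-channel images, 100
train / 50 test images per class, `(σ_sup, σ_cls, σ_noise) = (0.5,
0.15, 0.1)`.  Requiring `σ_cls < σ_sup` makes superclass structure
dominate, which is the prerequisite for the hierarchy analyses.  The
root seed spawns three fixed streams (`seed`, `seed+1`, `seed+2`) for
prototypes, train draws and test draws, so splits are disjoint and the
dataset is a pure function of its config.

What the generator does **not** emulate: photographic content, graded
semantic similarity *between* superclasses (prototypes are i.i.d., so
there is no animate/inanimate-style gradient), heavy-tailed or
structured noise, and class imbalance.  Passing tests therefore
demonstrate the pipeline's correctness and the within-vs-between
hierarchy effect, not claims about natural-image statistics.

## Models and training

`small-cnn` (the desk-scale reference): conv 3×3×8 → pool → conv 3×3×16
→ pool → dense_1(64) → dropout → dense_2(32, penultimate) → dropout →
C-way softmax.  He-normal conv init, Glorot-uniform dense init, RMSprop
(lr 10⁻³, ρ 0.9), batch 64, softmax cross-entropy, 30 epochs, 30%
dropout.  Epoch shuffling, dropout masks and initialization all derive
from the config seed; training is bit-reproducible (the numpy
implementation has no nondeterministic kernels, so deterministic mode is
simply always on).

`vgg19-cifar100` (the replication profile): the 16-conv VGG-19 stack
with user-supplied pretrained kernel/bias tensors, 4× nearest-neighbour
input upscaling to 128×128, two 1000-neuron dense layers with 30%
dropout, C-way softmax; RMSprop at lr 3×10⁻⁵ for 40 epochs, trained
end-to-end.  Building without a pretrained-weights file is a hard error
— silently random-initializing the conv stack would not be the
replication topology.  Batch size and loss are not pinned by the
training recipe this profile replicates; the package documents its
choices (64, cross-entropy) in the config.  Running this training is
GPU-scale and outside the test surface.

Replicate training draws seed `base + 1 + r` for replicate `r`; every
replicate is retained regardless of its final accuracy.  Training
consumes only class labels; the superclass structure never enters the
optimizer, so superclass organisation found in the representations is
emergent.  Dropout is inactive at inference and the fully-trained
uninjured model contains all neurons and weights.

## The experiment runner

Per replicate: train the uninjured baseline, compute its reference RDMs
(object and superclass level) on a fixed RSA condition set (the first
10 test stimuli of each class — 200 conditions at desk scale; the
subset size is configurable), then walk the schedule cumulatively.
Accuracy and within-superclass error are recorded at every increment;
RDMs and τ_A against the *same replicate's* uninjured reference only at
the configured checkpoints (full-schedule RSA is a flag).  Summaries are
mean and sample SD (n−1) per metric per fraction; undefined
within-superclass values are excluded from that metric's n, and a single
contributing replicate reports SD = 0 with n = 1.  Exports: a
`records.csv` with the fixed column order `replicate_id,
injured_fraction, accuracy, within_superclass_error_rate, tau_a_object,
tau_a_superclass` (missing values are empty fields, floats printed with
`%.17g` so reload is bit-faithful), a long-format `summaries.csv`, an
HDF5 RDM container, and a `manifest.json` recording the config and every
derived seed.  Statistical machinery beyond mean ± SD (ANOVA, post-hoc
corrections) is intentionally not reimplemented; the exports are shaped
for external stats tools.

Desk-scale study conditions (used by the acceptance suite and
`scripts/acceptance.py`): default generator, small-cnn with 30 epochs,
5 replicates, injury increment 0.005 to max fraction 0.5, RSA
checkpoints {0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5}.  These sizes keep the
full study in the minutes range on one CPU while leaving every
qualitative effect measurable.  The schedule endpoint is configurable;
0.5 comfortably passes the point where accuracy reaches chance.

## Numerical and degenerate-input conventions

- Arg-max ties → lowest class id (deterministic).
- Max-pool backward splits gradient equally among tied maxima in a
  window (ties have measure zero for continuous activations).
- Pearson on zero-variance rows → dissimilarity 1, logged.
- τ_A needs ≥ 2 entries; the scrambled floor needs ≥ 3 conditions.
- `target_count` rounds half away from zero; fractions outside [0, 1]
  are rejected.
- A schedule with `max_fraction = 0` is the baseline-only experiment.
- RDM entries are clipped to [0, 2] and symmetrized against float
  round-off before validation.

## Known limitations

- The synthetic generator has no between-superclass similarity gradient,
  so analyses that depend on graded coarse structure (e.g. stable
  rank order among cross-superclass dissimilarities) are noise-dominated
  at desk scale; the superclass comparison includes the within/between
  contrast for exactly this reason.
- With 5 superclasses the superclass τ_A is quantized (one rank swap =
  2/105 with the diagonal included); per-checkpoint curves are
  correspondingly coarse.  At the replication scale (20 superclasses)
  the statistic is much finer.
- The numpy network is CPU-only and desk-scale; the VGG-19 profile is
  provided for structural fidelity and config-level replication, not CI
  execution.
- Injury states chain linearly (the RNG stream is shared along the
  course); branching two alternative futures from one intermediate state
  is not supported.
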