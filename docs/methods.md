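# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, and what the synthetic data can and cannot
show.

## Grey wolf optimization

The pack hierarchy model keeps the three best-ever solutions (alpha, beta,
delta) and moves every agent to the average of three elite-directed pulls.
The coefficient vectors are drawn once per agent per dimension and shared by
the three pulls — the update equations use a single A/C pair — rather than
per elite, which is the other common convention. The distinction matters:
with shared coefficients the three pulls are correlated, the step noise is
larger, and the plain optimizer converges more slowly; the improved
variant's regeneration then provides a measurable benefit. With per-elite
draws the plain optimizer is already near its noise floor on smooth
problems and the regeneration's effect is neutral at best. We implement the
shared-coefficient form.

Box constraints are enforced by clipping. Integer dimensions (intensity
thresholds, filter counts) are rounded half-up *at evaluation time* while
the stored positions remain continuous. Rounding the stored positions after
every move discards sub-integer gradient information and makes the pack
prone to stalling one unit away from an integer optimum; with continuous
storage a position drifting from 64.7 to 64.4 crosses the rounding boundary
gradually and the stall largely disappears (we measured the per-run
attainment of the exhaustive Kapur maximum at m=3 rise from ~92% to ~99%).

### Fitness-based omega regeneration (the improved variant)

Each iteration, after the move and the greedy merge, agents are ranked by
fitness (ties broken by agent index) and the worst `floor(r*N)` are
eliminated, capped at `N - 3` so the elites always survive. Each eliminated
agent is replaced by

* an exact copy of one elite, with probability `p = 0.7`, the elite drawn
  with rank-proportional weights 3:2:1 for alpha:beta:delta; or
* a Gaussian resample `x_alpha + sigma * g`, `g ~ N(0, I)`,
  `sigma = 1/(t+1)`.

Two consequences of the implementation deserve explicit statement:

1. **Resamples are evaluated immediately** and may update the elites. The
   decaying probe around alpha is the mechanism's exploitation half — a
   shrinking local search. If resamples were only evaluated after their
   next move, the probe would never be observed at its sampled position and
   the mechanism would be inert (hyperparameter-recovery experiments drop
   from ~90% to ~30% exact recoveries without immediate evaluation).
2. **Regenerated wolves carry no greedy memory**: their first subsequent
   move is always accepted. If elite copies kept the elite's fitness as
   their personal memory, the greedy rule would freeze them at the elite
   (no move from an optimum is accepted), and a growing fraction of the
   pack would stop searching; we observed clear diversity collapse on
   multimodal benchmarks in that variant. An eliminated wolf's memory dies
   with it; its replacement is a new agent.

With these semantics the objective is called `N*(T+1)` times plus once per
Gaussian resample (on average `T * floor(r*N) * (1-p)` extra calls).

Known limitation: on mixed integer/continuous spaces with a tight iteration
budget (e.g. T=50) the final integer coordinates occasionally settle one
unit off the optimum and the continuous coordinate lands just outside a
1%-of-range tolerance; at T=200 this is rare. The sigma schedule is
absolute (not range-scaled), so on wide integer ranges the late probe
cannot flip an integer coordinate — only the move dynamics can.

## Preprocessing

* **Gaussian denoise** (sigma 0.5 px by default). The light setting is
  deliberate: sensor-like pixel noise must come down below the hair
  detector's difference threshold, but stronger smoothing widens the
  lesion's boundary ramp and biases the entropy threshold toward the
  background mode, inflating the segmented area by one to two pixels of
  ring (median IoU drops from ~0.94 to ~0.87 at sigma 1.0).
* **Hair removal.** Grayscale closing with a square 7x7 element lifts dark
  structures thinner than the element to the local background; luminance
  differences above 10 grey levels form the raw artifact mask. The mask is
  cleaned by dropping 8-connected components smaller than 16 px — hairs are
  long, so their components are large, while texture specks are not — and
  consolidated with a 3x3 binary closing. A plain 3x3 opening, the obvious
  alternative, deletes every mask thinner than three pixels and with it
  every thin hair, defeating the operation's purpose. Masked pixels are
  replaced from the closed image (default) or by a local median.
* **Contrast stretch.** Per-channel linear min-max stretch to [0, 255]
  through a 256-entry lookup table, rounding half-up; constant channels
  pass through. The stretch is idempotent and attains both extremes on any
  non-constant channel.

The chain order is denoise, hair removal, contrast stretch; hair removal
assumes denoised input.

## Kapur-entropy segmentation

For an intensity histogram p_0..p_255 and thresholds partitioning the grey
levels into m classes, each class contributes H_j = ln(w_j) - S_j / w_j,
where w_j is the class probability mass and S_j = sum p_i ln p_i over the
class; J = sum H_j is maximized. Empty bins and empty classes contribute
zero, so J >= 0 always. Prefix sums make a candidate evaluation O(m), and
the optimizer evaluates whole populations in one vectorized call.

The search runs over integer thresholds in [1, 254], minimizing -J, and is
repeated 25 times with sub-seeds spawned from the master seed; the final
thresholds are the per-position mean of the sorted per-run thresholds,
rounded half-up, with duplicates resolved by incrementing (logged). An
exhaustive search over all single thresholds (254 candidates) and all
threshold pairs (~32k) serves as the oracle in the tests; the averaged
search result has matched the oracle's maximum in every run we have
recorded, and individual repeats attain it in ~95-100% of runs depending on
histogram difficulty.

Binarization takes v >= th into the upper class; the darkest class is the
lesion by default (melanocytic lesions are darker than surrounding skin;
configurable). Morphology: border-seeded hole filling, opening, closing,
all with a 3x3 full structuring element (erosion uses border value 1 and
dilation 0, which makes closing exactly the complement-dual of opening),
then the largest 8-connected component. An empty result warns rather than
raises.

## The CNN and its training protocol

Architecture: three conv blocks (3x3 kernels, same padding, ReLU, 2x2
max-pool with floor division) with f1, f2, f3 filters, flatten, dense 128
ReLU, dropout d, softmax output. The parameter count follows the closed
form 9*c_in*f + f per conv block plus the dense layers; for input 32x32x3
and filters (32, 64, 128) this gives 355,778 trainable parameters. Inputs
are 8-bit images rescaled to [0, 1]; the full-scale protocol feeds
225x225x3, desk-scale work uses 32x32.

Training minimizes class-weighted categorical cross-entropy (weights
inversely proportional to class frequency, w_c = n/(k*n_c), so the weighted
sample mean is 1) with RMSprop (lr 1e-3, rho 0.9, eps 1e-7), plus an
optional L2 penalty wp/2 * sum(w^2) on the connection weights. Validation
loss is unweighted; early stopping restores the best-validation weights
after `patience` epochs without improvement. The squared-error measure
E = (1/T) * sum (f - y)^2 over the softmax outputs is reported as a
separate metric, not used as the training loss.

The network and its backpropagation are implemented directly in numpy
(im2col convolutions); training is deterministic given the seed. RMSprop's
per-parameter step is scale-invariant (~lr per update), so learning
progress is governed by the *number of updates*: at desk scale the
default batch size is 16 (the full-scale protocol value is 32) so that a
few epochs over a few hundred images supply enough updates. Ten epochs over
175 images train in a few seconds on one CPU.

Dataset plumbing: patient-grouped stratified 70/15/15 splitting assigns
whole patients to splits by relative-need allocation (malignant-bearing
patients first, each to the split with the largest relative malignant
deficit, then the rest by image-count deficit); no patient ever straddles
splits. Patient-grouped stratified k-fold uses scikit-learn's
StratifiedGroupKFold.

## Hyperparameter search

The search space is (f1, f2, f3) integer in [16, 256] and d continuous in
[0.2, 0.8]. The objective is the CNN's best validation loss trained with
the fixed protocol on a patient-grouped stratified subset of the training
split (15% by default, fixed once per search). Candidate fitness is cached
by decoded value, so elite copies produced by the regeneration cost no
training runs. Desk-scale defaults (small optimizer budget, few epochs,
small images) are the package defaults; the full-scale protocol (N=30,
T=200, 50 epochs per candidate at 225x225) is preserved as the "full"
profile but is a GPU-scale computation.

## Evaluation metrics

Confusion counts treat malignant as the positive class. Precision,
sensitivity, specificity, F1, accuracy; balanced accuracy, G-mean, Matthews
correlation and Cohen's kappa for imbalance-robust reporting. Any metric
with a vanishing denominator is reported as an explicit undefined marker
(`None`), never silently as 0 or 1: with 10% prevalence, a classifier that
predicts everything benign still scores 86% accuracy, and only the
undefined/near-zero imbalance-robust entries reveal it. AUC uses the rank
(Mann-Whitney) statistic with mid-rank tie handling, which equals
trapezoidal ROC integration exactly.

## Synthetic data: what it emulates, what it does not

A lesion is a radially perturbed ellipse on a noisy bright background:
radius modulated by harmonics 3-8 with amplitude `irregularity`, plus a
first-harmonic `asymmetry` term. Benign-like lesions are smooth and
homogeneous (irregularity 0.08, asymmetry 0.05, texture sigma 7); the
malignant-like class differs geometrically and in texture variance
(irregularity 0.32, asymmetry 0.25, sigma 28) while *sharing the benign
mean intensity* (90 against background 180 +- 6), so a classifier cannot
succeed with a global brightness threshold. Hair artifacts are dark
anti-aliased Bezier arcs at least 40 levels below the background with exact
stroke masks. Default prevalence is 10% malignant; malignant images are
concentrated on a melanoma-prone patient pool of about twice the image
prevalence, mirroring screening collections where a melanoma patient
contributes a couple of malignant images among several benign ones. All
randomness flows through per-record sub-seeds hashed from (manifest seed,
record index), so any record regenerates byte-identically.

What passing tests show: the pipeline is wired correctly, the optimizer
drives the entropy criterion to its true maximum, splits are leakage-free,
class weighting behaves as intended, and the CNN can learn shape/texture
differences. What they do not show: performance on real dermoscopy. Real
lesions have colour structure, ill-defined borders, imaging artifacts
beyond hair, inter-device variation, and a far harder class boundary; the
synthetic classes are separable by construction, so saturated desk-scale
metrics carry no clinical meaning.

## Numerical conventions

Rounding is half-up (`floor(x + 0.5)`) everywhere an 8-bit value is
produced. Grayscale conversion is the BT.601 luminance. Fitness ties in
ranking break by agent index; elite updates use strict comparisons so equal
fitness never displaces an incumbent. All stochastic components accept
integer seeds and use numpy Generators; sub-seeds are spawned via
SeedSequence and kept below 2^31.

## Known limitations

* The improved optimizer's advantage is exploitation-flavoured; on strongly
  multimodal objectives its elite cloning can reduce diversity, and its
  benefit over the plain optimizer shrinks as the iteration budget grows.
* The hyperparameter search at tight budgets can return a filter count one
  unit off the optimum (see above).
* The hair detector is tuned for dark hairs on brighter skin; bright or
  low-contrast artifacts (gel bubbles, specular glints) are out of scope.
* Median-mode inpainting is O(masked pixels * window) and slow for very
  dense hair.
* The CNN is a compact reference implementation, not a performance
  framework: single-threaded numpy, float32, no augmentation.
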