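# Methods

`readerbias` is a simulation pipeline for a question that comes up whenever a
medical-imaging dataset is labeled by several readers without consensus: how
much does annotation bias in the training labels degrade a binary image
classifier, and how much of that degradation can a label-free consistency
regularizer recover? The pipeline has five stages — synthetic data generation,
bias injection, model training, grid evaluation, and slope analysis — each
usable on its own.

## The error models

Labels are binary (0 = normal, 1 = lesion). Three reader-error models operate
on the training (and optionally validation) labels; the test split always
keeps its true labels.

* **Random error** at overall level *p*: a fraction *p* of each class is
  flipped. It is an equal mixture of false positives and false negatives,
  modeling accidental mistakes such as fatigue.
* **False-positive systematic error** at overall level *p*: a fraction *2p*
  of the negatives is flipped to positive; positives are untouched. This
  models a reader who consistently over-calls disease.
* **False-negative systematic error**: the mirror image on the positives.

On a class-balanced split all three constructions realize the same overall
introduced-error rate *p*, which is what makes the three bias types directly
comparable at a given level. Flip counts are exact, not binomial draws: the
number of flips in a class of size *n* at rate *r* is round-half-up(*r·n*),
and the flipped rows are sampled without replacement from an RNG stream keyed
by (seed, split, class), so the realization in one class is independent of
the other. Injection always starts from the true labels — re-injecting into
an already-biased manifest can never compound flips. Levels are restricted to
[0, 0.5) so that the systematic per-class rate *2p* stays below 1.

## Synthetic images

Class 0 is a flat background (default gray level 0.3) plus i.i.d. Gaussian
pixel noise (default sd 0.10); class 1 adds 1–3 additive isotropic Gaussian
bumps (default amplitude 0.12, spatial sd 3 px) at uniform random positions
in a 32×32 frame, clipped to [0,1] and stored as 8-bit PNG. The bumps stand
in for soft pulmonary opacities: a localized, low-contrast, position-variable
signal. The amplitude/noise ratio is the contrast-to-noise dial; the default
was calibrated once so that a small CNN trained on clean labels reaches a
test AUC in the mid-0.9s — discriminable but imperfect, leaving visible
headroom for label noise to erode. Every image is a pure function of
(dataset seed, row index), so changing one split count does not reshuffle
the other images.

What the generator deliberately does not emulate: anatomical structure,
inter-image intensity calibration differences, input-dependent reader error
(ambiguous lesions are no harder to label than obvious ones here), and any
correlation between readers. Passing the qualitative tests on this generator
shows the pipeline's mechanics and the direction of the effects, not effect
sizes on real radiographs.

## Models and losses

Images are resized to the network's input side, replicated to 3 channels,
and normalized v → (v − 0.5)/0.2365.

The desk-scale backbone (`small_cnn`) is three 3×3 conv blocks (8/16/32
channels, each conv–ReLU–2×2-max-pool) followed by a flattened linear
two-class head, ~9k parameters, implemented in NumPy with hand-derived
backward passes and trained with Adam (lr 1e-3). The flatten head (rather
than global average pooling) is deliberate: its position-specific weights let
this small network partially memorize individual training images, which is
the overfitting behavior under label noise that the study depends on. The
`resnet18` backbone name is reserved for full-scale work and is not included
in this build.

The baseline objective is mean cross-entropy against the (possibly biased)
labels, computed on an augmented view of each batch. The improved objective
adds **paired softmax divergence regularization (PSDR)**: for two
independently augmented views x′, x″ of the same image,

    L = L_CE + α · mean_t KL( f(x′_t; θ) ‖ f(x″_t; θ) ),

with KL in natural log, ε-clamped at 1e-8, and gradients flowing through
both views (d/dz′ = p′(log(p′/p″) − KL), d/dz″ = p″ − p′, verified against
finite differences). The batch aggregation is a mean rather than a sum so
that α has a batch-size-invariant scale. Augmentation is horizontal then
vertical random flipping, each with probability 0.5, drawn independently per
view; with flip probabilities (0,0) the two views coincide and the improved
model is gradient-identical to the baseline. Because the penalty never sees
the labels, it cannot be misled by them; it rewards augmentation-consistent
predictions, which resists fitting label noise.

## Training protocol

Up to 50 epochs by default (the desk-scale experiments cap at 30, see
below), Adam at 1e-3, batch 32, early stop when the running training loss
has not decreased by ≥ 1e-4 *and* the end-of-epoch training accuracy has not
increased, for 5 consecutive epochs. The history records, per epoch, the
running training loss, the end-of-epoch accuracy on the un-augmented
training inputs against the training-time labels (the curve an overfitting
plot shows), and validation accuracy/AUC. Everything is seeded: weight
initialization from the model spec, data order and the two augmentation
streams from the repetition seed.

α is selected by grid search: one fit per candidate from identical seeds,
choosing the α with the highest validation AUC, ties toward the smaller
(less regularized) value. Validation labels are kept clean in the built-in
experiment grid so that α selection is not itself corrupted by the bias
under study; biasing the validation split is supported for studying that
corruption.

## The experiment grid

One cell = (bias type, level, model variant, repetition). Each (bias type,
level) pair fixes one bias realization; repetitions rerun training with
repetition seed = base_seed + r (42, 43, …), which also varies weight
initialization — so repeat-to-repeat spread reflects optimization
randomness under a fixed relabeling, mirroring a protocol that repeats only
the train/evaluate steps. Test AUC is always computed against the true test
labels with the un-augmented test images. At level 0 every bias model is the
identity, so those cells are trained once per (variant, repetition) and
shared across bias types. Cells persist as JSON files and are skipped on
rerun, making an interrupted grid resumable.

Desk-scale defaults used by the acceptance experiment: 200 training images
per class, 50 per class validation, 100+100 test, levels {0, 10%, 25%},
3 repetitions, 30-epoch cap, α fixed at 1.0 (a singleton grid). The 30-epoch
cap is the closest point to the 50-epoch protocol at which the full grid
remains a desk-scale computation; shorter caps keep the network out of the
overfitting regime that the study is about. Fixing α avoids multiplying the
grid by the tuning grid; the tuning machinery itself is exercised on smaller
fixtures.

## Slope analysis

AUC is the Mann–Whitney statistic computed from midranks — exactly
(#concordant + 0.5·#tied)/(n₊·n₋) — rather than trapezoidal ROC
integration: one formula, exact under ties, testable against brute-force
pair counting.

Error levels are expressed in percentage points, so slopes are "AUC lost per
point of introduced error" (a few thousandths per point in practice). Per
bias type, ordinary least squares of AUC on level with a two-sided t-test of
slope = 0; repetitions enter as independent observations. Across bias
types, the classical homogeneity-of-slopes ANCOVA: F compares the model
auc ~ type + level + type:level against auc ~ type + level via
F = ((RSS_r − RSS_f)/(G−1)) / (RSS_f/(n−2G)), with p from the F
distribution. Numerically exact fits (RSS below 1e-12 of the total sum of
squares) are treated as zero-residual so that noise-free fixtures give F = 0
rather than a 0/0. The implementation is closed-form linear algebra; its
simulated operating characteristics (type-I error near nominal, slope
recovery, power against separated slopes) are part of the test suite.

## Known limitations

* The effect sizes are specific to the generator and the small CNN; the
  desk-scale protective effect of PSDR is modest (slope differences of
  ~0.001 AUC per percentage point) and is established per bias type only in
  direction, not magnitude.
* One-sided false-positive bias degrades this synthetic task far less than
  false-negative or random error (the positive-class evidence survives
  relabeling of negatives), so the regularizer has little room to show
  benefit there.
* Reader structure (per-reader error rates, correlation, input-dependent
  difficulty) is out of scope; errors are conditionally independent of the
  image given the true label.
* The NumPy backbone is single-threaded and desk-scale; it is not a
  substitute for full-resolution training and its absolute AUCs should not
  be compared with published full-scale numbers.
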