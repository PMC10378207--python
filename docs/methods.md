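# Methods

## Problem setting

A micro-expression is a brief (< 0.5 s), low-intensity, involuntary facial
movement. Clips are annotated with an *onset* frame (action begins), an
*apex* frame (maximal intensity) and an *offset* frame (action ends), and
the recognition task is to assign an emotion label to the clip. Two
properties shape the method: datasets are tiny (a few hundred clips) and
strongly class-imbalanced, and the discriminative signal is a localized,
sub-pixel to few-pixel motion rather than appearance.

`mexflow` represents each clip by the dense motion between onset and apex
alone and classifies that summary with a small attention CNN under a
prior-adjusted loss, evaluated by leave-one-subject-out (LOSO)
cross-validation.

## Preprocessing

**Apex spotting.** When the apex index is not annotated, it is found from
texture change: the face crop is divided into three fixed fractional boxes
(mouth: rows 0.60–0.95, cols 0.20–0.80; each eye+brow: rows 0.10–0.45,
cols 0.05–0.50 and 0.50–0.95). Per box and frame we compute a 59-bin
uniform LBP(8, 1) histogram (square 8-neighbourhood, neighbour ≥ centre,
58 uniform bins + 1 pooled non-uniform bin) and its chi-squared distance
(guard 1e-10) to frame 0. The box with the largest peak distance is
selected, and its distance signal is searched by divide and conquer:
recurse into the half with the larger mean, stop at windows of ≤ 3 frames,
argmax there, ties to the lower index. The search runs on a width-3
moving average of the signal (frame 0, whose distance is identically zero
by construction, stays out of the smoothing window) and the result is
refined to the raw signal's argmax within one frame — frame noise
otherwise creates local dips that can steer the half-mean decision away
from a peak adjacent to a split point. A sequence with no measurable
texture change returns index 1 under a `DegenerateSignalWarning`. Fixed
boxes stand in for landmark-based ROIs because face landmarking is out of
scope; the `RoiSpec` is user-overridable.

**Flow and strain.** Frames are resized to 170 × 140 before flow. Dense
displacement is TV-L1 optical flow (scikit-image implementation, default
pyramid settings), chosen for its robustness at small displacements and
motion-edge preservation; the solver sits behind
`compute_optical_flow` so any dense method meeting the
quarter-pixel translation-recovery contract can be substituted. The
optical-strain map is the Frobenius norm of the symmetric flow gradient,

    eps = 1/2 (∇Of + ∇Of^T),   os = sqrt(eps_xx² + eps_yy² + 2 eps_xy²),

with both off-diagonal terms counted (the standard reduction in the
optical-strain literature). Derivatives are central differences, one-sided
at borders, so any quadratic flow field is differentiated exactly in the
interior and a rigid translation has exactly zero strain.

**Triplet assembly.** (u, v, os) are each min–max normalized to [0, 1]
per sample and per channel, then bilinearly resized to 28 × 28. A constant
channel maps to all 0.5. Per-sample normalization is used because no
dataset-level statistics exist for arbitrary user data; the cost is that
absolute motion amplitude is discarded, only its spatial pattern is kept.
Whether flow should be computed at full resolution and then shrunk, or
computed at 28 × 28 directly, is an open choice; we compute at 170 × 140
and shrink, which preserves fine strain structure.

## Network

Each channel of the triplet feeds its own branch (parameters not shared):

    1×28×28 → inception(k=6) → 24×28×28 → maxpool2 → 24×14×14
            → inception(k=16) → 64×14×14 → maxpool2 → 64×7×7
            → MSFF(24×14×14, 64×7×7) → 128×7×7

An inception block runs four 'same'-padded ReLU paths (1×1; 1×1→3×3;
1×1→5×5; 3×3 maxpool→1×1), each emitting k channels; the 1×1 reduction
width equals k. **MSFF** fuses the two pyramid levels: the earlier level is
2×2 max-pooled, aligned by a 1×1 convolution, summed with the later level
and gated by spatial attention; the later level passes through its own
spatial-attention gate; the two gated maps are concatenated. Spatial
attention is the canonical gate sigmoid(conv7×7([channel-mean,
channel-max])). **MOFRW** then makes the three 128×7×7 branch maps compete:
one *shared* squeeze-excitation channel-attention module (reduction 4)
scores each branch, the three score vectors pass through an elementwise
softmax across branches (so the weights form a 3-way simplex per channel),
each branch map is scaled by its weight, and the concatenation is added
residually to the concatenated input, giving 384×7×7. Sharing the CAM
makes identical branches provably receive weight exactly 1/3. The head is
global average pooling plus a single fully connected layer — deliberately
minimal for datasets of a few hundred samples.

Weights are He-normal, biases zero, all seeded. The network runs on a
small in-repo reverse-mode autodiff engine over numpy (im2col/einsum
convolutions, float32); at ~50 k parameters a framework dependency is not
needed, and every gradient is verified against finite differences in the
test suite.

Ambiguities resolved as design choices: MSFF sums the aligned earlier
level with the later level *before* its attention gate; MOFRW's softmax
runs across the three branches (not across channels within a branch); the
classifier head and the 1×1 reduction widths are our choices, not derived
from a reference.

## Loss

With class priors p_y estimated on the training split only (never on test
subjects), the logit corrections are a_y = log(p_y^τ + ε), default τ = 0.5
and ε = 1e-12, and LASCE is standard softmax cross-entropy on logits + a
in log-sum-exp form. At τ = 0, a is constant and LASCE coincides with
plain cross-entropy exactly (softmax shift invariance). Plain CE, focal
(γ = 2) and logit-adjusted focal variants are provided for ablations. One
published formulation multiplies the log-softmax by prior-dependent
weights summed over all classes; that form is not a proper cross-entropy
and breaks the τ = 0 equivalence, so the label-indexed form above is used.

## Training and evaluation

Adam (lr 1e-4, weight decay 1e-4 added to the gradient), batch size 8,
70 epochs by default, no schedule and no early stopping. Augmentation:
horizontal flip with probability 0.5 — applied to the normalized triplet
as mirror + u → 1 − u, which is exactly the normalized image of the raw
sign-flipped u field — and per-channel affine dither (scale 0.9–1.1,
shift ±0.05, clipped to [0, 1]). One seed governs initialisation,
shuffling and augmentation; the whole stack is pure single-threaded
numpy, so a fixed seed reproduces reports bit for bit on CPU.

LOSO: one fold per subject, ordered by subject id; predictions are pooled
across folds into one confusion matrix (per-fold accuracies are stored
too, and the headline accuracy is the pooled one). Metrics: per-class
recall Acc_c = TP_c/N_c, F1_c = 2TP_c/(2TP_c+FP_c+FN_c), and their
unweighted means UAR and UF1; a class absent from all test folds is
excluded from the means and listed in the report. Argmax prediction ties
break toward the lower class index.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes —
not faces. Each class is a set of Gaussian displacement bumps
(row/col/radius as fractions, one direction per bump) placed where facial
action units live (mouth, brows, cheeks, chin, forehead); flow is the sum
of bumps at amplitude 2 px, plus a per-subject random affine flow
perturbation (sd 0.2 px, ≈10 % of amplitude, fixed per subject so LOSO
generalisation is non-trivial), plus i.i.d. pixel noise (sd 0.2 px).
Defaults: 3 classes × 30 samples, 10 subjects, 170 × 140 rasters. Because
facial actions are roughly bilaterally symmetric, every default class is
invariant as a set under horizontal mirroring (midline loci with vertical
motion, or left/right pairs with mirrored directions); without this the
flip augmentation would map one class's template onto another's, which no
real emotion class does. Frame sequences warp a smooth random texture
(Gaussian-filtered white noise, σ = 2 px — dense-flow solvers need
texture everywhere) by the class flow scaled with a tent ramp peaking at
round(0.6 · (T − 1)); warping is inverse bilinear with replicated borders.

A cosine nearest-class-template classifier run LOSO certifies
separability (≥ 0.95 accuracy at the default noise level), so training
results on the benchmark are about the network, not about an impossible
task. What passing on this benchmark does **not** show: robustness to
illumination change, registration error, landmark drift, head pose, or
the appearance variability of real faces.

## Benchmark problem sizes

The acceptance runs use: (a) the separable benchmark above with 30
training epochs per LOSO fold (10 folds); (b) an imbalanced benchmark with
per-class counts (60, 32, 27, 25, 102) — the shape of a real five-emotion
distribution — over 8 subjects, evaluated per seed on a fixed 4-subject
holdout with 30 epochs, for 5 seeds per loss. These sizes are the
package's scaled benchmark; they keep a full acceptance run in the
minutes range on one CPU core while leaving the training dynamics
(hundreds of Adam steps at batch 8) representative.

One caveat the scaled sizes introduce: 30 epochs on 81 training clips is
about 330 Adam steps at lr 1e-4, which is at the convergence edge for
the hardest class. Measured over optimizer seeds {1, 2, 3, 5, 42} the
pooled LOSO accuracy on benchmark (a) is {0.68, 0.99, 1.00, 0.80, 1.00}:
when a seed falls short, every fold sits at exactly 2/3 with the
training loss still descending — one class has not yet separated, not a
fold-specific collapse. Longer training resolves it (the loss keeps
falling), but 30 epochs is kept as the benchmark's training length; the
package default remains 70 epochs.

## What the attention maps do and do not show

Grad-CAM at the post-MOFRW map is the package's visualization default.
One finding from the synthetic benchmark should temper its
interpretation: with a global-average-pooled head, the class logit is a
spatial mean, so the logit's gradient at the final feature map is
constant over positions and Grad-CAM reduces to a class-weight-weighted
activation map (CAM). On the synthetic benchmark the trained network
then encodes class identity in spatially diffuse channel patterns — the
feature *magnitude* peaks exactly at the true motion locus, but the
class-evidence map does not, and the heatmap argmax is not a reliable
pointer to the moving region (measured: argmax inside the 2σ support of
the true displacement bump for 0 % of held-out samples, at every
candidate target layer). A position-preserving flattened head combined
with the element-wise gradient–activation attribution (`method="hires"`)
recovers genuine localization for mid-face classes but places the
evidence for upward-motion classes one 7 × 7 feature cell above the
locus — at the motion's destination — reaching 33–50 % depending on
training length. At the 7 × 7 attribution resolution one cell spans
roughly 24 × 20 source pixels, the same order as the locus disk itself,
so argmax-level localization is at the resolution limit. Heatmaps should
therefore be read as coarse, qualitative summaries, not as detectors of
the moving facial region.

## Numerical choices and degenerate inputs

* constant image pairs → zero flow (the TV prior's minimiser);
* constant channels → 0.5 after normalization; zero-gradient Grad-CAM →
  all-zero heatmap;
* chi-squared guard 1e-10; loss guard ε = 1e-12; CAM reduction clamped to
  1 (with a warning) when a map has fewer channels than the reduction;
* max-pool gradient splits ties evenly; argmax ties break to the lower
  index everywhere;
* float32 throughout the network; float64 in preprocessing.

## Known limitations

* No face detection/cropping: inputs must be pre-cropped, roughly frontal
  faces (a cropping hook can be layered on top).
* Fixed fractional ROIs assume a centred face; apex spotting degrades if
  the crop is loose.
* The divide-and-conquer apex search is exact only for signals whose
  half-means point toward the global peak (true for the tent-like signals
  it is designed for); it can miss a peak on strongly multimodal signals.
* Per-sample min–max normalization discards absolute motion amplitude.
* The synthetic benchmark is far easier than real micro-expression data;
  its accuracies say nothing about accuracy on CASME-class datasets.
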