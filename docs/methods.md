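# Methods

## Problem

Clinical assessment of facial acne rests on three linked quantities: the
number of lesions in a half-face photograph, the ordinal severity grade
derived from that number (a simplified Hayashi-style count scale), and the
position of each lesion. `acnedet` implements an ensemble of two neural
modules that predicts all three at once:

1. a **classification module** — a convolutional encoder with two linear
   heads, one over severity classes and one over count categories
   `1..C_max`;
2. a **localization module** — a multi-scale one-anchor box detector with,
   optionally, two fully connected classification heads appended on its
   pooled feature maps.

The two are fused at inference by **count-guided selection**: the
classifier's predicted count `k` replaces the detector's preset confidence
threshold, and the `k` highest-confidence candidates (after ordinary NMS)
become the output boxes. The sweep experiment in `evaluation.confidence_sweep`
shows why: count error as a function of a fixed confidence threshold has a
sharp interior minimum that shifts with lesion density, so no single preset
works across images.

## Grading and label distributions

Severity is a piecewise-constant function of the count: mild for 1–5,
moderate for 6–20, severe above 20, counts supported on 1–65. A four-level
variant (very severe > 50) is available via `GradingScheme.hayashi4()`.

For label-distribution learning the count label µ is softened into a
discrete Gaussian over the integer bins x = 1..C_max,

    p(x) ∝ exp(−(x − µ)² / 2σ²),   σ = 3 by default,

renormalized so boundary truncation is absorbed. The severity target is
the Gaussian's mass aggregated over the grading ranges. Aggregation (rather
than an extra learned severity transform) was a genuinely open design
point; mass aggregation keeps the two targets exactly consistent and needs
no extra parameters.

## Losses

Three head losses are provided (`losses`):

* weighted cross-entropy  `−1/N Σ w_y log x_y`;
* focal loss  `−1/N Σ w_y (1−x_y)^α log x_y`, α ≥ 0, default 2 — the
  modulating factor damps well-classified samples, and α = 0 recovers
  cross-entropy exactly (asserted to 1e-12 in the tests);
* KL divergence  `1/N Σ_j y_j (log y_j − log x_j)` against the Gaussian
  count distribution (predictions in log-softmax space, `0·log 0 := 0`).

Per-category weights come from training-set category sizes `n_j` under five
schemes: all-ones, raw sizes `w_j = n_j` (which up-weights *large*
categories — implemented as defined, pathologies included), min-max
normalization to [0, 1], standardization `(w − mean)/std` with the
*population* standard deviation (the sample/population choice was
unspecified; population is used and frozen in the reference values), and
the min-max result rescaled to sum to one. Standardized weights go
negative for small categories; they are passed through unmodified, and
training with them is expected to be able to collapse — that behaviour is
part of what the scheme comparison studies. An inverse-frequency scheme is
included as the field-standard practical option.

Joint detector training combines `α·loss_det + β·loss_cls` with
α = β = 0.5, weighting localization and classification equally.

## Architectures and training

All models run on a small numpy layer stack (`_nn`) with hand-written
analytic gradients (verified against finite differences in the test
suite); training is plain mini-batch gradient descent, fully deterministic
given a seed.

Classifier families: `resnet50_like` (7×7 stride-2 stem, max pool, four
bottleneck stages of 3/4/6/3 residual blocks with batch norm, average
pool, two heads; default input 224×224) and `tiny_cnn` (four stride-2
3×3 conv + ReLU layers, global average pooling, two heads; default input
96×96, ≈ 18k parameters). Global average pooling is what makes the tiny
variant count-capable: spot-detector channels pool to activations roughly
proportional to lesion count.

Detector families: `yolo_like` (conv–BN–SiLU blocks, default input
640×640) and `tiny_detector` (conv + ReLU), both emitting feature maps at
strides 4, 8 and 16 and a 1×1-conv detection head on the stride-8 map:
per-cell objectness plus box offsets (sigmoid cell offsets; sizes
`anchor·exp(t)`, anchor 10 px, `t` clipped to ±4). Every cell decodes to a
candidate (candidate floor 0 by default), so the count-guided selector is
never starved of candidates. Detection loss: class-balanced objectness
binary cross-entropy — lesion cells are a tiny fraction of the grid
(often 1 in 144), so the positive and background cells each contribute
half of the loss (background further scaled by 0.5), otherwise the
background gradient drowns the positives at this scale — plus
mean-squared box regression on positive cells scaled by 5. Each
ground-truth box is assigned to the cell containing its center (first
box wins a contested cell).

The appended detector heads pool the three maps by global average pooling,
concatenate, and apply FC → ReLU → two heads; the pooling choice was
unspecified and GAP+concat is the minimal one consistent with a
fixed-length feature vector. Two strategies train them:
**sequential** — detection loss first, then the backbone is frozen
(evaluation mode; parameters bitwise untouched, asserted in tests) and the
heads are trained with the KL loss; **joint** — one optimization of the
combined loss.

Default schedules: classifier — momentum-SGD, batch 32, lr 1e-3 halved
every 30 epochs, momentum 0.9, weight decay 5e-4, 120 epochs; detector —
Adam, batch 32, lr 3.2e-3 with a linear decay factor from 1 to 0.12 over
the run, β₁ 0.843, weight decay 3.6e-4. Pretrained weights are never
required; checkpoints store parameters, architecture config, normalization
statistics and the seed.

## Ensemble inference

`ensemble.predict`: NMS (IoU 0.45) on the decoded candidates, count
`k` = argmax of the count head (ties toward the smaller count), boxes =
top-k by confidence. NMS still runs before top-k — the fusion replaces the
confidence threshold, not duplicate suppression. If fewer than `k`
candidates survive, all are returned and a shortfall flag is set. By
default severity is recomputed from `k` through the grading scheme
(consistency mode), since the two heads can disagree; the raw severity
head is available with `consistent_severity=False`. The count can also be
taken from the detector's appended heads (`count_source="detector"`).

## Synthetic data

`synthetic` renders what the models must learn from: cone-like lesions —
a radial intensity peak with linear falloff, reddish against a skin-tone
background — each tightly enclosed by one box with the apex at the box
center. Per-image counts follow a truncated geometric distribution
(p = 0.1, support 1..65, mode 1), reproducing the long tail of real
count-annotated datasets. A per-image background tone jitter (±12 levels),
a linear illumination ramp in a random direction (±10 levels), and
Gaussian pixel noise (sd 3) provide nuisance variation. Spot centers stay
at least one radius apart so the ground-truth count is well defined; boxes
may still overlap. Default image size is 96×96, radius 4–6 px.

Presets: `easy` (counts 1..10, separation factor 2.3 so boxes never
overlap, mild illumination) and `hard` (counts 51..65, radius 3–5,
separation 1.0, illumination ±30, noise sd 6) — the hard preset targets
the regime where counting visibly degrades at very high lesion density.

What the generator does **not** emulate: faces and facial context
(contours, nose/mouth structure, hair), lesion-type heterogeneity
(papules vs. pustules vs. nodules), specular highlights, camera noise
statistics, scale variation between photographs. Passing the synthetic
experiments therefore demonstrates that the pipeline's machinery —
losses, label distributions, balancing, fusion — works end to end, not
that the tiny models would grade real clinical photographs.

A model-free check (`peak_count_oracle`, smoothed red-channel local
maxima) recovers the true count on low-density images, confirming the
images carry the count signal independent of any trained model.

## Balancing and splitting

Real count categories are severely imbalanced (head categories > 160×
larger than tail ones). `balance_by_count` brings every non-empty category
to exactly N images: sampling without replacement above N, duplication by
cycling a shuffled list below N (every original appears at least
⌊N/size⌋ times). The split is stratified by severity with
largest-remainder rounding, and balancing is applied **after** splitting,
to the training side only, so duplicated images cannot leak into the test
set. The ordering was an open choice; leakage prevention decided it.

## Reference study (desk scale)

`study.run_easy_study` is the package's reference experiment, sized for a
single CPU: 240 easy-preset images, stratified 80/20 split, fixed-N
balancing of the training side with N = the median category size (≈ 20,
giving ≈ 200 training images over the 10 count categories), classifier
trained with the KL loss for 120 epochs at batch 16 and lr 0.01 (halved
every 30), detector trained sequentially for 40 epochs per phase.
`run_hard_classifier` repeats the classifier study on the hard preset.
Batch 16 (rather than the full-scale default 32) doubles the number of
gradient steps per epoch, which at this dataset size converges better per
unit time.

Typical behaviour at these sizes: held-out severity accuracy ≈ 0.90–0.96,
count RMSE ≈ 0.8–1.2 against a constant-mean baseline ≈ 3, ensemble box
count exactly equal to the predicted count on every image, an interior
best confidence in the sweep, and hard-preset exact-count accuracy
collapsing toward zero.

## Numerical choices

* Probabilities are floored at 1e-12 before logarithms; softmax and
  log-softmax subtract the row maximum.
* Gaussian label distributions are computed in log space, so the σ → 0
  limit degrades gracefully to a one-hot vector.
* All reductions are means over the batch; batch order is the only
  stochastic element of an epoch and is driven by the schedule seed.
* Count argmax ties break toward the smaller count; NMS and top-k ties
  break toward the earlier candidate index.
* Standardization uses the population standard deviation.
* A non-finite loss aborts training with a diagnostic rather than
  continuing silently.

## Limitations

* The numpy stack is CPU-only and single-threaded beyond BLAS; full-size
  families (`resnet50_like`, `yolo_like`) are provided behind the same
  contracts but are not trainable at realistic scale here.
* The detector uses one anchor and one detection scale; heavily varying
  lesion sizes would need multi-scale heads.
* Exact-count accuracy is intrinsically low when counts are large — the
  metric, not the implementation, saturates; RMSE is the informative
  count metric there.
* Severity accuracy is bounded by count confusion at the grade
  boundaries; the Gaussian σ = 3 softening makes boundary targets
  genuinely ambiguous (a count-5 image has 45% of its severity target
  mass in "moderate").
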