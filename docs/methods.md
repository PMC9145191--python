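# Methods

This note documents the models and procedures implemented in
`thromboseg`, the parameters that matter, the synthetic data they are
validated on, and the design choices made where the design was open.

## Losses

### Box regression

Boxes are axis-aligned in continuous 0-based pixel coordinates,
corner-parameterized `(x_min, y_min, x_max, y_max)`; area is the product
of side lengths with no "+1 pixel" convention. This matches the
geometric definitions of the IoU-family losses exactly, and the
rasterization oracle used in the tests (unit-cell counting on
integer-corner boxes) agrees with the analytic areas to machine
precision.

The implemented family is

- `smooth_l1`: the Huber-style kernel `0.5x²` for `|x| < 1`, `|x| − 0.5`
  otherwise, summed over the four corner residuals. By default the
  residuals are divided by image width (x) and height (y) first
  (`SCIoUConfig.normalize_coords`, default on, nominal 512 × 512 frame):
  smooth L1 on raw pixel corners is unbounded and scale-dependent, while
  the IoU terms it is mixed with live in [0, 2), so normalization keeps
  the two terms of the combined loss commensurable. It can be switched
  off, and the residuals are then raw corner differences.
- `iou` (the loss `1 − IoU`), `giou`, `diou`, `ciou` with the enclosing
  -box, center-distance and aspect-ratio penalties.
- `sciou`: `δ·smoothL1 + (1−δ)·CIoU`. The default mixing weight is
  δ = 0.2, the best point of the published sweep over δ ∈ {0.1, …, 0.9}.

Numerical choices:

- Widths/heights are clamped to ε = 1e−7 before the arctan aspect
  ratios, and `c²` is clamped to ε before division, so zero-area
  proposals produce finite values rather than NaNs. Two boxes collapsed
  to the same single point have no defined enclosing diagonal and raise.
- `α` is defined as 0 whenever `v = 0` (including the exact-match case
  where the `v/((1−IoU)+v)` denominator vanishes); CIoU then reduces to
  DIoU, the correct limit.
- Both boxes degenerate (zero union) is an ill-posed overlap query: IoU
  is defined as 0 and a `DegenerateBoxWarning` is emitted rather than
  silently propagating a 0/0.

Gradients are hand-derived closed forms of the formulas as written —
including differentiation *through* `α` — with the standard subgradient
conventions at the min/max kinks; `v`'s gradient is zeroed where the
width/height clamp is active. At exact pred/target coincidence the IoU
surface has a kink whose subdifferential contains 0, and the zero
subgradient is returned so that the optimum is a fixed point of gradient
descent. All gradients are verified against central finite differences
in the test suite; no autodiff framework is required or used.

### Mask and classification

The baseline mask loss is the average binary cross-entropy over the
m × m ROI grid. The weighted binary focal loss replaces the scalar
α_t weight of the focal loss with the binary ground-truth mask ζ and its
complement ξ = 1 − ζ, splitting the loss into a positive and a negative
branch and weighting the positive branch by λ:

- γ (focusing exponent) defaults to 2, the canonical focal-loss setting;
  γ = 0 removes the modulation entirely.
- λ defaults to 2. The role of λ is to focus on the positive
  (thrombus) pixels, which implies λ > 1; no specific published value
  exists, so the default is the smallest natural choice above 1 and both
  parameters are exposed in `FocalConfig` and the CLI.
- Probabilities are clamped to [ε, 1−ε], ε = 1e−7, before logarithms.
- The reduction over the grid is the mean (mirroring the 1/m² of the BCE
  mask loss; the focal variants state no explicit normalizer), with a
  sum option in the config. With λ = 1 and γ = 0 the weighted focal loss
  is then *exactly* the BCE mask loss, which the tests assert to 1e−12.
- The mask loss is supervised only on positive-sample ROIs;
  `mask_loss_batch` takes an ROI-positivity flag and skips negatives.
- ξ is always derived as 1 − ζ rather than stored: the two masks are
  complementary by construction and storing both invites inconsistency.

Classification stays plain cross-entropy (the task has exactly two
classes, thrombus vs background) and the multi-task total is the
unweighted sum `L_cls + L_reg + L_mask`.

## Evaluation protocol

**Detection.** A detection is a true positive when it matches a
same-slice ground-truth box at IoU ≥ 0.5. Only the TP criterion is
standardized; the matching protocol adopted here is the de-facto
benchmark convention: one-to-one, greedy in descending confidence,
each detection taking the unmatched ground-truth box of highest IoU.
Matching is therefore invariant to input order, and raising the
threshold can only reduce TP. Slices with neither ground truth nor
detections contribute nothing (true negatives are not tracked; the
metrics do not use them). Zero-denominator metrics return NaN with an
`UndefinedMetricWarning` rather than a coerced 0 or 1 — silent coercion
hides pipeline failures. F1 values are compared to published tables
after rounding to the table's printed precision (round-half-even).

**Consecutive-slice rule.** Thrombi extend over many adjacent axial
slices, while tissue-intensity confusers fire on isolated ones. A
detection is confirmed only when it belongs to a run of at least
`min_run` consecutive positive slices. The threshold defaults to 8,
read as "at least 8" — consistent with every real patient having at
least eight thrombus-positive slices — and is configurable.

**Volumetric scores.** Confirmed per-slice masks are restacked into a
3D voxel set per patient and compared with the ground-truth volume via
total overlap, Dice, Jaccard, FN rate and FP rate. The foreground is a
single thrombus region; no connected-component decomposition is applied.
Slice spacing (3–5 mm in the clinical data) is carried as metadata only:
all five scores are voxel-count ratios and provably spacing-invariant.
Two identities hold in exact counts — TO + FN = 1 and
Dice = 2J/(1+J) — and are asserted to 1e−12 (each metric is a separately
rounded float division, so bitwise equality is not guaranteed). Cohort
reports average per-patient scores with equal weight (each patient's
restored volume is one observation); whether published cohort values are
patient-averaged or voxel-pooled is not stated, and patient-averaged is
the documented default here.

## The phantom generator

`thromboseg.phantom` generates the study conditions every other module
is validated under:

- 49–206 axial slices per study (uniform), matching the clinical range;
  512 × 512 frames nominally, 128 or smaller in tests.
- The fraction of thrombus-positive slices is drawn from
  N(0.20, 0.07²), clipped to [0, 1], matching the reported 20% ± 7%;
  the realized run is never shorter than 8 slices so the confirmation
  rule is meaningful. Positive slices form a single contiguous run —
  anatomically the aneurysm sac is one contiguous axial extent.
- Each slice holds a contrast-bright elliptical lumen drifting slowly
  across the stack; on run slices an eccentric thrombus annulus
  surrounds it, its radius, aspect and eccentricity drifting smoothly
  slice to slice (irregular morphology). Confuser blobs at
  thrombus-like intensity appear on every slice, and with probability
  0.7 a study carries a very bright stent arc overlapping the thrombus
  annulus.
- Intensities are abstract 8-bit gray levels ordered
  stent ≫ lumen > thrombus ≈ tissue (means 248 / 190 / 92 / 80, additive
  Gaussian noise σ = 4). No calibrated Hounsfield values are published
  for the clinical data, and only the ordering drives the confuser
  behavior.
- Ground-truth masks are the annulus pixels; boxes are tight (shrinking
  any side excludes a positive pixel), with pixel (r, c) occupying the
  unit cell [c, c+1) × [r, r+1).
- Reproducibility: one RNG stream per study, seeded from
  (master_seed, study_index) via a `SeedSequence`, so any study can be
  regenerated individually; the same seed is byte-identical.

What the phantom does **not** emulate: real organ anatomy and texture,
partial-volume effects, DICOM/HU calibration, scanner variation, or a
trainable detector's actual error distribution. Passing tests on
phantoms therefore demonstrate the *correctness of the losses, metrics
and protocol logic* under controlled conditions — not clinical detection
performance. The published clinical-scale table values require the
private 60-patient dataset and GPU training and are out of scope; what
is reproduced from the tables is their internal arithmetic (the printed
F1 values against the implemented harmonic mean).

The perturbation oracle (`perturb_prediction`) degrades ground truth
into a plausible detector output with controlled slice-miss and
false-alarm rates, box jitter and mask erosion/dilation; at zero rates
it returns ground truth exactly, anchoring the end-to-end round trip
(P = R = F1 = 1, TO = Dice = J = 1, FN = FP = 0).

## Box-fitting harness and δ-sweep

`fit_box` runs SGD with momentum directly on the four corner
coordinates (defaults: learning rate 5e-3, momentum 0.9, no schedule —
the published optimizer settings). It demonstrates the property that
motivates the combined loss: from a disjoint initialization, `1 − IoU`
provides no gradient and the box never moves, while GIoU/DIoU/CIoU and
the combined loss converge. The convergence test uses unit-scale box
geometry with the documented budget (2,000 steps) and a target of final
IoU > 0.9; both are harness constants chosen so the check runs in
milliseconds, not published values. IoU-family gradients scale inversely
with box size, so at a fixed learning rate convergence speed is
geometry-dependent; the δ-sweep's refinement detector therefore fits in
image-normalized coordinates.

`delta_sweep` mirrors the δ-selection procedure (a grid over
δ ∈ {0.1, …, 0.9}, precision/recall/F1 per δ) on a phantom cohort.
Without a trainable detector in scope, two drivers are provided: the
perturbation oracle (δ-independent; used to verify the sweep machinery —
zero perturbation must give F1 = 1 at every δ) and a proposal-refinement
detector that jitters each ground-truth box and polishes it for a fixed
step budget under the combined loss at the requested δ. In the latter, δ
genuinely changes the metrics through optimization efficiency, which is
the aspect of the published sweep that is reproducible without training.

## Detector adapter

`thromboseg.adapter` defines the integration contract with a torch-based
two-stage detector: the box-regression hook is replaced by the combined
loss, the mask hook by the weighted focal loss, and classification is
left unchanged. The adapter validates hook names and hyper-parameters
without torch and builds tensor-native closures only when torch is
importable; otherwise it raises `AdapterUnavailableError` with an
explicit message. The library, tests and CLI are fully functional
without torch.

## Known limitations

- The analytic gradients use fixed subgradient conventions at geometric
  ties (equal corners); optimization behavior exactly *at* a tie may
  differ from an autodiff framework's convention, though function values
  never do.
- The refinement-based δ-sweep measures optimization efficiency of the
  loss, not end-task detection accuracy of a trained network; its
  δ-ranking need not match a full training run.
- The phantom's miss/false-alarm process is i.i.d. per slice; real
  detector errors are spatially correlated.
- Greedy score-descending matching is the benchmark convention but is
  not guaranteed to maximize TP in adversarial configurations (an
  optimal assignment could differ); with one thrombus per slice, as in
  this anatomy, the two coincide.
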