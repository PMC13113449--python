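# Methods

## Model overview

`octaring` grades fovea-centered en-face OCTA vessel-density maps into
normal / mild / moderate non-proliferative diabetic retinopathy by
(1) partitioning each scan into concentric annuli, (2) summarizing each
annulus by percentile intensity features, (3) training a heterogeneous
classifier bank per annulus and keeping each annulus's best member,
(4) fusing the regional predictions by majority vote, and
(5) attributing decisions back to annuli with a local linear surrogate.
The central assumptions are that the scan is fovea-centered (the
default annulus center is the geometric image center, with an explicit
override for off-center data), that pixel intensity is a monotone proxy
for local perfusion, and that disease-related signal is spatially
structured around the fovea.

## Concentric geometry

The outer radial limit `r_max` is the distance from the center to the
nearest physical image border — 512 px for a 1024×1024 scan — and the
region count is `N = ⌈r_max/R⌉`. The ceiling convention with a
truncated outermost annulus is deliberate: it keeps every pixel of the
inscribed disk in exactly one region for any `R`, and it reproduces the
canonical seven-region decomposition (boundaries 0, 75, …, 450, 512) at
the default `R = 75`. Annuli are half-open `[r_in, r_out)` with the
last closed at `r_max`, so no pixel is double-counted; distances are
measured between pixel centers, with the image center at
`((H−1)/2, (W−1)/2)`, which keeps masks symmetric. Rasterized masks
agree with the closed-form annulus areas `π((nR)²−((n−1)R)²)` to within
pixel discretization (< 1.5 % at `R = 75`).

Candidate radial steps of 25–100 px are all supported; 75 px is the
default. `r_max < 1` px, non-positive `R`, or a center outside the
image are rejected.

## Percentile features

Each annulus's intensity distribution is summarized by its inverse CDF
at a configurable set of ranks, default the nine deciles 10–90. The
value at rank `p` over `N` masked pixels is the intensity at sorted
position `⌈p/100·N⌉` (lower-interpolation inverse CDF, i.e. the
smallest intensity whose empirical CDF reaches `p/100`), computed via
`numpy.percentile(..., method="inverted_cdf")`. Nine deciles are the
unique nine-element rank set consistent with quoting "10th, 20th, 50th,
80th, 90th" as examples; they are configurable. Zero-valued pixels are
retained — absent flow signal is the quantity of interest, not
background. Images are loaded as 8-bit grayscale (color inputs reduced
by standard luminance weighting). Features are monotone in rank,
invariant to pixel order, and equivariant under intensity scaling.

Each manifest row is one image; cohorts with both superficial and deep
layer maps list them as separate rows (or pre-average upstream) — the
package does not impose a fusion rule.

## Classifier bank and regional selection

The bank holds ten fixed-hyperparameter members, in the order used for
tie-breaking: KNN (K ∈ {3, 7}, Euclidean), logistic regression (C = 1,
L2, 100 iterations), SVM (RBF, C = 1, gamma = scale, probability
calibration enabled), random forest (100 trees), decision tree
(entropy, depth ≤ 80), extra trees (100 trees, depth ≤ 10), XGBoost
(80 trees, depth 8, learning rate 0.05), AdaBoost (100 rounds),
LightGBM (31 leaves, 100 trees, depth 1 — kept as tuned, effectively a
stump ensemble), and bagging (50 bootstrapped trees). AdaBoost's base
learner is a depth-3 tree: a genuinely weak learner that leaves the
reweighting something to do, where an unpruned tree would not.

Scale-sensitive members (LR, SVM, KNN) are standardized with statistics
fit on training rows only. KNN's two admissible neighborhood sizes are
resolved per region by accuracy on a seeded inner 75/25 split of the
training rows. Winner selection per region maximizes accuracy — by
default measured on that same inner validation split, so the held-out
test set never influences model choice (`selection="test"` is available
for post-hoc comparison) — with ties broken by higher F1, then by bank
order. All estimator randomness flows from each bank member's
`random_seed` (default 42).

## Majority voting

The image-level grade is the mode of the seven regional predictions.
With seven voters over three grades, ties (e.g. 3–3–1) are possible;
the tie defers to the tied grade endorsed by the region with the
highest recorded validation accuracy, falling back to the fixed grade
order (normal, mild, moderate). Votes are hard labels; `vote_shares`
(per-grade vote fraction) and `predict_proba` (mean of regional class
probabilities) are continuous diagnostic surfaces over the same voters,
not alternative decision rules.

## Evaluation

All partitioning is grouped by patient. The holdout split samples
patients (stratified by patient-majority grade, largest-remainder
apportionment) so the test patient count is exactly
`round(fraction · n_patients)`; k-fold deals shuffled patients
round-robin to folds within each grade, giving near-equal fold sizes
with every image in exactly one fold. Class presence in both partitions
is enforced whenever the quota admits it; the splitters are implemented
directly (rather than through library group-splitters) to guarantee
these exact counting invariants. Metrics are accuracy plus one-vs-rest
precision/recall/F1 derived from the 3×3 confusion matrix,
macro-averaged by default (weighted averaging available); the scalar
metrics are exactly recomputable from the emitted matrix.

## Regional attribution

The hard vote is piecewise constant, so the surrogate regresses a
continuous surface: by default the *soft voting* surface (mean regional
class probability for the predicted grade), with the hard vote share
available as an alternative target. During development the vote-share
target proved systematically misleading as an attribution signal: a
confident voter's share is locally flat, so the surrogate assigns
near-zero weight to precisely the most informative annuli and inflates
weakly informative ones sitting near their decision boundaries. The
soft surface preserves the voters' graded confidence and recovers
planted effects reliably; it is therefore the default.

For one image, `n_samples` standardized feature rows (default 5000) are
drawn from the training marginal distribution — unit Gaussian on the
standardized scale, the instance itself kept in the sample — and scored
by the ensemble surface; a ridge surrogate (α = 1) is fit with
exponential proximity weights `exp(−d²/w²)` on standardized distance to
the instance, `w = 0.75·√63`. Sampling the data distribution rather
than a tight neighborhood mirrors the reference LIME tabular sampler
and is what keeps high-margin voters visible to the surrogate. No
feature selection or dimensionality reduction is applied.

Per subject, a region's attribution is the sum of its nine features'
absolute surrogate weights (sum vs. mean is immaterial after
normalization, since regions have equal feature counts); subject means
are normalized to percentages over the seven regions, globally and
conditioned on the true grade. Percentages sum to 100 by construction;
aggregation is invariant to subject order and duplication.

## Synthetic cohorts

The generator emulates the structure this pipeline is designed to
exploit, not retinal biophysics. Baseline vasculature is a stylized
radial texture: 48 branches seeded around a small foveal avascular zone
(radius 8 px) walk outward with angular jitter, bifurcating on a fixed
schedule up to 260 branches, dilated to ~2 px half-width; intensities
are background 30 / vessel 200 with additive Gaussian noise (σ = 5)
clipped to [0, 255]. The fixed bifurcation schedule keeps baseline
density stereotyped across subjects, as real healthy maculae are — with
a free-running branching process, between-subject density variance
dominates the class signal in every annulus at once.

Disease is planted as capillary dropout: vessel pixels are deleted with
probability `1 − q` inside configurable annuli. Defaults: mild
q = {R2: 0.70, R3: 0.60}; moderate q = {R2: 0.55, R3: 0.45, R5: 0.60};
plus a diffuse whole-field dropout (mild 0.90, moderate 0.80)
reflecting that DR-related non-perfusion is graded and widespread, not
confined to sharp rings. The diffuse floor gives every annulus some
grade signal — matching the empirical situation in which all regions
carry discriminative information while the parafoveal annuli carry the
most — and is what makes majority voting competitive with the best
single region. Effective multipliers remain lowest in the planted
annuli, so region-wise standalone accuracy still identifies them.

Default images are 256×256 with radial step 19 px
(= round(75·128/512)), a proportional scale-down of the acquisition
geometry preserving the seven-annulus partition; the geometry is
scale-free, and the smaller canvas keeps cohort generation fast.
Patients are disjoint across grades, with 1–2 images per patient.

What passing tests on these cohorts show: that the pipeline recovers
planted, spatially localized density deficits, keeps patient-level
partitions leak-free, and attributes decisions to the correct annuli.
What they cannot show: performance on real OCTA, whose speckle,
projection and segmentation artifacts, inter-device intensity scales,
FAZ morphology variation, and disease heterogeneity the generator does
not model.

## Problem sizes and numerical choices

Study-scale synthetic runs use 300 images (100 per grade), an 80:20
patient-level holdout, and patient-grouped 5-fold cross-validation;
multi-seed properties (ensemble-vs-best-region margin, attribution
recovery) are evaluated over ten seeded replicates of that cohort, with
attribution aggregated over 36 test subjects (12 per grade) at 3000
surrogate samples per subject. Single-instance explanation defaults to
5000 samples. Degenerate inputs fail loudly: empty masks name their
region, single-class training sets and NaN features are rejected,
zero-variance regional blocks warn but are still scored. LightGBM's
depth-1 constraint is honored as tuned even though unusual;
reproducibility takes precedence over plausibility.

## Limitations

The classifier hyperparameters are fixed externally and not re-tuned;
no probability-weighted or stacked fusion is attempted (hard voting is
the method under study); attribution uses a single surrogate family
(local weighted linear fits) whose weights are sensitive to classifier
smoothness, so contribution percentages should be read comparatively,
not as causal effect sizes; and the acceptance-scale results
characterize synthetic cohorts only — the framework's clinical
performance must be established on real, multi-center OCTA data.
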