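# Methods

This note documents the models, algorithms and design choices in
`milsurv`, in the spirit of a model-description appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic experiments do and do not demonstrate.

## 1. Problem setting

The package targets discrete-time survival prediction from one
hematoxylin-and-eosin whole-slide image (WSI) plus two categorical
covariates per patient: the molecular class of endometrial carcinoma
(POLEmut, MMRd, NSMP, p53abn) and the FIGO 2009 anatomical stage (I–III).
The predicted endpoint is time to distant recurrence under right-censoring.
A WSI is represented as a *bag* of patch-level feature vectors; the label
(time, event) attaches to the bag, not to patches — the multiple-instance
learning (MIL) setting.

## 2. WSI preprocessing

Tissue is segmented by Otsu thresholding of the HSV saturation channel
(tissue is colored, background near-white; a grayscale mode exists for
unusual stains), followed by morphological closing with a disc spanning
three patch widths. Patches are cut on a non-overlapping grid of 180 µm
(`patch_px = round(180 / mpp)` pixels), anchored at the image origin,
kept when at least `min_tissue_frac` (default 0.5) of their pixels are
tissue, and resized bilinearly to 256 × 256.

Conventions that needed fixing and are frozen by tests: grid coordinates
are 0-based, row-major, origin top-left; pixel boxes half-open; the Otsu
threshold is the lowest level maximizing between-class variance (ties go
to the lowest level; a single-occupied-level histogram raises, and the
segmentation wrapper converts that degenerate case into an empty mask with
a warning). Note that for well-separated bimodal histograms the Otsu
criterion is nearly flat between the modes, so the argmax can sit well
away from the midpoint; the exhaustive-scan oracle, not intuition, defines
the expected value.

## 3. Bag compression

Before encoding, highly correlated nearby patches are averaged: patches
are visited in stored (row-major) order; a patch joins the first existing
cluster whose *seed* lies within 3 patch units (Euclidean, grid
coordinates) and whose *current mean* feature has cosine similarity ≥ 0.8
with it, else it seeds a new cluster. Output rows are cluster means at
centroid coordinates. The greedy scan is deterministic; comparing against
the running mean (not the seed) means cluster membership depends on visit
order — this choice is frozen by an independent re-implementation oracle
in the tests. Zero-norm rows are kept as singletons (cosine undefined).
The scale of reduction on real slides is qualitative, not a target.

## 4. The multimodal network

* **Encoder** — per-patch MLP, affine + ReLU (+ dropout in training),
  clinical-scale default D → 2048 → 1024 → 512 (a geometric taper to the
  slide-embedding size; intermediate widths are configurable).
* **Gated-attention pooling** — `score_n ∝ wᵀ(tanh(V h_n) ⊙ σ(U h_n))`
  with V, U: 512 → 256; softmax weights; the slide embedding is the
  attention-weighted sum. This is the gated variant of the attention-MIL
  family; it is permutation-invariant by construction (exactly, not
  approximately — asserted in tests).
* **Covariate arms** — learnable embedding of size 16 → ELU → dense 8,
  one table per covariate (4 molecular levels, 3 stage levels).
* **Gating and fusion** — each modality embedding `e_m` receives a
  factorized bilinear gate `g_m = σ((P_m e_m) ⊙ (Q_m c) + b)` where `c`
  concatenates all modality embeddings. A full per-output bilinear form on
  (512, 528)-dimensional inputs would require ~1.4·10⁸ parameters; the
  Hadamard factorization is the standard low-rank realization and is
  bilinear in `(e_m, c)` up to the bias. Gated embeddings are passed
  through a modality affine, appended with a constant 1, and fused with a
  Kronecker product, so the fused vector contains all unimodal, pairwise
  and third-order interaction blocks; with default sizes its length is
  (512+1)(8+1)(8+1) = 41,553.
* **Survival head** — dense 256 → 128 → K (default K = 4), sigmoid per
  logit, giving conditional hazards `h_k ∈ (0,1)`; survival
  `S_k = Π_{j≤k}(1−h_j)`; the scalar risk score is the integrated
  cumulative incidence `r = Σ_k (1−S_k) ∈ (0, K)`. Any affine transform of
  `r` preserves ranking, so concordance-based results do not depend on
  this particular integration.

Dropout (default 0.25) follows each fully connected layer in the encoder
and head hidden layers; it is disabled in eval mode, which is fully
deterministic. The whole network is NumPy with hand-written
backpropagation; gradients of every parameter group and of the input
features are checked against central finite differences on small
configurations, which also pins down the conventions left open above
(dropout after activation; per-modality gate weights).

## 5. Likelihood, discretization, optimization

The follow-up axis is cut at the quartiles (linear-interpolation
quantiles) of the *uncensored* event times into K = 4 right-closed
intervals `(t_{k-1}, t_k]`, the last unbounded. The per-patient negative
log likelihood is

    event in k:    −log h_k − Σ_{j<k} log(1−h_j)
    censored in k: −Σ_{j≤k} log(1−h_j)

Censored patients contribute survival through their own interval
*inclusive*; the discrete-likelihood family admits either convention, and
the inclusive one is frozen by the two-route algebra test
(`loss = −log L` with `L` assembled independently from `S` and `h`).
Optimization is Adam (weight decay as L2 folded into the gradient), batch
size one, initial learning rate 3·10⁻⁵ decayed tenfold at epochs 2, 5 and
15 over 24 epochs — the clinical-scale defaults. Stratified k-fold
crossvalidation stratifies on (interval × event); strata smaller than the
fold count are merged with a warning.

## 6. Evaluation and outcome analysis

* C-index: tau-truncated Harrell (default tau = 10 years; times clipped at
  tau, later events censored there; comparable pair = earlier time is an
  event and strictly precedes; tied scores count ½) plus the Uno IPCW
  variant via scikit-survival. Both are reported because the estimator
  family behind a published tau-truncated C-index is ambiguous.
* Time-dependent AUC and Brier: IPCW cumulative/dynamic AUC and Brier
  score via scikit-survival; integrated Brier by trapezoid.
* Kaplan–Meier with Greenwood log–log confidence bands and the log-rank
  test via lifelines.
* Cox proportional hazards: in-package Newton–Raphson on the Breslow
  partial likelihood to gradient norm < 1e-8, Wald inference from the
  observed information; errors on constant/collinear designs,
  non-convergence, and separation (detected as a diverging coefficient —
  under separation the score vanishes at large |β|, so a gradient-only
  stop would silently "converge"; the fit is cross-checked against
  lifelines on tie-free fixtures and against brute-force likelihood
  comparisons).
* Risk groups: cutoffs at the 50th and 75th percentile of *training*
  scores (the two lowest quartile groups are merged into "low"), applied
  unchanged to new cohorts.
* Treatment interaction: Cox model with main effects and the
  treatment × risk product; Wald p of the product term. The categorical
  mode tests treatment × high with the intermediate group adjusted and low
  as reference.
* Multi-slide patients: per-patient mean or median of slide-level risks,
  or feature-bag merging before inference.

## 7. Explainability

Integrated gradients are computed on the model's input feature bag along
the straight path from a baseline bag, with the *mean of the four
pre-sigmoid hazard logits* as the target — sigmoid outputs saturate, which
degrades path gradients, so attribution targets the logits. The integral
uses the midpoint Riemann rule with 128 steps by default; completeness
(attributions sum to the target difference from baseline) holds to 1% at
128 steps and 0.1% at 1,024 on test fixtures. The baseline is the toy
encoder's image of an all-white patch (feature missingness in image
space); an all-zeros baseline is available. Per-patch scores (sums over
feature dimensions) are patient-wise normalized by the maximum absolute
value, preserving sign and zeros; the top 5% most risk-increasing and
most risk-decreasing patches are extracted with index-ordered
tie-breaking. Attribution is computed on the compressed bag (the model's
actual input); cluster attributions map back to member patches for
display. Categorical contributions are counterfactual: risk at the actual
level minus risk at a chosen reference level, all else fixed.

## 8. The synthetic cohort generator

The generator replaces restricted clinical cohorts. Per patient: a latent
morphology score `m ~ N(0, 1.5²)`; a bag of `N ~ Uniform(32..128)`
patches (standard-normal features, default dimension 64) in which a
random quarter of patches (`signal_frac = 0.25`, focal signal) is shifted
along a fixed unit signature direction by `m`; molecular class and stage
drawn uniformly over their levels; true log relative hazard

    η = β_morph · m + β_class[class] + β_stage[stage]

with defaults β_morph = 1.0, β_class = (−1.5, 0, 0, +1.0),
β_stage = (0, 0.5, 1.0); event times exponential with rate
`0.06 · exp(η)` per year; independent exponential censoring (0.04/year)
truncated administratively at 10 years — matching the 10-year tau used in
evaluation. An optional treatment arm adds `β_treat · treat` and, for
subgroup-benefit scenarios, `β_treat_high · treat · 1[η in top tertile]`.
A multi-slide mode emits 2–3 bags sharing the patient's `m`.

Design notes:

* *Exponential proportional hazards* is the simplest law with closed-form
  pair-concordance behavior (`P(T_i < T_j) = σ(η_i − η_j)`), which gives
  an analytic oracle for every concordance test.
* *Uniform category priors.* Balanced levels exercise every embedding row
  equally and give the fixed effect vectors their designed spread; heavily
  imbalanced (clinically realistic) priors would concentrate patients in
  zero-effect levels and leave the testbed underpowered to detect whether
  the covariate arms work at all.
* *Morphology scale 1.5.* With the effect sizes above this makes image
  morphology the dominant prognostic modality — as in the clinical setting
  the generator emulates, where the image arm carries most of the signal —
  and places per-patch signal shifts at a magnitude the attention
  mechanism can actually detect against unit patch noise. The true-risk
  oracle then sits near C ≈ 0.82 at tau = 10, leaving clear headroom
  between a well-trained model, the acceptance bar, and chance.
* The generator does **not** emulate: stain/scanner variation, spatial
  correlation of tissue texture, non-proportional hazards, competing
  risks, or informative censoring. Passing the synthetic study shows the
  architecture and training loop can recover a planted multimodal risk
  signal under the stated noise model — not that the model transfers to
  real H&E slides.

## 9. Desk-scale study profile

The synthetic experiments use a scaled-down profile chosen once and used
everywhere (`milsurv.study`): cohorts of 600 training / 200 test patients
with 64-patch bags of 64-d features; encoder 64 → 96 → 64, attention
hidden 48, fused hidden (64, 32); Adam at 1e-3 decayed tenfold at epochs
7 and 9 of 10; weight decay 5e-3 (at desk scale the 600-bag cohort
overfits under the clinical-scale 1e-5); dropout 0.25. With these sizes
one three-arm training takes well under a minute on one CPU and lands
within a few C-index points of the true-risk oracle. The clinical-scale
constants remain the package defaults on `ModelConfig`/`TrainConfig`.

The negative control follows the standard permutation-test design:
outcome rows are shuffled against patients in *both* the training and the
held-out set, so the null world decouples outcomes from every input and
held-out concordance is 0.5 in expectation with only test-sampling noise.
(Permuting training labels alone and scoring against real outcomes
instead measures spurious-transfer alignment; because the bag's dominant
variance direction is the planted risk signature, that statistic spreads
widely across permutation draws — sd ≈ 0.1 — and is not a usable
single-draw control.)

Interaction-test simulations use the outcome-only path of the generator
(no bags; identical outcome code) at n = 2000 with 500 null replicates
(main treatment effect −0.3, no interaction) and 300 benefit replicates
(log-hazard −0.8 confined to the top risk tertile, a plausible strong
adjuvant-chemotherapy effect, HR ≈ 0.45).

## 10. Numerical choices and degenerate inputs

Hazards at exactly 0/1 are clamped to 1e-7 in the likelihood (with a
warning); attention scores are max-shifted before softmax; quantiles use
linear interpolation everywhere (interval edges, risk-group cutoffs);
time-on-edge maps to the interval the edge closes; risk-group labels use
≤ on both cutoffs; top-region ties break by patch index; `cos_min > 1`
makes compression the identity; a constant training-score vector is an
error for risk grouping. All randomness flows from explicit integer
seeds through `numpy.random.Generator`; identical seeds give bit-identical
cohorts, loss traces and artifacts.

## 11. Known limitations

The NumPy network is CPU-bound and batch-one; it is meant for
desk-scale study, not for 10k-patch clinical bags with 3,456-d features.
The toy patch encoder (8×8 mean-pool + fixed random projection) is a
deterministic stand-in, not a learned representation. Cox inference uses
Breslow ties (adequate for continuous times; not for heavily tied data).
The Uno C-index and AUC/Brier delegate censoring-distribution estimation
to scikit-survival and inherit its conventions at the follow-up boundary.
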