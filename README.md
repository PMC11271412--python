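# milsurv

Multimodal attention-MIL survival modelling for whole-slide images, with a
fully synthetic testbed.

`milsurv` implements a discrete-time survival network for gigapixel
histopathology: a whole-slide image (WSI) is reduced to a *bag* of
patch-level feature vectors, pooled by gated attention, fused with
categorical clinical covariates (the four-class molecular classification of
endometrial cancer and FIGO 2009 anatomical stage I–III) through a gated
Kronecker product, and mapped to conditional hazards over four follow-up
intervals. The target audience is computational-pathology and biostatistics
researchers who want to study, extend or stress-test this class of
prognostic model without access to clinical cohorts: a synthetic-cohort
generator with known ground truth stands in for the restricted data, and
every downstream stage — preprocessing, compression, training, evaluation,
explainability — is testable against it on a laptop CPU.

## The model

For a bag of patch features `h_1..h_N` (per-patch MLP encoder output), gated
attention pooling computes

    a_n ∝ exp( wᵀ( tanh(V h_n) ⊙ σ(U h_n) ) ),    Σ_n a_n = 1

and the slide embedding `z = Σ_n a_n h_n`. Each categorical covariate is
embedded (lookup 16 → ELU → dense 8). Every modality embedding `e_m` is
gated by `g_m = σ((P_m e_m) ⊙ (Q_m c))` with `c` the concatenation of all
modality embeddings, weighted, appended with a constant 1, and fused by the
Kronecker product — with the clinical-scale sizes (512, 8, 8) the fused
vector has (512+1)(8+1)(8+1) = 41,553 entries and contains every unimodal
and pairwise interaction block verbatim. A two-layer head produces K = 4
hazard logits; with conditional hazards `h_k = σ(logit_k)`,

    S_k = Π_{j≤k} (1 − h_k),      risk r = Σ_k (1 − S_k) ∈ (0, K).

Training minimizes the discrete-time negative log likelihood (events
contribute `−log h_k − Σ_{j<k} log(1−h_j)`, censored patients
`−Σ_{j≤k} log(1−h_j)`) with Adam at batch size one and a stepwise
learning-rate decay; intervals are the quartiles of the uncensored
event-time distribution. Everything is NumPy with hand-written exact
backpropagation, validated against numerical differentiation in the test
suite.

Evaluation covers the tau-truncated Harrell and Uno IPCW C-index,
IPCW cumulative/dynamic AUC and integrated Brier score, Kaplan–Meier
curves with Greenwood log–log confidence bands, the log-rank test, Cox
proportional-hazards fits (Breslow ties, Newton–Raphson), quantile risk
groups (low / intermediate / high with the two lowest quartiles merged),
treatment-interaction Wald tests, and integrated-gradients patch
attribution with top-region extraction and counterfactual covariate
contributions.

## Worked example

```python
from milsurv.study import prepare_study_cohort, run_arm, ARM_THREE
from milsurv.evaluate import assign_risk_groups, logrank_test

split = prepare_study_cohort(n_train=600, n_test=200, seed=2)
arm = run_arm(split, ARM_THREE, seed=2)
print(f"held-out C-index: {arm['cindex']:.3f}")

groups, labels = assign_risk_groups(arm["train_risk"], arm["test_risk"])
te = split["test_records"]
chi2, p = logrank_test(te["time_years"], te["event"], labels)
print(f"cutoffs: c50={groups.c50:.3f} c75={groups.c75:.3f}")
print(f"log-rank across risk groups: chi2={chi2:.1f}, p={p:.2e}")
```

This generates an 800-patient synthetic cohort (64-patch bags, 64-d
features, morphology + molecular class + stage effects on an exponential
hazard), trains the three-arm model and prints:

```
held-out C-index: 0.840
cutoffs: c50=0.938 c75=2.284
log-rank across risk groups: chi2=178.0, p=2.25e-39
```

A held-out C-index of 0.84 against a true-risk oracle of ~0.85 means the
network recovered nearly all of the planted prognostic signal; the
log-rank p-value shows the training-set quantile cutoffs transfer to
held-out patients. The same pipeline is available from the shell:

```
milsurv pipeline --n-train 60 --n-test 30 --epochs 3 --seed 1 --out run/
milsurv simulate --n-patients 20 --out cohort/
milsurv preprocess --image slide.png --mpp 0.5 --out prep/
```

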