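# Methods

`radiosurv` implements a pathway-guided multimodal deep survival
framework for small radiogenomic cohorts: tumor segmentation and RoI
extraction, two Cox-supervised single-modality autoencoders, two
multimodal fusion architectures (a hierarchical β-VAE and a
cross-attention β-VAE), a nested cross-validation protocol with
survival metrics, and gradient-based interpretation. This note records
the model assumptions, the parameters that matter, the numerical and
design choices made where the design was genuinely open, and what the
synthetic test-bed does and does not establish.

## Model

### Cox head and partial likelihood

Every architecture ends in a Cox regression component: tanh hidden
layers (depth and width configurable, including zero hidden layers)
and a single linear output neuron, the prognostic index (PI). Higher
PI means higher predicted hazard, i.e. shorter expected survival. The
supervised loss is the negative log Cox partial likelihood

    C_loss = - Σ_{i: δ_i = 1} [ PI_i - log Σ_{j: t_j ≥ t_i} exp(PI_j) ]

with the risk set R(t_i) = {j : t_j ≥ t_i} (censored-at-t included),
Breslow handling of tied event times, and log-sum-exp stabilization.
The public function returns this sum; inside training graphs the term
is divided by the number of observed events, a constant rescale that
keeps the Cox term on a comparable footing with reconstruction losses
regardless of batch size. Risk sets are batch-local and training is
full-batch, so the partial likelihood is always computed over the
complete training fold. Ridge (L2) regularization applies to the Cox
component's weights, with λ a tuned hyperparameter.

### Sparse pathway layer

The gene branch passes expression g0 ∈ R^m through a gene layer and a
pathway layer with ReLU activations:

    f(g0) = relu( (W ∘ A)^T relu(W0^T g0 + b0) + b )

where A ∈ {0,1}^{m×q} is the gene-by-pathway membership mask. The
element-wise mask is applied in every forward pass **and** the stored
weight W is re-projected onto the mask support after every optimizer
step, so masked entries are exactly zero at all times (a stronger
schedule than per-epoch projection; per-epoch changes nothing
observable since the forward masks regardless). The gene layer is
written as a full m×m matrix, with a diagonal variant (one scale per
gene) available via configuration for very small cohorts. Genes in no
pathway keep all-zero mask rows rather than being dropped, so
attribution indices always cover the full gene list.

### Single-modality models

* **Gene sparse AE-Cox** — encoder: sparse pathway layer → dense ReLU
  layer → latent Z1; decoder mirrors it (dense → mask-transposed layer
  → linear gene output); Cox head on Z1. Total loss =
  Cox + gene reconstruction MSE + L2.
* **Image AE-Cox** — encoder: two stride-2 ReLU convolutions; the
  latent is taken from the **channel means** (global average pooling)
  by default rather than the flattened feature map: tumor position is
  irrelevant to hazard in this problem, and pooling removes the
  positional features that the Cox head otherwise overfits
  (``pool="flatten"`` restores the flat variant). Decoder: dense →
  two transposed convolutions → sigmoid. Total loss =
  Cox + image reconstruction MSE + L2.

Reconstruction MSEs in training are per-sample sums over
features/pixels averaged over the batch — the same relative weighting
that the loss takes at realistic feature counts, where reconstruction
dominates the unweighted total.

### H-VAE-Cox (hierarchical fusion)

Step 1 and step 2 train the two single-modality models independently;
their encoders are then frozen (joint fine-tuning is available behind
a flag). Step 3 standardizes the concatenated codes Z1‖Z2 with
training-fold statistics and feeds them to a high-level β-VAE whose
mean μ, concatenated with the output of a 2-layer clinical
subnetwork, drives the Cox head. The high-level encoder/decoder are
**linear** by default (``encoder_hidden=0``; a ReLU MLP variant is
configurable): with ~100 training samples a nonlinear high-level
encoder memorizes the training risk ordering through the Cox gradient
(training C ≈ 1.0, held-out ≈ 0.5 in our ablations), while the linear
β-VAE preserves the survival-relevant directions and the ridge-like
linear Cox head recovers them. Total loss = L_vae + Cox + L2, with
L_vae = reconstruction MSE + the capacity-annealed KL term below.

### XAT-VAE-Cox (cross-attention fusion)

Images and expression enter directly. The image branch is a two-layer
conv stack with global average pooling followed by a **linear**
projection to a q-vector; the gene branch is the sparse pathway layer
(q-vector). Features are treated as single tokens of width q: each
branch is self-attended (single-head for images, multi-head for
genes), then fused by two cross-attention layers — image-as-query
against gene keys/values and gene-as-query against image keys/values
— whose outputs concatenate to 2q. Linear heads emit μ and log σ²; the
reparameterized z feeds two decoders (conv-transpose image branch,
dense gene branch); μ concatenated with a one-layer clinical feature
drives the Cox head. Total loss = Kvl·(image MSE + gene MSE +
capacity-regularized KL) + Kcl·(Cox + L2).

Two stabilizations matter at this sample size, both found by ablation
and configurable off:

* the q-projection of the image branch is linear — a trainable ReLU
  projection at that position dies for a noticeable fraction of
  initializations (the GAP features are small and positive), erasing
  the whole image modality;
* the Cox input μ‖clinical is ZCA-whitened with training-batch
  statistics that are frozen for inference. Whitening makes the
  ridge-regularized linear head invariant to the arbitrary rotation
  and conditioning of μ across initializations, which was the largest
  source of run-to-run variance.

The baseline VAE-Cox ablation replaces the sparse gene layer with
dense layers and removes all attention, keeping the loss and training
protocol identical.

A warm-start option copies a trained image AE's conv stack and gene
AE's sparse layer into the XAT branches (the desk-scale analog of a
pretrained backbone). It is off by default: in our ablations it did
not improve held-out concordance.

### β-VAE capacity regularizer

The KL term uses the capacity-annealing objective

    reg = kld_weight · γ · | KL - C(step) |,  C(step) = C_max · min(1, step / T)

with γ = 1000, C_max = 25, kld_weight = 0.005 (a plain β·KL mode is
available). The published horizon for T is 1e5 steps, which assumes
training runs of that length; at the test-bed's 100–400 full-batch
steps that leaves C(step) ≈ 0 throughout and the penalty collapses
the posterior (μ → 0) before it can encode anything. The schedule
therefore anneals over the actual run length by default
(``anneal_capacity_to_run``), reaching C_max at the final step; the
other three constants keep their standard values.

## Synthetic test-bed

The generator emulates a small multimodal NSCLC-like cohort:

* **Images**: 64×64 slices; clipped Gaussian background noise
  (sd 0.05) plus one additive Gaussian blob with peak 0.8 whose
  half-peak contour is a disk of radius r ~ Uniform(4, 10) pixels at a
  uniform interior position; the disk is the ground-truth mask.
* **Expression**: 60 genes in 6 disjoint 8-gene pathways (overlap
  configurable). Pathway activity a_p ~ N(0,1) per sample; member
  genes read loading·a_p + N(0,1), others pure noise. With loading 1
  and noise sd 1, within-pathway gene correlation is 0.5.
* **Clinical**: 6 standard-normal covariates.
* **Survival**: exponential event times with rate
  h0·exp(log-hazard), h0 = 1/365 per day;
  log-hazard = β_r·r + Σ_p β_p·a_p (3 active pathways) + β_c·x_clin.
  Censoring times are exponential with the rate solved by bisection so
  the expected censored fraction matches the 30% target.

Default coefficients (β_r = 0.7, β_p = 0.7, β_c = (0.35, −0.35, 0…))
give the true log-hazard a Harrell C around 0.8 with each modality
individually prognostic (per-modality oracle C ≈ 0.70); the
strong-signal benchmark configuration raises all three to 1.0 /
(0.3, −0.3, 0…), the regime used for the end-to-end recovery analyses.
Choosing exponential event and censoring models keeps every
downstream quantity checkable against closed forms or cheap
Monte-Carlo oracles.

What the test-bed does **not** emulate: CT texture and physics,
multiple lesions, overlapping pathway membership (off by default),
batch effects, non-proportional hazards, competing risks, and the
dimensionality of real transcriptomes. Passing the recovery analyses
shows the architectures, losses, protocol and interpretation machinery
work end-to-end and respect the known ground truth — not that the
models would attain any particular performance on real radiogenomic
data.

## Evaluation protocol

Outer folds (5 by default; 3 in the scaled-down benchmark) are
stratified by event status. Hyperparameters (learning rate and its
exponential decay, dropout, λ, Kvl, Kcl, Cox-head width) are tuned by
a seeded sequential search: each of `trials` sampled configurations is
trained for `tuning_epochs` on an inner split of the outer-training
fold (validation fraction 1/`inner_folds`), scored by inner-validation
concordance averaged over `executions_per_trial` runs. The best
configuration is retrained with `final_epochs` on the full
outer-training fold and scored once on the outer-validation fold.
Outer-validation samples never reach the tuner (asserted by an
instrumented test). Per-fold metrics: Harrell's C (in-package; tied
scores credit 0.5, tied event times are not comparable), Uno's IPCW C
with weights 1/G(t)² truncated at the 90th percentile of observed
times, and the IPCW cumulative/dynamic AUC (both via scikit-survival).
Pooled outer-validation PIs are split at their median (strictly
greater = high risk), compared by the two-group log-rank test, and
summarized by Kaplan–Meier curves.

All feature standardization (expression, clinical, fusion codes, Cox
inputs) uses training-fold statistics only.

## Interpretation

Attributions are expected gradients: straight-path integrated
gradients of PI with a midpoint rule (64 steps by default, seeded
jitter), baseline = the mean of the attributed samples (configurable).
For a linear PI this is exactly w_j(x_j − b_j) and in general the
attributions satisfy completeness up to quadrature error. Modality
contributions Φ are absolute attribution sums; multimodality scores
are their shares, summing to one. Gene ranking uses the mean absolute
attribution across high-risk samples (mean signed available), with
deterministic id-based tie-breaks and a floor-based top-fraction cut.
Latent attributions can be pushed through a low-level decoder with the
decoder's zero-point response subtracted, so zero latent attribution
maps to zero input-space importance. Grad-CAM weights each
activation map by its spatially averaged PI gradient and rectifies
the weighted sum; since the single-token attention configuration has
no spatial extent, heatmaps are taken at the last conv layer.

## Segmentation

The U-Net has configurable depth (default 2) with one ReLU conv per
level, 2×2 max pooling, non-overlapping 2×2 transposed-convolution
upsampling with skip connections, and a sigmoid 1×1 head; training
minimizes the smoothed dice loss (ε = 1). The pretrained-encoder flag
exists but is off everywhere so no downloads are needed. Dice and IoU
score empty-vs-empty mask pairs as 1 so perfect negatives are not
penalized. RoI cropping windows are max(1.5 × bounding-box side, 32)
pixels, centred on the centroid of the largest connected component,
clamped to the image and resized (bilinear) to the target size.

## Numerical choices and degenerate inputs

* All networks run on an in-package reverse-mode autodiff engine over
  numpy (float64), verified against central-difference gradients;
  softmax/log-sum-exp use detached max-shifts.
* Optimizer: Adam (β = 0.9/0.999, ε = 1e-8) with per-step exponential
  learning-rate decay (default 0.995) and post-step constraint hooks
  for mask re-projection. ReLU layers near small positive inputs use
  a small positive bias init.
* Median imputation is the deterministic stand-in for model-based
  dropout imputation; the strategy argument is the extension point.
* Gene filtering drops a gene when its missing fraction strictly
  exceeds the threshold (default 0.7); exactly at the threshold is
  kept.
* Canonical sample order after alignment is the lexicographic sort of
  the shared ids.
* A constant prognostic index stratifies everyone to low risk and is
  reported as log-rank χ² = 0, p = 1.
* The mean Kaplan–Meier censoring weight G(t) reaching zero before an
  event time raises an error advising a smaller truncation horizon.

## Problem sizes

The standard test-bed runs 150 samples, 64×64 images, 60 genes, 6
pathways and 3 outer folds with a 2-trial tuner; the segmentation
benchmark trains on 40 images for 30 epochs across 3 folds. The
multi-seed model comparison uses five independent dataset seeds with
the fixed family recipes. These sizes were chosen so the full
benchmark suite completes on a single CPU core while leaving the
recovery signals well clear of chance.

## Known limitations

* Single-token attention makes the attention layers linear maps with
  trivial softmax weights; the multi-token (pathway-wise) formulation
  is the natural extension but is not the default.
* The engine is CPU/numpy only; paper-scale inputs (10⁴ genes,
  224×224 crops, latent 500) are out of reach and untested.
* Efron tie handling, time-varying covariates, competing risks and
  calibration metrics are not implemented.
* The tuner is a seeded sequential search; with 2–3 trials it is
  indistinguishable from random search, which is all the protocol
  requires.
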