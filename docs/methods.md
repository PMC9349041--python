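# Methods

## Overview

`vqcyto` learns protein-localization representations from two-channel
fluorescence crops by self-supervision: a hierarchical vector-quantized
autoencoder reconstructs each crop and, through two classifier heads,
predicts the identity of the tagged protein. No localization annotation
enters training; annotations are used only downstream, to score embeddings
and to label feature spectra. This note records the model, the synthetic
data it is exercised on, the tunable parameters, and the numerical choices
made where the design was genuinely open.

## Preprocessing

Raw inputs are 3D confocal stacks (protein + nuclear-stain channels) or
pre-projected 2D fields of view.

1. **Projection/downsampling** — maximum-intensity projection along z, then
   2 × 2 block-mean downsampling (side halves, e.g. 1,024 → 512 px). The
   block mean was chosen as the downsampling operator because it is
   anti-aliased and constant-preserving; spatial dimensions must be even.
2. **Nucleus segmentation** — a Gaussian low-pass (σ = 10 px) followed by
   minimum-cross-entropy (Li) thresholding gives a foreground mask; plain
   thresholding merges touching nuclei, so the mask is refined: (1) the
   Laplacian-of-Gaussian response (σ = 5 px) of the raw image is thresholded
   at zero and multiplied by the foreground mask — blob interiors have
   negative LoG while the saddle between touching blobs does not, which
   re-opens merged seams; (2) morphological closing (disk radius 4, the
   floor required to bridge intra-nuclear texture gaps) plus hole filling;
   (3) re-multiplication by the foreground mask restores true holes; (4–5)
   connected regions of the LoG local-minima mask (below the 1st percentile)
   that straddle the refined mask's boundary (≥ 1 pixel on each side) are
   carved out, discarding bright non-nuclear specks. All four parameters
   are exposed in `SegmentationParams`.
3. **Signed distance transform** — Euclidean distance to the nuclear
   boundary, positive inside and negative outside. Each sign is normalized
   by its own maximum magnitude so the map spans [−1, 1] with +1 at the
   deepest nuclear interior; a single shared divisor would leave the
   positive side far below 1 whenever background extends farther from the
   nuclei than their interior depth, which is the typical geometry.
4. **Crops** — one window per nucleus, centered on the integer-rounded
   centroid; nuclei whose window would cross the field border are skipped.
   Fluorescence is min–max normalized per field of view *before* cropping
   (crops from one field stay mutually comparable); per-crop normalization
   is available by flag. Default crop size 100 px (64 px in the scaled-down
   test conditions).

## Model

Input crops are (C, H, W) with C = 2 (fluorescence + distance) and H = W
divisible by 4. Component wiring:

- `encoder1`: two stride-2 convolutions with a residual block between them;
  maps the crop to the **local latent** (H/4 × W/4 grid, `code_dim`
  channels; 25 × 25 × 64 at full size).
- `encoder2`: consumes the pre-quantization local latent and pools it by
  repeated stride-2 (ceiling) convolutions down to the **global latent**
  (4 × 4 grid, `n_splits × code_dim` channels; 576 at full size).
- `VQ1` / `VQ2`: two independent codebooks of `n_codes` (default 2,048)
  codes of dimension `code_dim` (default 64). The local latent is quantized
  one position-vector at a time; the global latent uses **split
  quantization**: each channel vector is cut into `n_splits` (default 9)
  contiguous subvectors, each matched to its nearest code (Euclidean, ties
  to the lowest index) in the shared global codebook. `n_splits = 1`
  reduces exactly to standard VQ.
- `decoder2` (ending in the adapter convolution `mselyr1`): reconstructs
  encoder2's input from the quantized global representation; with encoder2
  it forms an independent inner autoencoder.
- `decoder1`: reconstructs the crop from the quantized local representation
  concatenated with the global one, which is resized to the local grid by
  nearest-neighbor interpolation (the resize operator was an open choice;
  nearest-neighbor keeps quantized vectors intact).
- `fc1` / `fc2`: identification heads on the quantized local and global
  representations — two-layer perceptrons with `classifier_hidden`
  (default 1,000) units and ReLU, outputting one logit per protein.

The loss is a weighted sum (all weights default 1.0) of: reconstruction MSE
at both levels, codebook + commitment terms for both quantizers (commitment
coefficient 0.25), and categorical cross entropy from both heads. Codebooks
update by exponential moving average (decay 0.99) with Laplace-smoothed
cluster sizes; encoder gradients pass through quantization with the
straight-through estimator. Dead codes are left in place — perplexity
reporting makes under-use visible rather than masking it by re-seeding.

The implementation is a compact numpy CNN: im2col convolutions ('same'
padding, output side ⌈H/stride⌉) with hand-written reverse-mode gradients,
verified against central finite differences. Backbones are deliberately
small; the normative contract is the latent shapes, not a particular layer
count, and encoder/decoder widths (`width1`, `width2`) are configurable.

Ablation toggles (`use_nuclear_channel`, `use_distance_transform`,
`use_vq`, `use_split_quantization`, `use_id_task`, `use_decoder`) remove
the corresponding structure: single-channel input, raw nuclear image in
place of the distance map, identity in place of quantization, whole-vector
global quantization (codebook dimension grows to the full channel count),
no classifier heads / cross-entropy terms, no decoders / reconstruction
terms.

## Training protocol

Crops are split 8:1:1 into train/validation/test at crop level by default;
protein-stratified splitting is provided because crop-level splitting lets
near-duplicate crops from one field span partitions — flagged, not silently
changed. Augmentation is lossless 90° rotation plus flips applied jointly to
both channels (arbitrary-angle rotation is deliberately not the default).
Adam starts at lr 4 × 10⁻⁴. After each epoch the full validation-loss
history is replayed through a pure scheduling function: the lr is multiplied
by 0.1 whenever the best loss has not improved for 4 consecutive epochs
(the plateau counter resets on decay), and training stops when more than 12
consecutive epochs pass without improvement. "Improve" means decrease by
more than 1 × 10⁻⁶ absolute (no tolerance was prescribed; a strict-decrease
rule is fragile to float noise). The best-validation parameter snapshot is
returned. Batch size (64) and epoch cap (100) are configuration, not claims.

## Embeddings, Γ, and feature spectra

The default embedding of a crop is its quantized global representation,
flattened (pre-quantization mode by flag). UMAP projects embeddings to 2D
with Euclidean metric, 15 neighbors, min_dist 0.1, fixed seed. Points are
per-image; a per-protein-median mode exists because either convention is
defensible.

Class separation is scored by Γ = σ*({μ*(C_j)}) / μ*({σ*(C_j)}): μ* is the
coordinate-wise median; for point sets in R^m, σ* is defined as 1.4826 ×
the median Euclidean distance to the coordinate-wise median (consistent
with the MAD-based normal-scale estimate in 1D, rotation-tolerant in m-D).
The definition is recorded in every `ScoreReport` for auditability. A
degenerate denominator (all classes with zero spread) raises an error
rather than returning infinity, since score comparisons need finite values.
Separation between two groups is tested with a two-sided Mann–Whitney U
test on the projection onto the axis joining the group robust centers
(exact null for n ≤ 8 per group, normal approximation otherwise).

Feature spectra count local-codebook index occurrences over all images of a
protein (raw counts by default; per-row frequency normalization by flag,
since image counts per protein may differ). Column profiles are correlated
pairwise (Pearson; constant vectors correlate 0 off-diagonal to keep
rankings total), ordered by agglomerative clustering of correlation-matrix
rows (average linkage, Euclidean — the common clustermap default) with the
dendrogram leaf order as the feature ordering. Localization prediction
correlates a protein's spectrum against per-category mean spectra computed
without it (leave-one-out); the top correlation is the call. The
complex-neighbor analysis finds each protein's best-correlated partner and
reports, per correlation threshold, the fraction of passing proteins that
share a complex with that partner (thresholds no protein passes are
reported as missing, not zero). Manual segmentation of the ordering into
top-level feature clusters is supported only as user-supplied breakpoints,
never computed automatically.

## Synthetic data

The generator emulates the structure of a tagged-protein confocal screen:
per field, 2–4 non-overlapping elliptical nuclei (semi-axes 15–30 px at
512 px scale, i.e. 30–60 px full axes — comparable to cultured human cell
nuclei at this working resolution), a nuclear-stain channel, and a protein
channel drawn from one of seven localization families: nuclear-diffuse,
nucleolar, chromatin-like, cytoplasmic-diffuse, punctate, reticular,
filamentous. The cytoplasm is modeled as a 1.9 × scaled ellipse around each
nucleus. Pattern parameters (intensity, puncta count/radius, texture and
mesh scales, filament count) are sampled once per protein and reused for
all of that protein's images — identity is thus predictable from
localization alone, exactly the inductive structure the pretext task
exploits. Fluorescence support is restricted exactly to the declared
compartment (blur only softens edges inside), so compartment checks against
truth masks are exact. Noise is Poisson shot noise on scaled intensities
(scale 200) plus additive Gaussian read noise (σ = 0.01) — mild defaults
chosen so families remain separable, as in a reasonably exposed confocal
image. A volume mode replicates scenes across z with a Gaussian axial
profile so the projection operator has realistic input. All randomness
flows through one explicit generator; a dataset is a pure function of its
configuration.

What the generator does **not** model: morphology and cell-cycle
heterogeneity, illumination gradients, batch effects, multi-localizing
proteins, and photorealistic texture. Passing tests therefore demonstrate
the pipeline's mechanics and its qualitative claims (family separation,
split-quantization perplexity gain) under controlled conditions — not
performance on real microscopy.

## Scaled-down study conditions

The end-to-end conditions used by the test suite and the acceptance script:
5 proteins spanning 5 families, 20 images per protein at 256 px, 64 × 64
crops (~190 crops), a model with 32 codes × 16 dims, 4 global splits,
64-unit heads, batch 16, 15 epochs; the split-versus-standard perplexity
comparison trains 5 seeds per variant for 3 epochs. These sizes were chosen
as the smallest at which the qualitative effects are stable and clearly
resolved on a single CPU.

## Known limitations

- Reported dataset-scale results of the full-size method (absolute
  clustering scores on real screens, ~90% organelle prediction) require a
  real image corpus and long training; this package verifies structure,
  correctness against oracles, and qualitative behavior at desk scale.
- The numpy network trains by plain SGD-style batching on one CPU; there is
  no mixed precision or distribution, and the default full-size model is
  practical for inference-shape checks rather than full training.
- Crop-level splitting can leak near-duplicate crops across partitions
  (see above); stratified and FOV-level splitting are the remedy.
- UMAP determinism holds for a fixed seed and thread configuration.
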