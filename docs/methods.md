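# Methods

`gliopipe` implements a classical multi-stage brain-tumor MRI analysis
pipeline on 2-D slices: preprocessing, evolutionary intensity-cluster
segmentation, wavelet texture features with swarm-based feature selection,
and a convolutional encoder–decoder classifier. Every stage is exercised on
seeded synthetic head phantoms, so the whole chain is testable without
clinical data. This note records the models, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic head phantoms

`phantom.generate_phantom` renders a square slice (default 256×256, 8-bit
range) containing an elliptical head: a bright skull ring (annulus between
84% and 95% of the head radius, intensity 220), a dark CSF-like gap, and a
textured brain interior (mean 110, Gaussian texture noise σ = 8, a smooth
low-frequency bias field of amplitude ±10 rendered by spline-upsampling a
4×4 Gaussian grid). Global additive noise (σ = 4) is applied last and the
image is clipped to [0, 255]. All randomness comes from one
`numpy.random.default_rng(seed)`, so identical spec + seed gives
bit-identical output.

Three tumor classes carry invented, learnable signatures (the archive the
pipeline was designed around gives no image-level class description, so
these are stand-ins chosen once so that downstream stages have signal):

| class | offset above tissue | profile | boundary |
|---|---|---|---|
| AST | +25 | Gaussian-tapered (diffuse, low contrast) | near-circular |
| OLI | +50 | smooth plateau with a soft shoulder | mildly irregular |
| GBM | +75 (rim ×1.5, core ×0.55) | ring-enhancing | strongly irregular (harmonic perturbation) |

`generate_dataset` draws balanced sets over {AST, OLI, GBM, no tumor} with
per-sample seeds spawned from a master seed; tumor radius (10–18% of the
minor head semi-axis), centre, and class-conditional intensity offsets
(20–30 / 45–55 / 70–80) are drawn uniformly and recorded in a manifest.

What the phantoms do **not** emulate: MR physics (no k-space, no sequence
contrast mechanisms), partial-volume effects, anatomy (no ventricles, gyri,
or heterogeneous tissue classes), pathology realism (real gliomas infiltrate
and deform tissue), or 3-D structure. A green test on phantoms therefore
establishes algorithmic correctness and end-to-end plumbing, not clinical
performance.

## Preprocessing

**Greyscale conversion.** `grey = 0.31 R + 0.57 G + 0.15 B`, clipped to the
representable range. The weights are applied exactly as stated even though
they sum to 1.03; renormalising would silently change the stated constants.
The phantom's RGB renderer pre-divides by 1.03 so the round trip is exact to
within one grey level.

**Skull stripping.** Pixels below a threshold T are removed; the surviving
mask is cleaned by morphological opening (disk radius 3) and reduced to its
largest connected component, which separates the brain disc from the skull
annulus whenever the CSF gap drops below T. `threshold="auto"` uses Otsu's
method on the nonzero pixels. An empty result raises a warning (threshold
too high) rather than an error. On default phantoms the recovered mask
overlaps the true brain disc with IoU > 0.99.

**CLAHE.** Per-tile histograms over L′ grey levels (default 8×8 tiles,
L′ = 256) are clipped at

```
β = (p′ / L′) · (1 + (α / 100) · (s_max − 1))
```

with p′ the tile pixel count, clip factor α ∈ [0, 100] (default 50) and
maximum mapping slope s_max (default 4). The clipped excess is redistributed
evenly over all bins in a single pass (no iterative re-clipping), so a bin
can end at most at β + excess/L′. Each tile's mapping is the CDF scaled by
(L′ − 1) — monotone by construction, slope bounded by s_max plus the
redistribution increment — and pixels are mapped by bilinear interpolation
between the four nearest tile-centre mappings, with edge tiles reused
beyond the border. Uneven tile sizes are handled by computing β per tile.

## GA cluster segmentation

Segmentation is 1-D clustering of grey levels: a chromosome holds K scalar
centres (default K = 3: background / tissue / tumor). Evaluating a
chromosome assigns every pixel to its nearest centre by |r − z| (ties broken
uniformly at random), replaces each centre by its cluster mean (empty
clusters keep their previous centre), and scores

```
M = Σ_j Σ_{r ∈ C_j} |r − G_j| ,   fitness f = 1 / (M + 1e-9).
```

The Lloyd step makes the GA Lamarckian: improved centres are written back
into the chromosome. One generation = evaluation, fitness-proportional
roulette selection, per-gene arithmetic blend crossover
(M′ = aM + (1−a)N, default a = 0.7, applied with probability 0.8) and
Michalewicz non-uniform mutation

```
x ← x + (d − x)·f(K)  or  x ← x − (x − c)·f(K),   f(K) = (p₂(1 − K/K_max))^d
```

(p₂ uniform, shape d = 2, per-gene probability 0.1), with one elite carried
over so best fitness never regresses. Defaults: population 20, K_max = 100
generations, stop early when the best fitness changes by < 1e-6 relative
over 10 generations. Internally chromosomes are evaluated on the weighted
histogram of unique grey values — exactly equivalent for scalar intensities
and far faster; tie-breaks then randomise per grey value.

The tumor is the cluster with the highest mean intensity inside the brain
mask (configurable to lowest for hypo-intense lesions). The raw cluster mask
is cleaned by morphological closing, hole filling, and largest-component
selection (`clean_mask=True`): closing + filling converts a ring-enhancing
rim cluster into a solid region, and the largest component drops scattered
tissue-tail pixels. **Limitation:** for diffuse low-contrast lesions (the
AST signature) the brightest cluster is dominated by the tissue upper tail
and no post-processing rescues it; intensity-only clustering recovers
compact high-contrast tumors (IoU ≈ 1.0 on default-contrast phantoms) but
not diffuse ones, which is why class discrimination is carried by the
feature and network paths rather than by the GA mask alone.

## DWT texture features

A separable 2-D DWT (Haar by default, 4-tap Daubechies optional) splits the
slice into LL/LH/HL/HH sub-bands; two levels recurse on LL. Filtering is
periodized (circular convolution, stride-2), which keeps the transform
exactly orthogonal: sub-band sides are exactly n/2^level, energy is
conserved to machine precision, and the inverse reconstructs the input to
1e-8. (Symmetric half-point extension is available for analysis, but
periodization is the default precisely because critical sampling, energy
conservation and perfect reconstruction are the properties the tests pin
down.)

Six statistics are computed on LL1, HL1, LL2, HL2 (approximation + vertical
detail at both levels) and concatenated into a fixed-order 24-vector:
mean, population SD, mean of per-row sample variances, inverse difference
moment `Σ f(x,y)/(1+(x−y)²)` over grid coordinates, RMS, and smoothness
`1 − 1/(1+Σf)`. The IDM and smoothness keep these literal forms by default
(the IDM here is *not* a co-occurrence-matrix statistic); a
`strict_formulas=False` switch substitutes the conventional smoothness
`1 − 1/(1+σ²)`. By default features are computed on the slice masked to the
GA tumor region; whole-image extraction is available.

## PSO feature selection

Standard inertia-weight particle swarm (w = 0.72, c1 = c2 = 1.49, velocity
clamp ±4) over one real score per feature; a feature is selected iff
sigmoid(score) > 0.5 (binary transfer convention; an all-empty mask is
repaired to the top-scoring feature, so the mask is never empty). Selection
fitness is the stratified 3-fold cross-validated accuracy of a
standardised nearest-centroid classifier on the masked features minus
`sparsity_weight × selected fraction` (default 0.02) — cheap, deterministic
given the folds, and independent of the network stage. Fitness values are
memoised per mask. The global best is a running maximum, so its trace is
monotone; fixed seeds give identical traces and masks.

## Dual-head U-Net

Encoder: blocks of two same-padded 3×3 convolutions + ReLU, channel width
doubling per block (64 → 1024 over five blocks at full width), 2×2 stride-2
max pooling after every block except the deepest, so a 240-pixel input
reaches 15 pixels at the bottleneck. Decoder: each of the four blocks starts
with a stride-2 transposed convolution (kernel 3, implemented as
zero-interleaving + same convolution) whose output is concatenated with the
matching encoder map (skip connection) before two convolutions. Heads: a
1×1 convolution yields the per-pixel tumor logit (no fully-connected layer
anywhere in this path), and pooled bottleneck features followed by one
linear layer and softmax yield class probabilities. The default pooling
concatenates global *average* and global *max* pooling (`class_head=
"avgmax"`): a tumor covers 1–5% of pixels, so averaging alone dilutes its
contrast to ~1% of the pooled magnitude and desk-scale training becomes
slow and unstable, while per-channel maxima carry the lesion contrast
directly; plain average pooling remains available (`"avg"`). Dropout (rate
0.5 by default) regularises the two deepest encoder blocks; the
classification head reads the bottleneck *before* its dropout — with
dropout directly under the pooled head, desk-scale training cannot learn
at all, while the segmentation path keeps the regularisation.

Everything runs on NumPy with hand-written backpropagation (im2col
convolutions, verified against finite differences to ~1e-7 relative), since
no deep-learning framework is available in the runtime. Training minimises
classification cross-entropy plus segmentation binary cross-entropy with
Adam (default lr 2e-3, batch 2), with random horizontal/vertical flips
applied jointly to image and mask (`augment=True`). Runs are seeded and
fully deterministic; `epochs=0` returns the seeded initial network with an
empty history. Width (`base_channels`) and input side are exposed so
desk-scale training finishes in minutes; the full-width (1024-channel)
architecture is validated by introspection (`describe_architecture`)
without allocating weights.

## Evaluation metrics

All metrics derive from one-vs-rest TP/FP/TN/FN per class plus micro and
macro aggregates: accuracy, sensitivity (= recall = TPR), specificity,
precision, F1, FPR, and a separately reported detection rate defined here
as TP/total (the overall hit rate) — reported separately from TPR, so it
is deliberately not another alias for recall; the term has no single
standard definition, so this reading is a documented choice. Ratios with zero denominators are reported as NaN and
flagged, never coerced to 0.

## Pipeline and reproducibility

`run_pipeline` executes phantom generation → skull strip → CLAHE → GA
segmentation → DWT features on the GA mask → PSO selection →
classification, with per-stage artifacts persisted and each stage
toggleable. Two classification paths are reported side by side: the U-Net
image classifier, and a nearest-centroid classifier on the PSO-selected
features (the consumer that makes the feature stages functional); the
mechanistic link between selected scalar features and an image-consuming
network is left unspecified in the source, so the two branches are kept
separable by design. The metrics JSON strips wall-clock timings, so
identical config + seed runs are byte-identical.

## Numerical notes and limitations

* CLAHE quantises intensities to L′ bins before equalisation; output lives
  on [0, L′−1] and is rescaled by callers that need the original range.
* The GA requires at least as many distinct grey values as clusters.
* Periodized DWT requires sides divisible by 2^levels.
* The U-Net requires the input side divisible by 2^(encoder blocks − 1).
* Desk-scale training (20 images, 64×64, base 8 channels, 400 epochs)
  takes ~6–8 minutes on one CPU; full-width 256×256 training is out of
  reach for the NumPy backend and out of scope.
* Phantom class signatures are invented; accuracy numbers on phantoms say
  nothing about clinical data.
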