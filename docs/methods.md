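# Methods

## Problem and model

`acpseg` segments acoustic neuromas (vestibular schwannomas) on 2-D
contrast-enhanced T1 MRI slices. These tumors sit in the cerebellopontine
angle (CPA), vary widely in size, and often extend a thin stalk into the
internal auditory canal — a geometry that defeats a single fixed receptive
field and rewards attention toward a relatively stereotyped image location.

The network is a U-shaped hybrid of convolution and self-attention:

1. **CNN stem.** Four stride-2 residual stages turn a 1-channel H×W slice
   into feature maps at 1/2, 1/4, 1/8 (kept as skips) and 1/16 scale.
2. **ASPP.** On the 1/16 map, parallel 3×3 convolutions at dilation rates
   2, 4 and 8 (plus a 1×1 branch), concatenated and fused by a 1×1
   convolution. A kernel of size k dilated by `rate` covers
   `k + (k−1)(rate−1)` pixels — 5, 9 and 17 for the configured rates — so
   the module sees several scales at once without any pooling and hence
   without resolution loss.
3. **Tokenisation and transformer.** The (post-ASPP) map is cut into P×P
   patches (P=1 by default on the 1/16 grid), each flattened and projected
   to a D-dimensional token; a learned position table is added
   (`Z0 = [x_p E] + E_pos`, `N = H′W′/P²`). A stack of pre-norm
   transformer layers follows: `z′ = MSA(LN(z)) + z`, `z = MLP(LN(z′)) + z′`.
   The residual wiring makes a layer with zeroed output projections exactly
   the identity, which the tests assert literally.
4. **Decoder with CPAT.** Tokens are reshaped back onto the 1/16 grid and
   up-sampled ×2 four times (bilinear + two 3×3 convs), concatenating the
   1/8, 1/4 and 1/2 skips. After the conv pair of **every** stage sits one
   attention block — by default CPAT, the sequential composition of

   * channel attention `M_c(F) = σ(MLP(avgpool F) + MLP(maxpool F))`
     (one shared two-layer bottleneck MLP, C×1×1 gates), and
   * pixel attention `M_p(F) = σ(f_1×1(F))` (C×H×W gates),

   applied as `F′ = M_c(F) ⊗ F`, then `F″ = M_p(F′) ⊗ F′`. Since every
   gate is strictly inside (0,1), CPAT can only attenuate: |F″| ≤ |F|
   elementwise.
5. A 1×1 head emits two-class logits at full resolution; foreground
   probability is the class-1 softmax channel, thresholded at 0.5.

One published formulation of the channel-attention equation applies the
second MLP layer directly to the max-pooled branch. We treat that as a
transcription slip and share the full two-layer MLP across both branches
(the CBAM design); `ChannelAttention(strict_literal=True)` reproduces the
literal one-layer variant for comparison.

## Numerical substrate

The network, its gradients and the Adam/StepLR optimiser run on a small
reverse-mode autodiff engine over numpy arrays (`acpseg.nn`): dilated
convolution via strided im2col views, bilinear up-sampling as a pair of
1-D interpolation matrices, softmax/log-softmax with the standard stable
forms. Every primitive's backward pass is checked against central finite
differences in the test suite. Weight init: He-normal for convolutions,
Xavier-uniform for linear maps, N(0, 0.02) for the position table;
LayerNorm ε = 1e-6, BatchNorm ε = 1e-5 (GroupNorm available for
batch-size-1 training). Initialisation is a pure function of the seed,
applied in module-registration order.

## Ablation grid

`build_variant` returns configs that fix two ingredients and change one:
`transunet` (no ASPP, no decoder attention), `transunet+aspp`,
`+aspp+c` / `+aspp+p` / `+aspp+cpat` (channel-only, pixel-only, both),
`transunet+cpat`, and `acp` ≡ `transunet+aspp+cpat`. Each added module
strictly increases the parameter count and removing it restores the
baseline count exactly; the CPAT delta has a closed form
(2·C·max(C/r,1) + C² plus biases, summed over decoder widths) asserted in
the tests.

## Training recipe

Defaults follow the standard small-dataset protocol: Adam (β = 0.9/0.999,
ε = 1e-8, no weight decay), base learning rate 1e-4 decayed ×0.1 every 7
epochs (`lr_at_epoch(e) = base·γ^⌊e/step⌋`), batch size 4, 100 epochs,
augmentation by horizontal/vertical flips and intensity inversion (each
switchable; "inversion" is implemented as intensity inversion 1−x with
flips covering the geometric reading). The loss is
`0.5·CE + 0.5·softDice` (smoothing constant 1); the reference protocol
does not state a loss, and this weighting is the common choice for
U-shaped segmentation nets. Model selection uses mean validation Dice.

One master seed fans out to weight init, shuffling, augmentation and
dropout through per-epoch `SeedSequence` spawns, so training is
bit-reproducible and a resumed run continues identically to an
uninterrupted one (optimizer moments are checkpointed too).

## Synthetic phantoms

The clinical dataset (300 slices, cor/sag/tra views, split 8:1:1 with
floor-rounding on val/test → 240/30/30) is private, so the bench runs on
phantoms: a rotated bright ellipse near one lateral edge (the CPA), an
optional thin rectangular stalk along the major axis (canal growth),
correlated background texture (Gaussian-smoothed white noise, correlation
length 6 px), a quadratic-polynomial bias field (amplitude 0.08) emulating
coil inhomogeneity, and additive Gaussian noise (σ = 0.03), clipped to
[0, 1]. Defaults were chosen once to look like mildly noisy T1 slices at
the tested resolution. In-plane pixel spacing of the reference scans is
not published; phantoms default to 1 mm/px, configurable. View tags are
assigned round-robin so per-view reporting is exercised.

What the phantoms do **not** emulate: anatomical context (brainstem,
cerebellum, skull base), partial-volume boundaries, heterogeneous or
cystic tumor interiors, and inter-scanner intensity variation. Passing the
phantom bench therefore demonstrates that the architecture, gradients,
metrics and pipeline are correct and that the model can learn the target
geometry — not that clinical-grade accuracy transfers to real MRI.

## Metrics

Dice = 2|A∩B|/(|A|+|B|); both-empty pairs score 1.0. HD95 extracts
boundary pixels (foreground with a 4-neighbour background; image border
counts as background), pools the two directed nearest-neighbour boundary
distance multisets — which makes the statistic symmetric by construction —
scales by the pixel spacing and takes the 95th percentile with linear
interpolation. The "max of directed 95th percentiles" convention is a
flag. If exactly one mask is empty HD95 is undefined; such items are
excluded from HD95 means with a recorded count rather than given an
arbitrary penalty. Reports print Dice in percent (2 dp) and HD95 in mm
(4 dp), overall and per view.

## Problem sizes used in the checks

All automated checks run on the `tiny` configuration — 64×64 phantoms,
stem widths (8, 16, 32, 64), D = 64, 4 heads, 2 transformer layers,
decoder widths (32, 16, 16, 8) — which trains at a few steps per second on
one CPU core; one forward pass at the full 512×512 resolution verifies the
shape contract. The learning smoke test overfits 8 slices within 200
optimizer steps at a constant 3e-3 learning rate (the step decay is kept
out of range there; the default recipe above is unchanged). The held-out
phantom run in `scripts/acceptance.py` trains on 24 slices for 30 epochs
and evaluates the 3-slice test split.

## Known limitations

- 2-D only: no volumetric context, no 3-D surface distances.
- CPU-scale numerics (float64, single process); the full ViT-B
  configuration builds and runs but is not practical to train here.
- The pretrained-backbone hook (`load_pretrained_backbone`) maps tensors
  by name from an npz archive and is untested against any published
  checkpoint file.
- Batch statistics: BatchNorm with batch size 4 is noisy; GroupNorm is the
  documented alternative.
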