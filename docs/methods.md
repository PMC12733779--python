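# Methods

## Model

VMPANet is a five-stage encoder–decoder for binary lesion segmentation of
256×256 RGB dermoscopy images. Stage *i* of both paths carries `C_i = 8·i`
channels at spatial size `256/2^{i−1}`: (8,256,256), (16,128,128),
(24,64,64), (32,32,32), (40,16,16). Stage 1 keeps full resolution
(stride 1); stages 2–5 downsample by 2 inside their large-kernel
convolution.

### Selective-scan (SS2D) block

The global-context primitive is a two-dimensional selective scan. A feature
map is flattened along four directional paths — row-major forward/backward
and column-major forward/backward, each a bijection between grid positions
and sequence indices — and each path runs an S6 recurrence with per-token
step size and input/output projections:

    Δ_t = softplus(W_dt · (W_x u_t)[:r] + b_dt) > 0
    h_t = exp(Δ_t A) ⊙ h_{t−1} + Δ_t B_t u_t,      h_0 = 0
    y_t = C_t · h_t + D ⊙ u_t

with `A = −exp(A_log)` strictly negative, so the discretised decay
`exp(Δ_t A)` lies in (0,1) and the hidden state is bounded for bounded
input (the suite checks 10⁴ tokens). The input matrix uses the simplified
first-order discretisation `Δ·B`, standard for S6 kernels. The four outputs
are mapped back through each direction's inverse and summed. Around the
scan sit a channel LN, a 1×1 input projection (optionally doubled for a
multiplicative SiLU gate), an optional depthwise 3×3 + SiLU, a merged-map
LN, and a 1×1 output projection. The block is used as
`v1·SS2D(LN(x)) + v2·x`; the encoder computes the bare Mamba path (the λ
blend happens in the fusion step), the decoder uses v1 = v2 = 1.

The recurrence is sequential by nature, so forward and the hand-derived
backward (reverse-sweep BPTT over the stored state history) are
numba-compiled; both are verified against an unrolled float64 loop oracle
and central-difference gradients.

### Encoder stage (PCM)

`f_ipc = BN/ReLU chain over [DW7×7 stride s → Conv3×3 → Conv1×1]`, then
`f_m = Mamba(f_ipc)` and `f_et = Conv1×1(λ₁ f_m + λ₂ f_ipc)` with
λ₁ = λ₂ = 0.5. Two prompt heads distil single-channel masks:
`p₁ = σ(BN(Conv1×1(f_ipc)))` and `p₂ = σ(LN(Conv1×1(f_m)))`; the stage
output is `f_pt = f_et + p₁ + p₂` (unit prompt weights). The p₂
normalisation is a layer norm over the **spatial extent** of the map: an LN
across the channel axis of a single-channel map would collapse every pixel
to the affine offset and the global prompt would carry no information.
Prompts propagate shallow-to-deep implicitly, through f_pt feeding the next
stage; there is no separate cross-stage mask path.

### Decoder stage (MCA) and EASC

`f_vmt = MambaBlock(f_in)`; four depthwise branches (kernels 3/5/7/9, each
followed by a pointwise map to C/4) are concatenated back to C and embedded
by `BN(Conv1×1(DW3×3(·)))`. The EASC chain then applies three gates, each
`σ(score)·x + x`:

- **Edge enhancement**: `x̄ = BN(x − AvgPool3×3(DW7×7(x)))` (3×3 mean pool,
  stride 1, zero-padded, so the subtraction is size-aligned), score =
  `Conv1×1→1(x̄)`.
- **Spatial attention**: kernel schedule 7 → 3 → 1, i.e. two BN'd depthwise
  convs then a pointwise projection to one channel through a ReLU (the η
  activation; configurable).
- **Channel attention**: adaptive max pool to 1×1, a ReLU'd pointwise to a
  hidden width, a sigmoid pointwise back to C — a per-channel gate
  broadcast spatially. The chain order is EE → SA → CA, and the stage closes
  with `+ f_vmt`.

Because every gate is multiplicative-with-residual, zero input maps to zero
and positive input x satisfies x < out < 2x elementwise — both are tested
as invariants, and each ablation switch (no EE/SA/CA, no Mamba path, no
prompts, no CAF) is pure configuration.

### Cross-attention fusion (CAF)

For stages t = 1..4 the decoder output of stage t+1 is bilinearly upsampled
×2 and projected to `Q` (1×1 conv + BN); the same-stage encoder output is
projected to `K`. With Q, K ∈ R^{C×N} (N = H·W), the affinity `Q·Kᵀ` is
taken over the channel axis — the only conformable product for these
shapes — giving a C×C attention matrix, row-softmaxed with τ = √N (the
reduced axis has length N). Two value branches share the weights:
`f_a = A(Q,K,Q) + A(Q,K,flat(f_pt))`, and `f_ct = ReLU(Conv1×1(f_a))`.
Cost is linear in N for fixed C. Stage 5 has no deeper decoder partner, so
its MCA consumes the deepest encoder output directly.

### Heads and loss

Each decoder stage has an independent head, DW3×3 → 1×1(C→m) → ReLU →
1×1(m→1), bilinearly upsampled to the input size. Training minimises
`Σ_t w_t (BCE_t + Dice_t)` over the five stages with unit weights
(`[1,1,1,1,1]`, the best-performing setting of the deep-supervision sweep;
`[1,0.75,0.5,0.25,0.1]` and its reverse are available through config).
BCE clamps probabilities to [1e−7, 1−1e−7]; Dice uses Laplace smoothing
ε = 1 in numerator and denominator, so two empty masks give loss 0. The
prediction is the stage-1 sigmoid thresholded at 0.5.

## Budget calibration and FLOP convention

The published size of this architecture is 0.383 M parameters and
1.159 GFLOPs, split encoder 0.135 M / 0.328 G, decoder incl. CAF
0.242 M / 0.816 G, segmentation heads 0.006 M / 0.015 G. The scan
internals (state size, dt-rank, expansion, gate), the channel-attention
hidden widths and the head hidden widths are not part of the published
architecture, so they are free hyperparameters; they were calibrated once —
a simulated-annealing search over per-stage integer values against those six
budget figures — and frozen as the package default:

| stage | enc (d_inner, N, r) | dec (d_inner, N, r) | CA hidden | head hidden |
|-------|--------------------|--------------------|-----------|-------------|
| 1     | 8, 1, 3            | 8, 2, 3            | 16        | 5           |
| 2     | 16, 2, 4           | 16, 4, 8           | 30        | 4           |
| 3     | 24, 5, 3           | 48, 9, 16          | 22        | 10          |
| 4     | 64, 16, 31         | 64, 34, 36         | 64        | 18          |
| 5     | 80, 32, 32         | 80, 66, 67         | 34        | 91          |

(d_inner = expansion × C; N = state size; r = dt-rank; conv branch on, gate
off throughout.) State capacity concentrates in the deep, low-resolution
stages, which is also where long-range mixing is cheapest. The defaults
reproduce 0.134962/0.242008/0.006021/0.382991 M parameters and
0.328/0.818/0.015/1.161 GFLOPs.

FLOPs are counted analytically, pinned as: one multiply–accumulate = one
FLOP; convolutions (`H·W·C_out·(C_in/groups)·k²`), linear projections,
attention matrix products (`C²N` per product) and the selective scan at
`9·L·D·N` per direction (the usual analytic count for S6 kernels) are
counted; normalisation, activations, elementwise arithmetic, pooling and
interpolation are not — matching the defaults of the common profilers this
figure class is reported with.

## Training protocol

AdamW (lr 1e−3, β = (0.9, 0.999), ε = 1e−8, weight decay 1e−2, amsgrad
off) with single-cycle cosine annealing to η_min = 1e−5 over T_max = 50
epochs; reference schedule 200 epochs at batch size 8 on 256×256 inputs.
Augmentation: horizontal/vertical flips at p = 0.5 and a random rotation in
±30° (bilinear for images, nearest for masks) — the rotation range and flip
probability are conventional choices, exposed in config. Images are
normalised by per-dataset channel mean/std computed on the training split.
Checkpoint selection uses an 80/20 sub-split of the training set by
validation Dice. A fixed seed drives initialisation, the sub-split, batch
order and augmentation, making CPU runs bit-reproducible.

## Synthetic data

The generator emulates the structure the network must cope with: a warm
skin-tone background with a smooth illumination gradient and mild sensor
noise; one star-convex lesion `r(θ) = r₀(1 + Σ a_k sin(kθ + φ_k))`
(4 harmonics, amplitude ≤ 0.15, elliptical base with axis ratio 0.6–1.0),
rejection-sampled to an area fraction in (0.05, 0.40) and a single
4-connected component; a Gaussian-blurred blend (σ = 2 px) for the fuzzy
border; a guaranteed mean intensity gap ≥ 0.25 between surrounding skin and
lesion; and dark 1–2 px hair arcs drawn over the final composite (masks
untouched). Masks are stored as {0,255} PNGs and binarised at >127 on load.
Datasets are written with a 7:3 train/test manifest. The star-convex
parameterisation was chosen over noise blobs because at zero perturbation
the mask has an exact per-pixel analytic oracle.

What the generator does **not** emulate: real lesion colour distributions,
multi-lesion scenes, ruler/gel artefacts, camera vignetting, or the
diversity of ISIC-grade photography. Passing tests on this data demonstrates
that the architecture, gradients, optimiser and pipeline are correct and can
learn lesion-like structure; it says nothing about clinical accuracy, for
which benchmark training on real datasets is required (out of scope here —
it needs dataset downloads and GPU-scale training).

## Numerical choices and problem sizes

- float32 parameters and activations; oracle tests run blocks in float64.
- BN keeps float64 running statistics; eval mode uses them, train mode uses
  batch statistics.
- Softmax subtracts a detached row max; BCE clamps at 1e−7; Dice ε = 1.
- Bilinear resizes use the align_corners=False convention, implemented as
  two constant interpolation-matrix products (exactly linear, so the
  adjoint is the transposed product).
- Empty-mask metric conventions: a scalar metric whose denominator is zero
  returns 1 when the class is absent from both maps, else 0; HD95 returns 0
  for two empty masks and the image diagonal when exactly one is empty.
  HD95 itself is the max of the two directed 95th-percentile boundary
  distances (boundary = foreground pixel with a background 4-neighbour,
  distances by Euclidean distance transform); the percentile reading is the
  accepted interpretation of the metric's name, although the bare formula
  is sometimes printed as the full Hausdorff max.
- The learning-sanity check (memorise 8 synthetic pairs to training
  DSC ≥ 0.95 within 300 AdamW steps) runs at 64×64 — the behaviour being
  checked is optimisation health, which is resolution-independent, and this
  size keeps the check comfortably CPU-sized. The same reasoning sets the
  smoke-test sizes (48×48) in the pipeline tests.

## Known limitations

- The scan kernel is a straightforward serial recurrence; it is fast enough
  for CPU experimentation but makes no attempt at the blocked/parallel
  scans of GPU implementations.
- Batch-norm statistics make train-mode forward depend on batch
  composition; eval mode is deterministic.
- The budget calibration pins overall capacity, not the original training
  dynamics; published benchmark accuracies on ISIC2017/2018/PH2 are not
  reproducible in this environment and are not claimed.
- Single-lesion, binary segmentation only; no test-time augmentation, no
  mixed precision, no multi-head attention variants.
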