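# Methods

## The substitution scheme

A pointwise convolution with `Ic` input channels and `F` filters
(`Ic·F` weights, biases ignored) is replaced by a subnetwork with a single
hyperparameter `Ch`, the number of input channels fed to each group of
filters:

1. **Layer K.** The input is split into `GK1 = ceil(Ic/Ch)` groups of
   exactly `Ch` channels, taken consecutively. If `Ch` does not divide
   `Ic`, the deficit `d = GK1·Ch − Ic` (always `0 ≤ d < Ch`) is covered by
   replicating the first `d` input channels into the last group, after its
   remaining `Ch − d` real channels. Each group gets
   `FgK1 = floor(F/GK1)` filters. Filters left over
   (`GK2 = F − FgK1·GK1 < GK1`) form a second parallel path with one
   filter per group, reusing the first `GK2` channel groups. The outputs
   of both paths concatenate to exactly `F` channels.
2. **Interleaving.** A fixed permutation places the odd-numbered channels
   first and the even-numbered ones last (`[0, 2, 4, …, 1, 3, 5, …]`
   0-based; for odd `F` the first block holds the extra channel), so the
   next grouped layer mixes outputs of different K groups.
3. **Layer L.** The same planning applied to the `F` interleaved channels
   (input count `F`, filter count `F`). L is built only when the layer
   does not widen, `Ic ≥ F`.
4. **Sum.** The L output is added element-wise onto the K output — a
   residual join: gradients reach K directly and through L.

Every filter in every path carries exactly `Ch` weights, so a substituted
layer costs `2·F·Ch` weights with L and `F·Ch` without — independent of
`Ic`. The scheme is worthwhile when `Ch ≤ Ic/2` and `Ch ≤ F/2`
(`is_eligible`); at the boundary `Ch = Ic/2` with L present it exactly
matches the original cost. When `Ch` divides both `Ic` and `F` and
`Ic < F` the plan degenerates to a single plain grouped convolution: no
extra paths, no replication, no L.

### Degenerate plans (`floor(F/G) = 0`)

When there are more channel groups than filters (tiny `Ch` against a wide
input, e.g. squeeze-excitation reduce layers), two readings are offered:

* `degenerate="extra"` (default of `plan_paths`): the main path carries
  zero filters and all `F` filters live in the one-filter-per-group extra
  path at width `Ch`.
* `degenerate="widen"`: the group width is raised to `ceil(Ic/F)` so every
  group keeps at least one filter.

Whole-model substitution uses `"widen"`: it is the behaviour that
reproduces the published parameter totals of the substituted classifier
at every channel width (see below). A path planned with a single group is
a plain convolution over the real channels; replication never pads past
the input.

### Numerical and structural choices

* Indices are 0-based internally; printed tables use the field's 1-based
  convention.
* Group counts round up (`ceil`), filters per group round down (`floor`).
* Replication follows the deficit reading — the last group keeps its
  remaining real channels and then repeats channels from the start — which
  never drops a real channel.
* The intermediate activation sits after the K concatenation
  (`after_k`, swish with fixed β = 1 by default) before interleaving; a
  linear mode (`activation="none"`) exists for oracle comparisons. The
  activation after the sum belongs to the enclosing block.
* Subnetwork convolutions are bias-free by default (they are followed by
  batch norm inside MBConv blocks); replicated channels get independent
  weights per slot, and the densifier accumulates colliding entries.
* The oracle runs in double precision; the builder defaults to single.
  Equivalence tests use relative tolerance 1e-5.

## EfficientNet-B0 integration

The baseline is the canonical B0: stem 3×3/32 (stride 2) + BN + swish;
MBConv stages 16×1, 24×2, 40×2, 80×3, 112×3, 192×4, 320×1 (expansion 1×1
conv + BN + swish when the expansion ratio is 6, depthwise 3×3/5×5 + BN +
swish, squeeze-excitation with reduce/expand 1×1 convs of width
`max(1, floor(0.25·block_input))` with biases, projection 1×1 conv + BN,
identity residual when shapes allow); head 1×1 conv to 1280 + BN + swish;
global average pooling, dropout 0.2, dense softmax head with bias.
Trainable parameters (conv and dense weights, biases, BN scale/offset):
4,020,358 for 10 classes, 4,010,110 for 2, 4,017,796 for 8 — the
difference between class counts is exactly `Δclasses · 1281`. Stochastic
depth (drop-connect) is omitted; it carries no parameters and is
irrelevant to smoke-scale training.

### Substitution conventions

The published whole-model totals of the substituted classifier
(kEffNet-B0 V2) pin down conventions that the per-layer arithmetic alone
does not determine. An exhaustive search over candidate conventions
against the totals for `Ch ∈ {2, 4, 8, 12, 16, 32}`, class counts
{2, 8, 10} and the "no L" ablation rows yields a unique consistent set:

* **Which layers.** Every 1×1 convolution — MBConv expansion and
  projection, SE reduce and expand, and the head conv — is substituted
  whenever at least two channel groups fit (`Ic > Ch`). This is weaker
  than the `is_eligible` guidance: e.g. at `Ch = 32` the SE reduce conv
  1152→48 is still substituted. Layers with `Ic ≤ Ch` keep the original
  convolution. A `substitute_se=False` switch excludes SE convs.
* **Batch norm.** Substituted expansion/projection/head layers normalise
  after each grouped layer: K's BN replaces the block's original BN, and
  when L is present its BN adds `2F` parameters beyond the baseline.
* **Biases.** Substituted SE convs keep one bias per output channel per
  grouped layer (as the SE convs they replace) and use no BN.
* **Degenerate widths.** Whole-model substitution uses the `"widen"`
  degenerate reading (above).

With these conventions the model totals are 311,994 / 354,818 / 444,346 /
534,274 / 950,650 (10 classes, `Ch` = 2/4/8/12/32) — each equal to its
published counterpart — and 623,202 at `Ch = 16`, which is 24 parameters
(0.004%) below the published 623,226. The same −24 offset appears for
every class count at `Ch = 16` only, and the 16-channel "no L" ablation
row is 384 low while all other ablation rows match exactly. No
single-layer convention variant explains both offsets jointly; we treat
the 16-channel published rows as carrying a small accounting inconsistency
and keep the convention that is exact everywhere else.

### Stride skipping

For 32×32 inputs the first `k` stride-2 convolutions (the stem first,
then downsampling blocks in forward order) run at stride 1. With `k = 4`
exactly the stem and the first three downsampling blocks are affected and
one downsampling survives, so a 32×32 input reaches the head at the
spatial size a 224-class input would. Strides carry no weights, so
parameter counts are invariant.

### Flip ensemble and smoke training

`hflip_ensemble_predict` sums `softmax(model(x))` and
`softmax(model(flip(x)))`; class scores sum to 2, parameters are
unchanged, forward cost doubles. `smoke_train` is a learnability sanity
check only: RMSProp on shuffled minibatches of a synthetic set. The test
suite trains the substituted 8-channel B0 on 64 synthetic 32×32 images of
4 classes for 5 epochs (seed fixed) and requires accuracy above the 0.25
chance level — problem sizes chosen to keep the whole suite quick, not to
reproduce any accuracy figure.

## Synthetic data

`generate_synthetic_set` emulates small balanced RGB classification sets
(stand-ins for natural-image and stained-cell/histology patches): each
class has a base colour, a class-dependent blob count and texture
frequency, plus additive Gaussian noise (default σ = 0.08), deterministic
per seed. A linear probe on mean-colour features separates the classes,
which guarantees learnability for smoke training. The generator does not
model the things that make real biological imaging hard — staining
variability, class imbalance, label noise, scale variation, or any
spatial semantics beyond blobs — so passing smoke tests demonstrates
trainability of the architecture, not classification performance on real
data.

## MAC accounting

Reported multiply-accumulate counts are weight-uses per spatial position:
`H·W·weights` for each convolution, with SE convs counted at their pooled
1×1 maps. Activation, normalisation and pooling operations are not
counted. These figures order variants consistently but are not comparable
to conventions that count multiplies and adds separately.

## Known limitations

* Only the B0 stage table ships; the descriptor is extensible but no
  compound-scaled variants are provided or tested.
* No procedure searches for a good `Ch`; ablation over a range is the
  user's job.
* Spatial kernels other than 1×1 are never substituted.
* The NumPy toolkit is CPU-only and built for smoke-scale work, not for
  training at dataset scale.
* The exhaustive planner invariant sweep in the tests covers
  `ic, f ≤ 128` for `Ch ∈ {2, 4, 8, 16, 32}` exhaustively and samples up
  to 512 property-based; the invariants are arithmetic identities, so
  coverage beyond that adds little.
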