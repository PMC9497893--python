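# igpconv — interleaved grouped pointwise convolutions without divisibility constraints

Pointwise (1×1) convolutions dominate the parameter budget of modern
efficient CNN classifiers: a layer with `Ic` input channels and `F` filters
costs `Ic·F` weights, and in an EfficientNet-B0 more than 90% of all
weights sit in such layers. `igpconv` implements a substitution scheme
that replaces each pointwise layer with a two-layer grouped subnetwork —
a grouped layer **K**, a fixed odd/even channel **interleaving**, a second
grouped layer **L**, and an element-wise **sum** joining L back onto K —
in which every filter sees only `Ch` input channels. The substituted
layer costs

    P = 2·F·Ch        (or F·Ch when the layer widens, Ic < F, and L is dropped)

instead of `Ic·F`. Two mechanisms remove all divisibility constraints
between `Ic`, `F` and `Ch`: the last channel group is completed by
*replicating* channels from the start of the input, and filters that do
not divide evenly across groups go to a second parallel path with one
filter per group. The interleaving lets the second layer mix outputs of
different first-layer groups, and the summation makes L residual, so
gradients reach K both directly and through L.

The package targets parameter-frugal backbones for biological and medical
image classification (cell, histology and natural-image patches at
32–224 px), where full-width classifiers are heavily over-parameterised.

What is here:

* **`igpconv.plan`** — pure integer planning: group counts, channel index
  groups with replication, the interleaving permutation, and exact
  parameter/MAC accounting for any `(Ic, F, Ch)`.
* **`igpconv.oracle`** — naive reference convolutions and a plan
  "densifier" that folds the grouped weights into equivalent dense
  matrices; the correctness oracle for everything trainable.
* **`igpconv.subnet`** — the K/interleave/L/sum subnetwork as a trainable
  forward-callable (NumPy, with reverse-mode autodiff from `igpconv.nn`).
* **`igpconv.backbone`** — canonical EfficientNet-B0 from a declarative
  stage table, whole-model substitution with savings reports, a
  stride-skip variant for 32×32 inputs, horizontal-flip softmax-sum
  ensembling, and a smoke-train loop.
* **`igpconv.synthetic`** — deterministic, class-separable synthetic image
  sets so every test runs without downloads.
* **`igpconv` CLI** — `plan`, `report`, `convert`, `smoke-train`,
  `selftest`.

## Worked example

Plan the substitution of a pointwise layer with 14 input channels and
10 filters at `Ch = 4`:

```sh
$ igpconv plan --ic 14 --f 10 --ch 4
Ic  F   P    Ch  GK1  FgK1  GK2  GL1  FgL1  GL2  Total  %
14  10  140  4   4    2     2    3    3     1    80     57.14%
```

Layer K gets `GK1 = ceil(14/4) = 4` groups of `FgK1 = floor(10/4) = 2`
filters (the fourth group replicates channels 13, 14, 1, 2 — 1-based), plus
`GK2 = 2` one-filter groups for the remaining filters. Layer L regroups
the 10 interleaved K outputs into 3 groups of 3 filters plus one extra
group. Every one of the 20 filters carries 4 weights: 80 parameters,
57.14% of the original 140.

Whole-model substitution of EfficientNet-B0 (10 classes) at `Ch = 32`:

```sh
$ igpconv report --classes 10 --ch 32 --fmt json --out report.json
baseline parameters:    4,020,358
substituted parameters: 950,650 (23.6%)
```

i.e. a 76.4% saving of trainable parameters. The same library call:

```python
import numpy as np
from igpconv import effnet_b0, substitute_pointwise

model, report = substitute_pointwise(effnet_b0(num_classes=10), ch=32,
                                     rng=np.random.default_rng(0))
print(model.n_params())        # 950650
print(report.percent_params)   # 23.6
```

A short learnability check on synthetic 4-class images (accuracy above the
0.25 chance level within a few epochs):

```sh
$ igpconv smoke-train --classes 4 --n 64 --size 32 --ch 8 --epochs 5 --seed 42
{
 "loss": [1.4880993068218231, 1.4320855140686035, 1.1910274624824524,
          1.5213473439216614, 1.1200355887413025],
 "accuracy": [0.28125, 0.453125, 0.4375, 0.28125, 0.515625]
}
```

(whitespace condensed; the command prints one value per line)

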