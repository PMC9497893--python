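"""EfficientNet-B0 construction, pointwise substitution and accounting.

The backbone is built from a declarative stage table (the canonical B0:
stem 32, MBConv stages 16x1 / 24x2 / 40x2 / 80x3 / 112x3 / 192x4 / 320x1,
head 1280, squeeze-excitation ratio 0.25).  ``substitute_pointwise``
rebuilds it with every groupable 1x1 convolution — MBConv expansion and
projection, SE reduce/expand, and the head conv — replaced by the
interleaved grouped subnetwork, and reports the parameter/MAC savings.

Substitution conventions (chosen to reproduce the published whole-model
totals of the substituted classifier, see docs/methods.md):

* a layer is substituted whenever at least two channel groups fit
  (``ic > ch``); layers narrower than ``ch`` keep the original convolution;
* if a grouped layer would get zero filters per group, the group width is
  widened to ``ceil(ic / f)`` so every group keeps one filter;
* substituted expansion/projection/head convs are bias-free and batch
  normalised per grouped layer — when layer L is present this adds one BN
  pair beyond the original block's single BN;
* substituted SE convs keep per-convolution biases and use no BN, like the
  SE convolutions they replace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Optional, Sequence

import numpy as np

from . import nn
from .plan import LayerSpec, can_group, make_substitution_plan
from .subnet import SubnetConfig

__all__ = [
    "StageSpec", "BackboneDescriptor", "effnet_b0", "apply_stride_skip",
    "SavingsReport", "build_baseline", "substitute_pointwise",
    "hflip_ensemble_predict", "smoke_train", "DivergenceError",
]


@dataclass(frozen=True)
class StageSpec:
    kernel: int
    filters: int
    repeats: int
    stride: int
    expand_ratio: int
    se_ratio: float = 0.25


B0_STAGES: tuple[StageSpec, ...] = (
    StageSpec(3, 16, 1, 1, 1),
    StageSpec(3, 24, 2, 2, 6),
    StageSpec(5, 40, 2, 2, 6),
    StageSpec(3, 80, 3, 2, 6),
    StageSpec(5, 112, 3, 1, 6),
    StageSpec(5, 192, 4, 2, 6),
    StageSpec(3, 320, 1, 1, 6),
)


@dataclass(frozen=True)
class BackboneDescriptor:
    """Stage-by-stage structure of the classifier."""

    stages: tuple[StageSpec, ...] = B0_STAGES
    stem_filters: int = 32
    head_filters: int = 1280
    num_classes: int = 10
    input_size: int = 224
    skip_strides: int = 0
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.skip_strides > self.n_strided_convs():
            raise ValueError(
                f"skip_strides={self.skip_strides} exceeds the "
                f"{self.n_strided_convs()} stride-2 convolutions")

    def n_strided_convs(self) -> int:
        return 1 + sum(1 for s in self.stages if s.stride == 2)


def effnet_b0(num_classes: int = 10, input_size: int = 224,
              skip_strides: int = 0) -> BackboneDescriptor:
    return BackboneDescriptor(num_classes=num_classes, input_size=input_size,
                              skip_strides=skip_strides)


def apply_stride_skip(desc: BackboneDescriptor, k: int) -> BackboneDescriptor:
    """Force the first ``k`` stride-2 convolutions (stem first) to stride 1,
    so low-resolution inputs traverse the full network.  Weight counts are
    unaffected."""
    if k < 0 or k > desc.n_strided_convs():
        raise ValueError(
            f"k must be in [0, {desc.n_strided_convs()}], got {k}")
    return replace(desc, skip_strides=k)


# --------------------------------------------------------------------------
# model modules


class _PWLayer(nn.Module):
    """A pointwise layer slot: either the original 1x1 convolution or the
    grouped K/interleave/L/sum subnetwork, together with the slot's
    normalisation and activation contract."""

    def __init__(self, rng, name: str, ic: int, f: int,
                 ch: Optional[int], kind: Literal["main", "se"],
                 final_act: Literal["swish", "sigmoid", "none"],
                 cfg: SubnetConfig, substitute_se: bool = True):
        self.name, self.ic, self.f, self.kind = name, ic, f, kind
        self.final_act = final_act
        self.cfg = cfg
        use_bias = kind == "se"
        use_bn = kind == "main"
        self.substituted = (
            ch is not None
            and can_group(LayerSpec(ic, f, ch))
            and (kind != "se" or substitute_se)
        )
        if self.substituted:
            plan = make_substitution_plan(LayerSpec(ic, f, ch),
                                          require_eligible=False,
                                          degenerate="widen")
            self.plan = plan
            if not cfg.enable_l:
                plan = replace(plan, has_l=False)
            self.has_l = plan.has_l
            self.k_convs = [nn.GroupedPointwise(rng, p.input_groups,
                                                p.filters_per_group, use_bias)
                            for p in self.plan.k_paths if p.total_filters > 0]
            self.bn_k = nn.BatchNorm(f) if use_bn else None
            self.l_convs, self.bn_l, self.perm = [], None, None
            if self.has_l:
                self.perm = np.asarray(self.plan.interleave_perm, dtype=np.intp)
                self.l_convs = [nn.GroupedPointwise(rng, p.input_groups,
                                                    p.filters_per_group, use_bias)
                                for p in self.plan.l_paths if p.total_filters > 0]
                self.bn_l = nn.BatchNorm(f) if use_bn else None
        else:
            self.plan = None
            self.has_l = False
            self.conv = nn.PointwiseConv(rng, ic, f, use_bias=use_bias)
            self.bn = nn.BatchNorm(f) if use_bn else None

    def _act(self, t, which):
        if which == "swish":
            return nn.swish(t, self.cfg.swish_beta)
        if which == "relu":
            return nn.relu(t)
        if which == "sigmoid":
            return nn.sigmoid(t)
        return t

    def __call__(self, x, training=False):
        if not self.substituted:
            y = self.conv(x)
            if self.bn is not None:
                y = self.bn(y, training)
            return self._act(y, self.final_act)
        k = (nn.concat_channels([c(x) for c in self.k_convs])
             if len(self.k_convs) > 1 else self.k_convs[0](x))
        if self.bn_k is not None:
            k = self.bn_k(k, training)
        if not self.has_l:
            return self._act(k, self.final_act)
        mid = self.cfg.activation if \
            self.cfg.intermediate_activation_placement == "after_k" else "none"
        k = self._act(k, mid)
        l = nn.gather_channels(k, self.perm)
        l = (nn.concat_channels([c(l) for c in self.l_convs])
             if len(self.l_convs) > 1 else self.l_convs[0](l))
        if self.bn_l is not None:
            l = self.bn_l(l, training)
        return self._act(nn.add(k, l), self.final_act)

    def original_param_count(self) -> int:
        """Parameters this slot would hold with the original convolution."""
        n = self.ic * self.f
        if self.kind == "se":
            n += self.f
        else:
            n += 2 * self.f
        return n


class _SEModule(nn.Module):
    """Squeeze-and-excitation: pooled features through reduce/expand 1x1
    convs rescale the block's channels."""

    def __init__(self, rng, name, channels, se_filters, ch, cfg, substitute_se):
        self.channels = channels
        self.reduce = _PWLayer(rng, f"{name}_se_reduce", channels, se_filters,
                               ch, "se", "swish", cfg, substitute_se)
        self.expand = _PWLayer(rng, f"{name}_se_expand", se_filters, channels,
                               ch, "se", "sigmoid", cfg, substitute_se)

    def __call__(self, x, training=False):
        s = nn.global_avg_pool(x)
        s = nn.reshape(s, (x.data.shape[0], 1, 1, self.channels))
        s = self.reduce(s, training)
        s = self.expand(s, training)
        return nn.mul(x, s)


class _MBConv(nn.Module):
    """Mobile inverted bottleneck: expansion pointwise, depthwise, SE,
    projection pointwise, with an identity residual when shapes allow."""

    def __init__(self, rng, name, in_ch, out_ch, kernel, stride,
                 expand_ratio, se_ratio, ch, cfg, substitute_se):
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        exp = in_ch * expand_ratio
        self.expand = None
        if expand_ratio != 1:
            self.expand = _PWLayer(rng, f"{name}_expand", in_ch, exp,
                                   ch, "main", "swish", cfg, substitute_se)
        self.dw = nn.DepthwiseConv2D(rng, exp, kernel, stride)
        self.dw_bn = nn.BatchNorm(exp)
        se_filters = max(1, int(in_ch * se_ratio))
        self.se = _SEModule(rng, name, exp, se_filters, ch, cfg, substitute_se)
        self.project = _PWLayer(rng, f"{name}_project", exp, out_ch,
                                ch, "main", "none", cfg, substitute_se)

    def __call__(self, x, training=False):
        y = x
        if self.expand is not None:
            y = self.expand(y, training)
        y = nn.swish(self.dw_bn(self.dw(y), training))
        y = self.se(y, training)
        y = self.project(y, training)
        if self.stride == 1 and self.in_ch == self.out_ch:
            y = nn.add(y, x)
        return y


class Classifier(nn.Module):
    """The full image classifier: stem, MBConv stages, head conv, global
    pooling, dropout and a dense softmax head."""

    def __init__(self, desc: BackboneDescriptor, ch: Optional[int] = None,
                 cfg: SubnetConfig = SubnetConfig(), substitute_se: bool = True,
                 rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng()
        self.desc, self.ch = desc, ch
        skips = desc.skip_strides

        def next_stride(s):
            nonlocal skips
            if s == 2 and skips > 0:
                skips -= 1
                return 1
            return s

        self.stem = nn.Conv2D(rng, 3, desc.stem_filters, 3,
                              stride=next_stride(2))
        self.stem_bn = nn.BatchNorm(desc.stem_filters)
        self.blocks: list[_MBConv] = []
        in_ch = desc.stem_filters
        for si, st in enumerate(desc.stages, start=1):
            for rep in range(st.repeats):
                stride = next_stride(st.stride) if rep == 0 else 1
                self.blocks.append(_MBConv(
                    rng, f"s{si}r{rep + 1}", in_ch, st.filters, st.kernel,
                    stride, st.expand_ratio, st.se_ratio, ch, cfg,
                    substitute_se))
                in_ch = st.filters
        self.head = _PWLayer(rng, "head_conv", in_ch, desc.head_filters,
                             ch, "main", "swish", cfg, substitute_se)
        self.dense = nn.Dense(rng, desc.head_filters, desc.num_classes)

    def __call__(self, x, training=False,
                 dropout_rng: Optional[np.random.Generator] = None):
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))
        y = nn.swish(self.stem_bn(self.stem(t), training))
        for b in self.blocks:
            y = b(y, training)
        y = self.head(y, training)
        y = nn.global_avg_pool(y)
        if dropout_rng is not None:
            y = nn.dropout(y, self.desc.dropout_rate, dropout_rng, training)
        return self.dense(y)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self(images, training=False).data)

    def pw_layers(self) -> list[_PWLayer]:
        out = []
        for b in self.blocks:
            if b.expand is not None:
                out.append(b.expand)
            out.extend([b.se.reduce, b.se.expand, b.project])
        out.append(self.head)
        return out

    def save_weights(self, path) -> None:
        np.savez(path, **{f"p{i}": p.data
                          for i, p in enumerate(self.parameters())})

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            for i, p in enumerate(self.parameters()):
                p.data = z[f"p{i}"]


# --------------------------------------------------------------------------
# reports


def _pct(part: int, whole: int) -> float:
    return float((Decimal(part) * 100 / Decimal(whole))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SavingsReport:
    """Per-layer and whole-model parameter/MAC accounting, baseline versus
    substituted."""

    rows: list[dict] = field(default_factory=list)
    baseline_total: int = 0
    substituted_total: int = 0
    baseline_macs: int = 0
    substituted_macs: int = 0

    @property
    def percent_params(self) -> float:
        return _pct(self.substituted_total, self.baseline_total)

    @property
    def percent_macs(self) -> float:
        return _pct(self.substituted_macs, self.baseline_macs)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "baseline_total": self.baseline_total,
            "substituted_total": self.substituted_total,
            "percent_params": self.percent_params,
            "baseline_macs": self.baseline_macs,
            "substituted_macs": self.substituted_macs,
            "percent_macs": self.percent_macs,
        }


def _spatial_sizes(model: Classifier) -> list[int]:
    """Output H (=W) of each pointwise layer slot, in pw_layers() order."""
    size = model.desc.input_size
    size = -(-size // model.stem.stride)
    sizes = []
    for b in model.blocks:
        pre = size
        size = -(-size // b.dw.stride)
        for layer in ([b.expand] if b.expand is not None else []):
            sizes.append(pre)           # expansion acts before downsampling
        sizes.extend([1, 1])            # SE convs act on pooled 1x1 maps
        sizes.append(size)              # projection
    sizes.append(size)                  # head conv
    return sizes


def savings_report(model: Classifier, baseline_total: int,
                   baseline_macs: Optional[int] = None) -> SavingsReport:
    rows = []
    sizes = _spatial_sizes(model)
    macs_base = macs_sub = 0
    for layer, hw in zip(model.pw_layers(), sizes):
        orig_w = layer.ic * layer.f
        new_w = (sum(c.w.data.size for c in layer.k_convs + layer.l_convs)
                 if layer.substituted else orig_w)
        rows.append({
            "layer": layer.name,
            "ic": layer.ic,
            "f": layer.f,
            "substituted": layer.substituted,
            "original_params": layer.original_param_count(),
            "new_params": layer.n_params(),
            "macs_original": hw * hw * orig_w,
            "macs_new": hw * hw * new_w,
        })
        macs_base += hw * hw * orig_w
        macs_sub += hw * hw * new_w
    return SavingsReport(
        rows=rows,
        baseline_total=baseline_total,
        substituted_total=model.n_params(),
        baseline_macs=macs_base,
        substituted_macs=macs_sub,
    )


def build_baseline(desc: BackboneDescriptor,
                   rng: Optional[np.random.Generator] = None) -> Classifier:
    """The unmodified classifier (standard pointwise convolutions)."""
    return Classifier(desc, ch=None, rng=rng)


def substitute_pointwise(
    desc: BackboneDescriptor,
    ch: int,
    cfg: SubnetConfig = SubnetConfig(),
    substitute_se: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Classifier, SavingsReport]:
    """Rebuild the classifier with every groupable pointwise convolution
    replaced by the interleaved grouped subnetwork."""
    if ch < 1:
        raise ValueError("ch must be >= 1")
    model = Classifier(desc, ch=ch, cfg=cfg, substitute_se=substitute_se,
                       rng=rng)
    baseline = build_baseline(desc, rng=np.random.default_rng(0))
    report = savings_report(model, baseline.n_params())
    return model, report


# --------------------------------------------------------------------------
# inference and smoke training


def hflip_ensemble_predict(model: Classifier, images: np.ndarray) -> np.ndarray:
    """Sum of softmax scores over the image and its horizontal mirror; the
    argmax of the sum is the prediction.  Doubles forward cost, adds no
    parameters."""
    p = model.predict_proba(images)
    p_flip = model.predict_proba(np.asarray(images)[:, :, ::-1, :])
    return p + p_flip


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def smoke_train(model: Classifier, images: np.ndarray, labels: np.ndarray,
                epochs: int, seed: int, lr: float = 2e-3,
                batch_size: int = 16) -> dict:
    """Short sanity-check optimisation loop (RMSProp, shuffled minibatches).

    Returns ``{"loss": [...], "accuracy": [...]}`` per epoch.  This is a
    learnability check on tiny synthetic data, not a training protocol.
    """
    rng = np.random.default_rng(seed)
    opt = nn.RMSProp(model.parameters(), lr=lr)
    history = {"loss": [], "accuracy": []}
    n = len(labels)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model(images[idx], training=True)
            loss, probs = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((probs.argmax(axis=-1) == labels[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history
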