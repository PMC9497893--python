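"""Materialize a substitution plan as a trainable subnetwork.

The subnetwork mirrors the planned blueprint: gather-and-convolve K paths,
concatenation to F channels, an optional intermediate activation, the fixed
odd/even interleaving permutation, L paths on the permuted channels, and an
element-wise sum joining L back onto K (a residual join — gradients reach K
both directly and through L).  Batch normalisation is deliberately not part
of the subnetwork; the enclosing block owns its normalisation and final
activation (see :mod:`igpconv.backbone`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from . import nn
from .plan import SubstitutionPlan

__all__ = ["SubnetConfig", "Subnetwork", "build_subnetwork", "swish"]


def swish(x, beta: float = 1.0):
    """Smooth gating activation ``x * sigmoid(beta * x)`` on arrays."""
    x = np.asarray(x)
    return x / (1.0 + np.exp(-beta * x))


@dataclass(frozen=True)
class SubnetConfig:
    """Behavioural knobs of the subnetwork.

    activation: nonlinearity used at the intermediate placement
        ("swish", "relu" or "none"; "none" gives the linear mode used for
        oracle equivalence checks).
    swish_beta: fixed gate sharpness of swish (not trained).
    enable_l: ablation switch — False drops interleaving and layer L, the
        output is the K concatenation alone.
    intermediate_activation_placement: "after_k" applies the activation to
        the K concatenation before interleaving; "none" keeps the interior
        linear.  The final activation after the sum belongs to the caller.
    use_bias: per-path bias vectors (off by default; the enclosing blocks
        normalise right after the convolution).
    """

    activation: Literal["swish", "relu", "none"] = "swish"
    swish_beta: float = 1.0
    enable_l: bool = True
    intermediate_activation_placement: Literal["after_k", "none"] = "after_k"
    weight_init: str = "glorot-uniform"
    use_bias: bool = False

    def __post_init__(self):
        if self.activation not in ("swish", "relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.intermediate_activation_placement not in ("after_k", "none"):
            raise ValueError("intermediate_activation_placement must be "
                             "'after_k' or 'none'")
        if self.weight_init != "glorot-uniform":
            raise ValueError("only glorot-uniform initialization is supported")


class Subnetwork(nn.Module):
    """Forward-callable owning the grouped-path weights of one plan."""

    def __init__(self, plan: SubstitutionPlan, cfg: SubnetConfig,
                 rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng()
        self.plan = plan
        self.cfg = cfg
        self.k_convs = [
            nn.GroupedPointwise(rng, p.input_groups, p.filters_per_group,
                                use_bias=cfg.use_bias)
            for p in plan.k_paths if p.total_filters > 0
        ]
        self.has_l = plan.has_l and cfg.enable_l
        self.l_convs = []
        self.perm = None
        if self.has_l:
            self.perm = np.asarray(plan.interleave_perm, dtype=np.intp)
            self.l_convs = [
                nn.GroupedPointwise(rng, p.input_groups, p.filters_per_group,
                                    use_bias=cfg.use_bias)
                for p in plan.l_paths if p.total_filters > 0
            ]

    def _activate(self, t: nn.Tensor) -> nn.Tensor:
        if self.cfg.intermediate_activation_placement == "none":
            return t
        if self.cfg.activation == "swish":
            return nn.swish(t, self.cfg.swish_beta)
        if self.cfg.activation == "relu":
            return nn.relu(t)
        return t

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.shape[-1] != self.plan.spec.ic:
            raise ValueError(
                f"expected {self.plan.spec.ic} input channels, "
                f"got {x.data.shape[-1]}")
        k = nn.concat_channels([conv(x) for conv in self.k_convs]) \
            if len(self.k_convs) > 1 else self.k_convs[0](x)
        k = self._activate(k)
        if not self.has_l:
            return k
        inter = nn.gather_channels(k, self.perm)
        l = nn.concat_channels([conv(inter) for conv in self.l_convs]) \
            if len(self.l_convs) > 1 else self.l_convs[0](inter)
        return nn.add(k, l)

    def forward_array(self, x: np.ndarray) -> np.ndarray:
        """Convenience forward on a plain N×H×W×Ic array."""
        return self(nn.Tensor(np.asarray(x))).data

    # weight plumbing for oracle tests and serialization -------------------

    def k_path_weights(self) -> list[list[np.ndarray]]:
        """Per-path, per-group weight matrices in plan order."""
        return [conv.get_weights() for conv in self.k_convs]

    def l_path_weights(self) -> list[list[np.ndarray]]:
        return [conv.get_weights() for conv in self.l_convs]

    def set_k_path_weights(self, weights: Sequence[Sequence[np.ndarray]]) -> None:
        for conv, w in zip(self.k_convs, weights):
            conv.set_weights(w)

    def set_l_path_weights(self, weights: Sequence[Sequence[np.ndarray]]) -> None:
        for conv, w in zip(self.l_convs, weights):
            conv.set_weights(w)


def build_subnetwork(plan: SubstitutionPlan, cfg: SubnetConfig = SubnetConfig(),
                     rng: Optional[np.random.Generator] = None) -> Subnetwork:
    """Build the trainable subnetwork for a plan; deterministic given ``rng``."""
    return Subnetwork(plan, cfg, rng)
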