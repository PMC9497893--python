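"""Integer planning of interleaved grouped pointwise substitutions.

A standard pointwise (1x1) convolution with ``ic`` input channels and ``f``
filters carries ``ic * f`` weights.  The substitution scheme replaces it with
two grouped pointwise layers K and L joined by a channel interleaving and a
final element-wise sum.  Every filter in either layer sees exactly ``ch``
input channels (the scheme's single hyperparameter), so an eligible layer is
rebuilt with ``2 * f * ch`` weights — or ``f * ch`` when the second layer L
is dropped because the layer widens (``ic < f``).

Non-divisible shapes are handled without padding the network itself:

* when ``ch`` does not divide the input channel count, the last channel
  group is completed by replicating channels from the start of the input;
* when the filter count is not a multiple of the group count, a second
  parallel path contributes the remaining filters, one filter per group,
  reusing the first channel groups of the main path.

Everything in this module is pure integer arithmetic on 0-based indices; no
tensor framework is involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Optional, Sequence

__all__ = [
    "LayerSpec",
    "PathPlan",
    "SubstitutionPlan",
    "IneligibleLayerError",
    "is_eligible",
    "can_group",
    "channel_groups",
    "interleave_permutation",
    "plan_paths",
    "make_substitution_plan",
    "count_params",
    "baseline_params",
    "grouped_params",
    "count_macs",
    "table1_row",
    "plan_to_json",
    "plan_from_json",
]

DegenerateMode = Literal["extra", "widen"]


class IneligibleLayerError(ValueError):
    """Raised when a layer must be kept as an original pointwise convolution."""


@dataclass(frozen=True)
class LayerSpec:
    """The triple describing one pointwise layer: input channels, filters,
    and the channels-per-group hyperparameter."""

    ic: int
    f: int
    ch: int

    def __post_init__(self) -> None:
        for name in ("ic", "f", "ch"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class PathPlan:
    """One grouped path: ``groups`` filter groups of ``filters_per_group``
    filters each, with per-group input-channel index lists.

    ``input_groups[m]`` lists the 0-based input channel indices consumed by
    group ``m``.  All lists share one length (the effective group width);
    repeated indices in the last list of a main path realise replication.
    """

    groups: int
    filters_per_group: int
    input_groups: tuple[tuple[int, ...], ...]

    @property
    def total_filters(self) -> int:
        return self.groups * self.filters_per_group

    @property
    def width(self) -> int:
        """Input channels seen by each filter in this path."""
        return len(self.input_groups[0]) if self.input_groups else 0

    @property
    def weight_count(self) -> int:
        return self.total_filters * self.width


@dataclass(frozen=True)
class SubstitutionPlan:
    """Complete K / interleave / L / sum blueprint for one layer."""

    spec: LayerSpec
    k1: PathPlan
    k2: Optional[PathPlan]
    has_l: bool
    interleave_perm: Optional[tuple[int, ...]]
    l1: Optional[PathPlan]
    l2: Optional[PathPlan]
    param_count: int = field(default=0)
    mac_count_per_position: int = field(default=0)

    @property
    def k_paths(self) -> tuple[PathPlan, ...]:
        return (self.k1,) if self.k2 is None else (self.k1, self.k2)

    @property
    def l_paths(self) -> tuple[PathPlan, ...]:
        if not self.has_l:
            return ()
        return (self.l1,) if self.l2 is None else (self.l1, self.l2)


def is_eligible(spec: LayerSpec) -> bool:
    """Substitution predicate: ``ch`` may not exceed half the input channels
    nor half the filters, otherwise grouping cannot reduce the layer and the
    caller keeps the original convolution."""
    return spec.ch <= spec.ic / 2 and spec.ch <= spec.f / 2


def can_group(spec: LayerSpec) -> bool:
    """Weaker predicate: at least two channel groups exist (``ic > ch``).

    This is the substitution criterion effectively applied when converting a
    whole backbone (see :mod:`igpconv.backbone`): any layer that admits more
    than one group is rebuilt, even if it fails the stricter
    :func:`is_eligible` guidance.
    """
    return math.ceil(spec.ic / spec.ch) >= 2


def channel_groups(n_channels: int, ch: int) -> list[list[int]]:
    """Partition ``n_channels`` into ``ceil(n_channels / ch)`` groups of
    exactly ``ch`` indices, replicating initial channels into the last group
    when the division is not exact.

    With deficit ``d = G*ch - n_channels`` the last group holds the final
    ``ch - d`` real indices followed by the first ``d`` indices repeated from
    the start (wrapping around if necessary).
    """
    if n_channels < 1 or ch < 1:
        raise ValueError("n_channels and ch must be >= 1")
    g = math.ceil(n_channels / ch)
    d = g * ch - n_channels  # deficit: 0 <= d < ch
    groups = [list(range(m * ch, (m + 1) * ch)) for m in range(g - 1)]
    last = list(range((g - 1) * ch, n_channels))
    last += [i % n_channels for i in range(d)]
    groups.append(last)
    return groups


def interleave_permutation(n: int) -> list[int]:
    """Source-index order placing the odd-numbered channels (1st, 3rd, ...)
    first and the even-numbered ones last; 0-based this is
    ``[0, 2, 4, ..., 1, 3, 5, ...]``.  For odd ``n`` the first block holds
    the extra channel.  The result is a bijection on ``{0..n-1}``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(range(0, n, 2)) + list(range(1, n, 2))


def plan_paths(
    n_input: int,
    f: int,
    ch: int,
    degenerate: DegenerateMode = "extra",
) -> tuple[PathPlan, Optional[PathPlan]]:
    """Plan the main and (optional) extra grouped path for one layer.

    The main path uses ``G = ceil(n_input / ch)`` groups of
    ``floor(f / G)`` filters; filters not covered go to an extra path with
    one filter per group, reusing the first channel groups of the main path.

    When ``floor(f / G) == 0`` (more groups than filters) two behaviours are
    offered.  ``degenerate="extra"`` keeps the requested width: the main
    path carries zero filters and all ``f`` filters live in the extra path.
    ``degenerate="widen"`` raises the group width to ``ceil(n_input / f)``
    so that every group holds at least one filter; this is the behaviour
    observed in whole-model parameter totals of the reference classifier.
    """
    if n_input < 1 or f < 1 or ch < 1:
        raise ValueError("n_input, f and ch must be >= 1")
    # a single group is a plain convolution: never replicate past the input
    ch = min(ch, n_input)
    g = math.ceil(n_input / ch)
    if f // g == 0 and degenerate == "widen":
        ch = math.ceil(n_input / f)
        g = math.ceil(n_input / ch)
    fg = f // g
    igroups = tuple(tuple(gr) for gr in channel_groups(n_input, ch))
    main = PathPlan(groups=g, filters_per_group=fg, input_groups=igroups)
    n_extra = f - fg * g
    if n_extra == 0:
        return main, None
    extra = PathPlan(
        groups=n_extra,
        filters_per_group=1,
        input_groups=igroups[:n_extra],
    )
    return main, extra


def make_substitution_plan(
    spec: LayerSpec,
    *,
    require_eligible: bool = True,
    degenerate: DegenerateMode = "extra",
) -> SubstitutionPlan:
    """Turn a :class:`LayerSpec` into a full K/interleave/L/sum blueprint.

    Layer L (fed by the interleaved K output, summed with K at the end) is
    included only when the layer narrows or preserves width
    (``ic >= f``); widening layers keep the single grouped layer K.

    Raises :class:`IneligibleLayerError` when the spec fails
    :func:`is_eligible` (or, with ``require_eligible=False``, when not even
    two channel groups fit) — the caller keeps the original convolution.
    """
    if require_eligible:
        if not is_eligible(spec):
            raise IneligibleLayerError(
                f"layer (ic={spec.ic}, f={spec.f}) is kept original: "
                f"ch={spec.ch} exceeds ic/2 or f/2"
            )
    elif not can_group(spec):
        raise IneligibleLayerError(
            f"layer (ic={spec.ic}, f={spec.f}) is kept original: "
            f"ch={spec.ch} admits a single group only"
        )
    k1, k2 = plan_paths(spec.ic, spec.f, spec.ch, degenerate=degenerate)
    has_l = spec.ic >= spec.f
    perm = l1 = l2 = None
    if has_l:
        perm = tuple(interleave_permutation(spec.f))
        # L consumes the f interleaved K outputs and emits f channels;
        # it can never hit the degenerate case (ceil(f/ch) <= f always).
        l1, l2 = plan_paths(spec.f, spec.f, spec.ch, degenerate=degenerate)
    plan = SubstitutionPlan(
        spec=spec, k1=k1, k2=k2, has_l=has_l,
        interleave_perm=perm, l1=l1, l2=l2,
    )
    n = _weight_count(plan)
    return SubstitutionPlan(
        spec=spec, k1=k1, k2=k2, has_l=has_l,
        interleave_perm=perm, l1=l1, l2=l2,
        param_count=n, mac_count_per_position=n,
    )


def _weight_count(plan: SubstitutionPlan) -> int:
    return sum(p.weight_count for p in plan.k_paths + plan.l_paths)


def count_params(plan: SubstitutionPlan) -> int:
    """Trainable weight count of the subnetwork: ``ch`` weights per filter
    over every path, bias-free.  Equals ``2 * f * ch`` when layer L is
    present and ``f * ch`` otherwise (non-degenerate plans)."""
    return _weight_count(plan)


def baseline_params(spec: LayerSpec) -> int:
    """Weight count of the original pointwise layer: ``ic * f``."""
    return spec.ic * spec.f


def grouped_params(ic: int, f: int, g: int) -> int:
    """Weight count of a plain grouped pointwise convolution with ``g``
    groups (exact divisibility assumed): ``ic * f / g``."""
    if ic % g or f % g:
        raise ValueError(f"g={g} must divide both ic={ic} and f={f}")
    return ic * f // g


def count_macs(plan: SubstitutionPlan, h: int, w: int) -> int:
    """Multiply-accumulate count of the subnetwork over an ``h`` x ``w``
    output map: one MAC per weight per spatial position.  Activation and
    normalisation operations are not included."""
    if h < 1 or w < 1:
        raise ValueError("h and w must be >= 1")
    return h * w * plan.mac_count_per_position


def percent(part: int, whole: int, decimals: int = 2) -> Decimal:
    """Percentage rounded half-up, mirroring printed report style."""
    q = Decimal(10) ** -decimals
    return (Decimal(part) * 100 / Decimal(whole)).quantize(q, rounding=ROUND_HALF_UP)


def table1_row(spec: LayerSpec) -> dict:
    """One summary row for a planned layer: group/filter columns of both
    layers, the weight total, and the percentage of the original cost."""
    plan = make_substitution_plan(spec)
    return {
        "Ic": spec.ic,
        "F": spec.f,
        "P": baseline_params(spec),
        "Ch": spec.ch,
        "GK1": plan.k1.groups,
        "FgK1": plan.k1.filters_per_group,
        "GK2": plan.k2.groups if plan.k2 else 0,
        "GL1": plan.l1.groups if plan.has_l else 0,
        "FgL1": plan.l1.filters_per_group if plan.has_l else 0,
        "GL2": plan.l2.groups if plan.has_l and plan.l2 else 0,
        "Total": plan.param_count,
        "Percent": float(percent(plan.param_count, baseline_params(spec))),
    }


def _path_to_json(p: Optional[PathPlan]) -> Optional[dict]:
    if p is None:
        return None
    return {
        "groups": p.groups,
        "filters_per_group": p.filters_per_group,
        "input_groups": [list(g) for g in p.input_groups],
    }


def _path_from_json(d: Optional[dict]) -> Optional[PathPlan]:
    if d is None:
        return None
    return PathPlan(
        groups=d["groups"],
        filters_per_group=d["filters_per_group"],
        input_groups=tuple(tuple(g) for g in d["input_groups"]),
    )


def plan_to_json(plan: SubstitutionPlan) -> str:
    doc = {
        "spec": {"ic": plan.spec.ic, "f": plan.spec.f, "ch": plan.spec.ch},
        "k1": _path_to_json(plan.k1),
        "k2": _path_to_json(plan.k2),
        "has_l": plan.has_l,
        "interleave_perm": list(plan.interleave_perm) if plan.interleave_perm else None,
        "l1": _path_to_json(plan.l1),
        "l2": _path_to_json(plan.l2),
        "param_count": plan.param_count,
        "mac_count_per_position": plan.mac_count_per_position,
    }
    return json.dumps(doc, indent=1)


def plan_from_json(text: str) -> SubstitutionPlan:
    d = json.loads(text)
    return SubstitutionPlan(
        spec=LayerSpec(**d["spec"]),
        k1=_path_from_json(d["k1"]),
        k2=_path_from_json(d["k2"]),
        has_l=d["has_l"],
        interleave_perm=tuple(d["interleave_perm"]) if d["interleave_perm"] else None,
        l1=_path_from_json(d["l1"]),
        l2=_path_from_json(d["l2"]),
        param_count=d["param_count"],
        mac_count_per_position=d["mac_count_per_position"],
    )
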