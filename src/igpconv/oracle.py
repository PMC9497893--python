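"""Naive reference implementations of pointwise and grouped pointwise
convolution, plus a plan "densifier".

These are the ground truth the trainable subnetwork is checked against:
deliberately simple gather / matrix-product computations in double
precision, with no attention to performance.  ``densify`` folds a planned
subnetwork's grouped weights into equivalent dense F x C matrices so the
whole K / interleave / L / sum pipeline (in linear mode) collapses to two
plain pointwise convolutions and a permutation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .plan import PathPlan, SubstitutionPlan

__all__ = [
    "pointwise_conv",
    "grouped_pointwise_conv",
    "densify",
    "subnet_forward_dense",
]


def pointwise_conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Regular 1x1 convolution: ``out[n,h,v,j] = sum_c x[n,h,v,c] * w[j,c]``.

    ``x`` is an N x H x W x C feature-map stack, ``w`` an F x C weight
    matrix (one row per filter; spatial extent 1 so spatial axes dropped).
    """
    x = np.asarray(x)
    w = np.asarray(w)
    if x.ndim != 4 or w.ndim != 2:
        raise ValueError("x must be N×H×W×C and w must be F×C")
    if x.shape[-1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]}, weights expect {w.shape[1]}"
        )
    return x @ w.T


def grouped_pointwise_conv(
    x: np.ndarray,
    per_group_weights: Sequence[np.ndarray],
    input_groups: Sequence[Sequence[int]],
) -> np.ndarray:
    """Grouped 1x1 convolution with explicit channel gathering.

    Group ``m`` applies ``per_group_weights[m]`` (Fg x len(input_groups[m]))
    to the gathered channels ``x[..., input_groups[m]]``; outputs are
    concatenated over groups.  Replicated (repeated) indices are legal —
    gather semantics mean a channel consumed twice feeds two weight slots.
    """
    if len(per_group_weights) != len(input_groups):
        raise ValueError("one weight matrix per input group required")
    n_ch = x.shape[-1]
    outs = []
    for w, idx in zip(per_group_weights, input_groups):
        idx = list(idx)
        if any(i < 0 or i >= n_ch for i in idx):
            raise IndexError(f"channel index out of range in group {idx}")
        outs.append(pointwise_conv(x[..., idx], w))
    return np.concatenate(outs, axis=-1)


def _densify_paths(
    paths: Sequence[PathPlan],
    weights: Sequence[Sequence[np.ndarray]],
    n_in: int,
    n_out: int,
) -> np.ndarray:
    """Scatter grouped path weights into a dense n_out x n_in matrix.

    Rows follow the concatenation order of the paths' group outputs.
    Replicated input indices accumulate: a channel consumed through two
    slots of one filter contributes the sum of both weights.
    """
    dense = np.zeros((n_out, n_in), dtype=np.float64)
    row = 0
    paths = [p for p in paths if p.total_filters > 0]  # zero-filter paths own no weights
    for path, path_w in zip(paths, weights):
        if len(path_w) != path.groups:
            raise ValueError("weight/group count mismatch")
        for idx, w in zip(path.input_groups, path_w):
            w = np.asarray(w, dtype=np.float64)
            if w.shape != (path.filters_per_group, len(idx)):
                raise ValueError(
                    f"expected weights {(path.filters_per_group, len(idx))}, got {w.shape}"
                )
            for j in range(path.filters_per_group):
                np.add.at(dense[row + j], list(idx), w[j])
            row += path.filters_per_group
    if row != n_out:
        raise ValueError(f"paths provide {row} filters, expected {n_out}")
    return dense


def densify(
    plan: SubstitutionPlan,
    k_weights: Sequence[Sequence[np.ndarray]],
    l_weights: Optional[Sequence[Sequence[np.ndarray]]] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Fold a plan's grouped weights into dense equivalents.

    Returns ``(wk_eff, wl_eff)`` with ``wk_eff`` of shape F x Ic and
    ``wl_eff`` (present iff the plan has layer L) of shape F x F, built
    against the *interleaved* channel ordering: in linear mode the
    subnetwork output equals

        k + pointwise_conv(k[..., perm], wl_eff)   with
        k = pointwise_conv(x, wk_eff)
    """
    f, ic = plan.spec.f, plan.spec.ic
    wk_eff = _densify_paths(plan.k_paths, k_weights, ic, f)
    wl_eff = None
    if plan.has_l and l_weights is not None:
        wl_eff = _densify_paths(plan.l_paths, l_weights, f, f)
    elif not plan.has_l and l_weights:
        raise ValueError("plan has no layer L but L weights were given")
    return wk_eff, wl_eff


def subnet_forward_dense(
    plan: SubstitutionPlan,
    x: np.ndarray,
    k_weights: Sequence[Sequence[np.ndarray]],
    l_weights: Optional[Sequence[Sequence[np.ndarray]]] = None,
) -> np.ndarray:
    """Linear-mode subnetwork output computed via the densified matrices:
    K output plus (when present) L applied to the interleaved K output."""
    if plan.has_l and not l_weights:
        raise ValueError("plan has layer L but no L weights given")
    wk_eff, wl_eff = densify(plan, k_weights, l_weights)
    k = pointwise_conv(x, wk_eff)
    if wl_eff is None:
        return k
    perm = list(plan.interleave_perm)
    l = pointwise_conv(k[..., perm], wl_eff)
    return k + l
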