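"""Synthetic RGB classification fixtures.

Generates small, balanced, class-separable image sets standing in for the
kind of data the substituted classifiers target (natural-image and
stained-cell/histology patches at smoke scale): each class has its own
base colour, blob count and texture frequency, with additive pixel noise.
A linear probe on mean-colour features already separates the classes, so
short training runs can demonstrate learnability without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticImageSet", "generate_synthetic_set"]


@dataclass(frozen=True)
class SyntheticImageSet:
    images: np.ndarray          # N x H x W x 3, float32 in [0, 1]
    labels: np.ndarray          # N ints in [0, classes)
    classes: int
    seed: int

    def __len__(self) -> int:
        return len(self.labels)


def generate_synthetic_set(classes: int, n: int, size: int,
                           seed: int, noise: float = 0.08) -> SyntheticImageSet:
    """Balanced synthetic image set, deterministic given ``seed``.

    Each class draws images around a class-specific colour with
    class-dependent blob counts and a sinusoidal texture of class-dependent
    frequency; ``noise`` is the additive Gaussian pixel noise level.
    """
    if classes < 2:
        raise ValueError("classes must be >= 2")
    if n < classes or n % classes:
        raise ValueError("n must be a positive multiple of classes")
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    per = n // classes
    base_colors = rng.uniform(0.15, 0.85, size=(classes, 3))
    images = np.empty((n, size, size, 3), dtype=np.float32)
    labels = np.repeat(np.arange(classes), per)
    yy, xx = np.mgrid[0:size, 0:size] / size
    i = 0
    for c in range(classes):
        freq = 2 + 2 * c
        for _ in range(per):
            img = np.broadcast_to(base_colors[c], (size, size, 3)).copy()
            tex = 0.10 * np.sin(2 * np.pi * freq * (xx + rng.uniform()))
            img += tex[..., None]
            for _ in range(1 + c % 3):
                cy, cx = rng.uniform(0.2, 0.8, size=2)
                r = rng.uniform(0.08, 0.2)
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2
                img[mask] = rng.uniform(0, 1, size=3)
            img += rng.normal(0, noise, size=img.shape)
            images[i] = np.clip(img, 0.0, 1.0)
            i += 1
    return SyntheticImageSet(images=images, labels=labels,
                             classes=classes, seed=seed)
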