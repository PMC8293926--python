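"""On-the-fly label-preserving augmentation for training batches.

Flips are exact; shifts are limited to +-10% of the image side and
rotations to +-15 degrees (linear interpolation, edge replication), so
the abnormality stays inside the frame and the class label is
preserved.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import rotate, shift

MAX_ROTATION_DEG = 15.0
MAX_SHIFT_FRAC = 0.10


def augment_batch(batch: np.ndarray, rng: np.random.Generator,
                  flip: bool = True, do_shift: bool = True,
                  do_rotate: bool = True) -> np.ndarray:
    """Augment a (B, H, W) batch of images in [0, 1]."""
    out = batch.copy()
    b, h, w = out.shape
    for i in range(b):
        img = out[i]
        if flip:
            if rng.random() < 0.5:
                img = img[:, ::-1]
            if rng.random() < 0.5:
                img = img[::-1, :]
        if do_rotate:
            angle = rng.uniform(-MAX_ROTATION_DEG, MAX_ROTATION_DEG)
            img = rotate(img, angle, reshape=False, order=1, mode="nearest")
        if do_shift:
            dy = rng.uniform(-MAX_SHIFT_FRAC, MAX_SHIFT_FRAC) * h
            dx = rng.uniform(-MAX_SHIFT_FRAC, MAX_SHIFT_FRAC) * w
            img = shift(img, (dy, dx), order=1, mode="nearest")
        out[i] = np.clip(img, 0.0, 1.0)
    return out
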