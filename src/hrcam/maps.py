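"""Activation-map container, bilinear upsampling, normalization, export.

Bilinear upsampling uses the *corner-aligned* pixel-center convention:
the centers of the four corner pixels of the input map coincide with
those of the output, i.e. an output index u maps to source coordinate
``u * (h_in - 1) / (h_out - 1)``.  Different conventions shift maps by
up to one input pixel; this one is fixed and documented so that maps
are comparable across methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

METHODS = ("hrcam", "zhou_cam", "grad_cam")


@dataclass
class ActivationMap:
    """A real-valued class activation map at input resolution."""

    values: np.ndarray
    class_id: int
    normalized: bool = False
    source_method: str = "hrcam"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if self.source_method not in METHODS:
            raise ValueError(f"unknown method {self.source_method!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def bilinear_upsample(values: np.ndarray, out_size: tuple[int, int]
                      ) -> np.ndarray:
    """Upsample a 2-D map to ``out_size`` (corner-aligned bilinear).

    Output values are convex combinations of input values, hence stay
    within [min, max] of the input.  Downsampling requests are refused.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.size == 0:
        raise ValueError("map must be a non-empty 2-D array")
    h_in, w_in = v.shape
    h_out, w_out = out_size
    if h_out < h_in or w_out < w_in:
        raise ValueError(f"refusing to downsample {v.shape} -> {out_size}")

    def src_coords(n_in: int, n_out: int) -> np.ndarray:
        if n_in == 1 or n_out == 1:
            return np.zeros(n_out)
        return np.arange(n_out) * (n_in - 1) / (n_out - 1)

    ys, xs = src_coords(h_in, h_out), src_coords(w_in, w_out)
    y0 = np.clip(np.floor(ys).astype(int), 0, h_in - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w_in - 1)
    y1 = np.minimum(y0 + 1, h_in - 1)
    x1 = np.minimum(x0 + 1, w_in - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    return ((1 - wy) * (1 - wx) * v[np.ix_(y0, x0)]
            + (1 - wy) * wx * v[np.ix_(y0, x1)]
            + wy * (1 - wx) * v[np.ix_(y1, x0)]
            + wy * wx * v[np.ix_(y1, x1)])


def min_max_normalize(amap: ActivationMap) -> ActivationMap:
    """Rescale to [0, 1]; a constant map normalizes to all zeros.

    Idempotent: normalizing a normalized map returns it unchanged.
    """
    if amap.normalized:
        return amap
    v = amap.values
    lo, hi = float(v.min()), float(v.max())
    out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return ActivationMap(values=out, class_id=amap.class_id, normalized=True,
                         source_method=amap.source_method)


# ---------------------------------------------------------------------------
# Export: 16-bit PNG + JSON sidecar so raw values are recoverable.
# ---------------------------------------------------------------------------

def save_map(amap: ActivationMap, path: str | Path) -> None:
    path = Path(path)
    v = amap.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    img16 = np.round(scaled * 65535).astype(np.uint16)
    Image.fromarray(img16).save(path.with_suffix(".png"))
    sidecar = {"min": lo, "max": hi, "class_id": int(amap.class_id),
               "normalized": bool(amap.normalized),
               "method": amap.source_method}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_map(path: str | Path) -> ActivationMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    img16 = np.asarray(Image.open(path.with_suffix(".png")), dtype=float)
    values = meta["min"] + (meta["max"] - meta["min"]) * img16 / 65535.0
    return ActivationMap(values=values, class_id=meta["class_id"],
                         normalized=meta["normalized"],
                         source_method=meta["method"])


def save_overlay(amap: ActivationMap, image: np.ndarray, path: str | Path,
                 alpha: float = 0.5) -> None:
    """Write a simple red-overlay visualization PNG (inspection aid)."""
    norm = min_max_normalize(amap).values
    gray = np.clip(np.asarray(image, dtype=float), 0, 1)
    rgb = np.stack([gray * (1 - alpha) + alpha * norm,
                    gray * (1 - alpha),
                    gray * (1 - alpha)], axis=-1)
    Image.fromarray(np.round(rgb * 255).astype(np.uint8)).save(Path(path))
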