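"""Two-class synthetic pathology simulator with ground-truth masks.

The simulated cohort has a normative class (a fixed smooth phantom plus
additive Gaussian noise) and an abnormal class carrying two regimes of
perturbation on top of the same phantom: *localized* circular blobs at
random positions, and a *diffuse* low-frequency spatially correlated
intensity field restricted to a random elliptical region.  Every
abnormal image carries a binary ground-truth mask that marks exactly
the pixels whose noiseless intensity was perturbed, which makes
pixel-wise evaluation of activation maps well-posed.

A single global seed drives a per-image seed sequence, so datasets of
different sizes share a common prefix of images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class DatasetError(ValueError):
    """Malformed on-disk dataset."""


@dataclass
class LabeledImage:
    """A 2-D image with a class label and optional abnormality mask.

    ``pixels`` are intensities in [0, 1]; ``mask`` (when present) is a
    boolean array of the same shape with True marking abnormal pixels.
    Normative (label 0) images always carry an all-zero mask.
    """

    pixels: np.ndarray
    label: int
    mask: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must equal pixels shape")
            if self.label == 0 and self.mask.any():
                raise ValueError("normative (label 0) images must have empty masks")


@dataclass
class SimulationConfig:
    """Parameters of the simulated cohort.

    Defaults define the study conditions used throughout the package:
    64x64 images, Gaussian pixel noise with sd 0.05, one to three
    additive blobs of radius 3-8 px and amplitude 0.25-0.5, and a
    diffuse zero-mean correlated field (correlation length 6 px,
    amplitude 0.15) confined to a random ellipse.
    """

    n_per_class: int = 100
    image_size: tuple[int, int] = (64, 64)
    noise_sd: float = 0.05
    n_blobs: tuple[int, int] = (1, 3)
    blob_radius: tuple[float, float] = (3.0, 8.0)
    blob_amplitude: tuple[float, float] = (0.25, 0.5)
    diffuse_corr_length: float = 6.0
    diffuse_amplitude: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if h < 8 or w < 8:
            raise ConfigurationError("image_size must be at least 8x8")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for lo, hi, name in [(*self.n_blobs, "n_blobs"),
                             (*self.blob_radius, "blob_radius"),
                             (*self.blob_amplitude, "blob_amplitude")]:
            if lo > hi or lo < 0:
                raise ConfigurationError(f"invalid {name} range ({lo}, {hi})")
        if self.blob_amplitude[1] > 1.0 or self.diffuse_amplitude > 1.0:
            raise ConfigurationError("amplitudes above 1 cannot stay within [0, 1]")
        if self.diffuse_corr_length <= 0 or self.diffuse_amplitude < 0:
            raise ConfigurationError("invalid diffuse-field parameters")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("image_size", "n_blobs", "blob_radius", "blob_amplitude"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# Phantom intensity range kept strictly inside (0, 1) so that an additive
# perturbation always changes the clipped noiseless intensity.
_TEMPLATE_LO, _TEMPLATE_HI = 0.15, 0.80


def normative_template(image_size: tuple[int, int]) -> np.ndarray:
    """Fixed smooth background phantom shared by both classes.

    A radial bump on a diagonal intensity gradient; values lie in
    [0.15, 0.80] so class signal resides only in the perturbations.
    """
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy + 0.5) / h - 0.5
    x = (xx + 0.5) / w - 0.5
    r2 = x * x + y * y
    t = 0.55 * np.exp(-r2 / 0.08) + 0.25 * (x + y + 1.0)
    t = (t - t.min()) / (t.max() - t.min())
    return _TEMPLATE_LO + (_TEMPLATE_HI - _TEMPLATE_LO) * t


def _blob_perturbation(shape: tuple[int, int], center: tuple[float, float],
                       radius: float, amplitude: float) -> np.ndarray:
    """Additive disk: support is exactly {d <= radius}, profile tapers
    towards the rim but stays strictly positive on the support."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    inside = d2 <= radius ** 2
    profile = amplitude * (1.0 - 0.9 * d2 / radius ** 2)
    return np.where(inside, profile, 0.0)


def _diffuse_perturbation(shape: tuple[int, int], rng: np.random.Generator,
                          corr_length: float, amplitude: float) -> np.ndarray:
    """Zero-mean correlated field restricted to a random ellipse."""
    h, w = shape
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=corr_length,
                            mode="reflect")
    sd = field.std()
    if sd > 0:
        field *= amplitude / (3.0 * sd)  # ~99.7% of values within +-amplitude
    cy = rng.uniform(0.25 * h, 0.75 * h)
    cx = rng.uniform(0.25 * w, 0.75 * w)
    ay = rng.uniform(0.2 * h, 0.45 * h)
    ax = rng.uniform(0.2 * w, 0.45 * w)
    yy, xx = np.mgrid[0:h, 0:w]
    region = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    return np.where(region, field, 0.0)


def _abnormal_perturbation(shape: tuple[int, int], rng: np.random.Generator,
                           config: SimulationConfig) -> np.ndarray:
    pert = np.zeros(shape)
    n_blobs = int(rng.integers(config.n_blobs[0], config.n_blobs[1] + 1))
    h, w = shape
    for _ in range(n_blobs):
        radius = rng.uniform(*config.blob_radius)
        amp = rng.uniform(*config.blob_amplitude)
        cy = rng.uniform(radius, h - 1 - radius) if h - 1 > 2 * radius else h / 2
        cx = rng.uniform(radius, w - 1 - radius) if w - 1 > 2 * radius else w / 2
        pert += _blob_perturbation(shape, (cy, cx), radius, amp)
    if config.diffuse_amplitude > 0:
        pert += _diffuse_perturbation(shape, rng, config.diffuse_corr_length,
                                      config.diffuse_amplitude)
    return pert


def _render(template: np.ndarray, pert: np.ndarray, noise: np.ndarray
            ) -> np.ndarray:
    return np.clip(template + pert + noise, 0.0, 1.0)


def generate_dataset(config: SimulationConfig) -> list[LabeledImage]:
    """Generate ``2 * n_per_class`` images (balanced, deterministic).

    Class 0 is the phantom plus noise; class 1 additionally carries the
    localized and diffuse perturbations.  Class-1 masks are exactly the
    support of the noiseless perturbation.  The same seed reproduces the
    dataset bit for bit, and the first ``n`` images per class coincide
    across configs differing only in ``n_per_class``.
    """
    config.validate()
    template = normative_template(config.image_size)
    images: list[LabeledImage] = []
    for label in (0, 1):
        for i in range(config.n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed,
                                       spawn_key=(label, i)))
            if label == 1:
                pert = _abnormal_perturbation(config.image_size, rng, config)
                mask = pert != 0
            else:
                pert = np.zeros(config.image_size)
                mask = np.zeros(config.image_size, dtype=bool)
            noise = (rng.normal(0.0, config.noise_sd, size=config.image_size)
                     if config.noise_sd > 0 else np.zeros(config.image_size))
            pixels = _render(template, pert, noise)
            images.append(LabeledImage(pixels=pixels, label=label, mask=mask,
                                       sample_id=f"c{label}_{i:05d}"))
    return images


def noiseless_pair(config: SimulationConfig, label: int, index: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Return (template, noiseless perturbed image) for one sample.

    Regenerates the perturbation of sample ``index`` of class ``label``
    with the noise turned off; used to assert that mask support equals
    the set of pixels the perturbation actually changed.
    """
    config.validate()
    template = normative_template(config.image_size)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(label, index)))
    if label == 1:
        pert = _abnormal_perturbation(config.image_size, rng, config)
    else:
        pert = np.zeros(config.image_size)
    return template, _render(template, pert, np.zeros(config.image_size))


# ---------------------------------------------------------------------------
# On-disk format: 8-bit grayscale PNGs, {0,255} mask PNGs, CSV manifest.
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
_MANIFEST_COLUMNS = ["sample_id", "label", "image_path", "mask_path"]


def write_dataset(images: Iterable[LabeledImage], directory: str | Path) -> Path:
    """Write images/masks as PNGs plus a CSV manifest; returns manifest path."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        image_rel = f"images/{img.sample_id}.png"
        arr8 = np.round(img.pixels * 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(directory / image_rel)
        mask_rel = ""
        if img.mask is not None:
            mask_rel = f"masks/{img.sample_id}.png"
            Image.fromarray(img.mask.astype(np.uint8) * 255,
                            mode="L").save(directory / mask_rel)
        rows.append({"sample_id": img.sample_id, "label": img.label,
                     "image_path": image_rel, "mask_path": mask_rel})
    manifest = directory / MANIFEST_NAME
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_dataset(directory: str | Path) -> list[LabeledImage]:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`DatasetError` for a missing manifest or label column,
    image files on disk that the manifest does not list, missing
    referenced files, and mask/image shape mismatches.
    """
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise DatasetError(f"no manifest found at {manifest}")
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "label" not in reader.fieldnames:
            raise DatasetError("manifest lacks a 'label' column")
        rows = list(reader)
    listed = {r["image_path"] for r in rows}
    on_disk = {f"images/{p.name}" for p in (directory / "images").glob("*.png")}
    orphans = sorted(on_disk - listed)
    if orphans:
        raise DatasetError(f"image files lack manifest rows: {orphans[:5]}")
    images = []
    for r in rows:
        img_path = directory / r["image_path"]
        if not img_path.exists():
            raise DatasetError(f"missing image file {img_path}")
        pixels = np.asarray(Image.open(img_path), dtype=float) / 255.0
        mask = None
        if r.get("mask_path"):
            mask_path = directory / r["mask_path"]
            if not mask_path.exists():
                raise DatasetError(f"missing mask file {mask_path}")
            mask = np.asarray(Image.open(mask_path)) > 127
            if mask.shape != pixels.shape:
                raise DatasetError(
                    f"mask {mask_path.name} shape {mask.shape} does not match "
                    f"image shape {pixels.shape}")
        images.append(LabeledImage(pixels=pixels, label=int(r["label"]),
                                   mask=mask, sample_id=r["sample_id"]))
    return images
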