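"""Synthetic endomicroscopy-like imagery with per-pixel ground truth.

Two tissue classes on a shared speckled background:

* class 0 ("meningioma-like") — carries dark elliptical blobs, the
  stand-ins for psammoma bodies; the rendered ellipse pixels form the
  ground-truth mask for weakly supervised segmentation scoring.
* class 1 ("GBM-like") — same background plus brighter elongated
  streaks, so the two classes differ in structure rather than in global
  brightness; no clinically maskable structure exists, so its mask is
  empty.

Images are single-channel floats in [0, 1] (endomicroscopy is
monochrome); an option replicates to 3 channels for RGB-expecting
backbones. All randomness flows from the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw

__all__ = ["SynthConfig", "SynthSample", "generate_dataset", "write_dataset",
           "read_dataset", "samples_by_split"]


class ConfigurationError(ValueError):
    """Raised for degenerate generator configurations."""


@dataclass
class SynthConfig:
    """Generator settings; defaults define the toolkit's benchmark conditions."""

    image_size: int = 64
    n_per_class: int = 60
    blob_count_range: tuple[int, int] = (2, 5)
    blob_radius_range: tuple[int, int] = (4, 9)
    texture_noise_sd: float = 0.08
    contrast: float = 0.5
    seed: int = 0
    rgb: bool = False
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.blob_radius_range[0] > self.blob_radius_range[1]:
            raise ConfigurationError("blob_radius_range is empty")
        if self.blob_radius_range[1] >= self.image_size / 2:
            raise ConfigurationError("max blob radius must be < image_size/2")
        if self.blob_count_range[0] > self.blob_count_range[1] \
                or self.blob_count_range[0] < 1:
            raise ConfigurationError("blob_count_range is empty")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if not 0 < self.contrast <= 1:
            raise ConfigurationError("contrast must be in (0, 1]")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


@dataclass
class SynthSample:
    image: np.ndarray          # (H, W) float in [0, 1]
    label: int                 # 0 = blob-bearing, 1 = streak class
    mask: np.ndarray           # (H, W) bool; all-False for label 1
    split: str = "train"
    sample_id: str = ""


def _background(rng: np.random.Generator, size: int, noise_sd: float):
    """Speckled bright background: smoothed uniform noise around 0.65."""
    base = rng.uniform(0.0, 1.0, size=(size, size))
    tex = ndimage.gaussian_filter(base, sigma=1.5)
    tex = (tex - tex.mean()) * 4.0 * noise_sd + 0.65
    return np.clip(tex, 0.0, 1.0)


def _render_blobs(rng: np.random.Generator, size: int, cfg: SynthConfig):
    """Dark non-overlapping ellipses; returns (intensity delta, mask)."""
    lo_n, hi_n = cfg.blob_count_range
    n_blobs = int(rng.integers(lo_n, hi_n + 1))
    lo_r, hi_r = cfg.blob_radius_range
    mask = np.zeros((size, size), dtype=bool)
    placed = 0
    tries = 0
    while placed < n_blobs:
        r_rad = int(rng.integers(lo_r, hi_r + 1))
        c_rad = int(rng.integers(lo_r, hi_r + 1))
        rot = rng.uniform(0, np.pi)
        margin = max(r_rad, c_rad) + 1
        cy = int(rng.integers(margin, size - margin))
        cx = int(rng.integers(margin, size - margin))
        rr, cc = draw.ellipse(cy, cx, r_rad, c_rad, shape=(size, size),
                              rotation=rot)
        tries += 1
        if mask[rr, cc].any() and tries - placed <= 100:
            continue  # reject overlap; give up after 100 extra tries
        mask[rr, cc] = True
        placed += 1
    return mask


def _render_streaks(rng: np.random.Generator, size: int, contrast: float):
    """Bright elongated ridges for the structure-free class."""
    delta = np.zeros((size, size))
    for _ in range(int(rng.integers(2, 5))):
        y0, x0 = rng.integers(4, size - 4, size=2)
        angle = rng.uniform(0, np.pi)
        length = int(rng.integers(size // 3, size))
        y1 = int(np.clip(y0 + length * np.sin(angle), 0, size - 1))
        x1 = int(np.clip(x0 + length * np.cos(angle), 0, size - 1))
        rr, cc = draw.line(int(y0), int(x0), y1, x1)
        line = np.zeros((size, size))
        line[rr, cc] = 1.0
        delta += ndimage.gaussian_filter(line, sigma=1.2)
    if delta.max() > 0:
        delta = delta / delta.max()
    return delta * contrast * 0.6


def _make_sample(rng: np.random.Generator, label: int, cfg: SynthConfig):
    size = cfg.image_size
    img = _background(rng, size, cfg.texture_noise_sd)
    if label == 0:
        mask = _render_blobs(rng, size, cfg)
        img = img - cfg.contrast * mask
    else:
        mask = np.zeros((size, size), dtype=bool)
        img = img + _render_streaks(rng, size, cfg.contrast)
    return SynthSample(image=np.clip(img, 0.0, 1.0), label=label, mask=mask)


def _assign_splits(n: int, fractions, rng: np.random.Generator):
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    names = (["train"] * n_train + ["val"] * n_val
             + ["test"] * (n - n_train - n_val))
    order = rng.permutation(n)
    out = [""] * n
    for pos, idx in enumerate(order):
        out[idx] = names[pos]
    return out


def generate_dataset(config: SynthConfig) -> list[SynthSample]:
    """Generate the two-class dataset with stratified train/val/test splits.

    Deterministic given the config (including seed). Splits are assigned
    per class so both classes appear in every split in equal numbers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[SynthSample] = []
    for label in (0, 1):
        cls = [_make_sample(rng, label, config)
               for _ in range(config.n_per_class)]
        splits = _assign_splits(config.n_per_class, config.split_fractions, rng)
        for i, (s, sp) in enumerate(zip(cls, splits)):
            s.split = sp
            s.sample_id = f"c{label}_{i:04d}"
        samples.extend(cls)
    return samples


def samples_by_split(samples: list[SynthSample], split: str):
    return [s for s in samples if s.split == split]


def as_arrays(samples: list[SynthSample], rgb: bool = False):
    """Stack samples into ``(X, y)`` with X shaped ``(n, C, H, W)``."""
    x = np.stack([s.image for s in samples])[:, None]
    if rgb:
        x = np.repeat(x, 3, axis=1)
    y = np.array([s.label for s in samples], dtype=int)
    return x, y


def write_dataset(samples: list[SynthSample], out_dir) -> Path:
    """Write 8-bit PNG images/masks and a CSV manifest; returns manifest path."""
    import imageio.v3 as iio

    if not samples:
        raise ValueError("no samples to write")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "path", "mask_path", "label", "split"])
        for s in samples:
            img_rel = f"images/{s.sample_id}.png"
            iio.imwrite(out / img_rel,
                        np.round(s.image * 255).astype(np.uint8))
            mask_rel = ""
            if s.label == 0:
                mask_rel = f"masks/{s.sample_id}.png"
                iio.imwrite(out / mask_rel,
                            (s.mask.astype(np.uint8) * 255))
            wr.writerow([s.sample_id, img_rel, mask_rel, s.label, s.split])
    return manifest


def read_dataset(manifest_path) -> list[SynthSample]:
    """Load a written dataset back into memory."""
    import imageio.v3 as iio

    root = Path(manifest_path).parent
    samples = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            img = iio.imread(root / row["path"]).astype(float) / 255.0
            if img.ndim == 3:
                img = img[..., 0]
            if row["mask_path"]:
                mask = iio.imread(root / row["mask_path"]) > 127
            else:
                mask = np.zeros(img.shape, dtype=bool)
            samples.append(SynthSample(image=img, label=int(row["label"]),
                                       mask=mask, split=row["split"],
                                       sample_id=row["id"]))
    return samples
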