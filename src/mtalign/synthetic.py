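"""Ground-truthed synthetic drift stacks for validating the registration.

The generator emulates the drift observed in sequential multi-tag
acquisition runs: a single textured source image stands in for the fixed
specimen, and each synthetic tag image is a crop whose centre is displaced
from the source centre by a uniform real-valued shift in
[-shift_range, +shift_range]^2 (default 10 px, sampled sub-pixel via Keys
bicubic interpolation).  To mimic acquisition-time intensity perturbations,
about a quarter of the images receive a gamma-correction contrast change
(gamma uniform in [0.5, 2]), a disjoint quarter receive Gaussian blur
(sigma = 1 px, 5x5 kernel), and the remaining half are only translated.
The true shifts and corruption labels are recorded so estimated
translations can be scored against ground truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack, TagImagePair, Translation, bicubic_shift, write_stack

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_base_image",
    "central_crop",
    "generate_stack",
    "score_registration",
    "write_synthetic_stack",
]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic drift experiment.

    Defaults follow the drift regime used throughout the package: 500
    images, uniform shifts within +-10 px, a 0.25/0.25/0.50 split of
    gamma-corrupted / blurred / untouched images, and a crop large enough
    to host the default 3x3 layout of 240-px search windows.
    """

    n_images: int = 500
    shift_range: float = 10.0
    crop_size: tuple[int, int] = (768, 768)
    frac_gamma: float = 0.25
    gamma_range: tuple[float, float] = (0.5, 2.0)
    frac_blur: float = 0.25
    blur_sigma: float = 1.0
    blur_kernel: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("need at least 2 synthetic images")
        if self.shift_range < 0:
            raise ValueError("shift_range must be non-negative")
        if self.frac_gamma + self.frac_blur > 1.0 + 1e-12:
            raise ValueError("corruption fractions must sum to at most 1")
        if self.blur_kernel % 2 != 1:
            raise ValueError("blur kernel size must be odd")


@dataclass
class SyntheticTruth:
    """Per-image ground truth: true shift (x, y) and corruption label."""

    true_shifts: np.ndarray
    corruption: list[str] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tag": self.tags,
            "true_dx": self.true_shifts[:, 0],
            "true_dy": self.true_shifts[:, 1],
            "corruption": self.corruption,
        })

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SyntheticTruth":
        df = pd.read_csv(path)
        return cls(true_shifts=df[["true_dx", "true_dy"]].to_numpy(dtype=float),
                   corruption=[str(c) for c in df["corruption"]],
                   tags=[str(t) for t in df["tag"]])


def make_base_image(h: int, w: int, seed: int = 0) -> np.ndarray:
    """Deterministic band-limited texture standing in for a phase image.

    Smoothed white noise at a cell-scale (sigma 8 px) and a granular
    (sigma 1.5 px) band, mixed and min-max scaled to [0, 255].  The result
    has a well-spread histogram (entropy comfortably above 3 bits at 64
    bins), which the MI criterion needs to lock on to.
    """
    rng = np.random.default_rng(seed)
    coarse = ndimage.gaussian_filter(rng.normal(size=(h, w)), 8.0)
    fine = ndimage.gaussian_filter(rng.normal(size=(h, w)), 1.5)

    def standardize(a: np.ndarray) -> np.ndarray:
        return (a - a.mean()) / a.std()

    img = 0.6 * standardize(coarse) + 0.4 * standardize(fine)
    img -= img.min()
    img *= 255.0 / img.max()
    return img


def _crop_box(base_shape: tuple[int, int], cfg: SyntheticConfig) -> tuple[int, int]:
    """Top-left corner of the centred crop; raises if shifts cannot fit."""
    hb, wb = base_shape
    hc, wc = cfg.crop_size
    oy, ox = (hb - hc) // 2, (wb - wc) // 2
    headroom = math.ceil(cfg.shift_range) + 2  # +2 px of bicubic support
    if min(oy, ox, hb - hc - oy, wb - wc - ox) < headroom:
        raise ValueError(
            f"crop {cfg.crop_size} with shift range {cfg.shift_range} does not "
            f"fit in a {base_shape} base image"
        )
    return oy, ox


def central_crop(base: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """The unshifted, uncorrupted crop at the base-image centre."""
    oy, ox = _crop_box(base.shape, cfg)
    hc, wc = cfg.crop_size
    return np.asarray(base, dtype=float)[oy:oy + hc, ox:ox + wc].copy()


def _apply_gamma(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law contrast change on intensities normalised to [0, 1]."""
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return img.copy()
    return lo + (hi - lo) * ((img - lo) / (hi - lo)) ** gamma


def generate_stack(base: np.ndarray, cfg: SyntheticConfig,
                   ) -> tuple[ImageStack, SyntheticTruth]:
    """Generate a ground-truthed synthetic stack from a base image.

    Image j is the crop of ``base`` centred at (center + x_j, center + y_j)
    with (x_j, y_j) drawn uniformly from [-shift_range, +shift_range]^2;
    aligning image j back onto the central crop therefore requires exactly
    the translation (x_j, y_j).  Corruption subsets are drawn without
    replacement and disjoint.  Fully reproducible from ``cfg.seed``.
    """
    base = np.asarray(base, dtype=float)
    oy, ox = _crop_box(base.shape, cfg)
    hc, wc = cfg.crop_size
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_images
    shifts = rng.uniform(-cfg.shift_range, cfg.shift_range, size=(n, 2))
    n_gamma = round(n * cfg.frac_gamma)
    n_blur = round(n * cfg.frac_blur)
    perm = rng.permutation(n)
    gamma_idx = set(perm[:n_gamma].tolist())
    blur_idx = set(perm[n_gamma:n_gamma + n_blur].tolist())
    gammas = rng.uniform(*cfg.gamma_range, size=n)

    pairs: list[TagImagePair] = []
    labels: list[str] = []
    tags: list[str] = []
    digits = len(str(n))
    truncate = (cfg.blur_kernel // 2) / cfg.blur_sigma
    for j in range(n):
        x_j, y_j = shifts[j]
        moved = bicubic_shift(base, -x_j, -y_j)
        crop = moved[oy:oy + hc, ox:ox + wc]
        if j in gamma_idx:
            g = float(gammas[j])
            crop = _apply_gamma(crop, g)
            labels.append(f"gamma({g:.4f})")
        elif j in blur_idx:
            crop = ndimage.gaussian_filter(crop, cfg.blur_sigma, truncate=truncate)
            labels.append("blur")
        else:
            crop = crop.copy()
            labels.append("none")
        tag = f"syn_{j + 1:0{digits}d}"
        tags.append(tag)
        pairs.append(TagImagePair(tag_name=tag, phase=crop, fluorescence=crop.copy(),
                                  index=j + 1, source_dtype=np.dtype(np.uint16)))
    stack = ImageStack(pairs=pairs)
    truth = SyntheticTruth(true_shifts=shifts, corruption=labels, tags=tags)
    return stack, truth


def score_registration(truth: SyntheticTruth, estimated: np.ndarray,
                       ) -> tuple[float, float, float, float]:
    """Per-axis accuracy of estimated shifts against ground truth.

    Returns (mean |err_x|, mean |err_y|, sd of err_x, sd of err_y) in px,
    with err = estimated - true and sample (ddof=1) standard deviations.
    """
    estimated = np.asarray(estimated, dtype=float)
    if estimated.shape != truth.true_shifts.shape:
        raise ValueError(
            f"estimated shifts {estimated.shape} do not match truth "
            f"{truth.true_shifts.shape}"
        )
    err = estimated - truth.true_shifts
    mae = np.abs(err).mean(axis=0)
    sd = err.std(axis=0, ddof=1) if err.shape[0] > 1 else np.zeros(2)
    return float(mae[0]), float(mae[1]), float(sd[0]), float(sd[1])


def write_synthetic_stack(stack: ImageStack, truth: SyntheticTruth,
                          out_dir: str | os.PathLike) -> tuple[Path, Path]:
    """Write images + manifest (readable by read_stack) and the truth CSV."""
    out_dir = Path(out_dir)
    manifest = write_stack(stack, out_dir)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path)
    return manifest, truth_path
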