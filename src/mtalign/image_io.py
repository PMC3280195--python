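"""Image-stack I/O, translation resampling and composite diagnostics.

A stack is a sequence of tag acquisitions; each tag contributes a
phase-contrast image (used for registration, because its content does not
depend on the tag) and a fluorescence image (which receives the translation
estimated from the phase images).

Coordinate convention (used package-wide): origin at the top-left corner,
``x`` is the column index increasing rightward, ``y`` the row index
increasing downward.  A :class:`Translation` ``t`` applied to an image moves
its content by ``(t.dx, t.dy)``: ``out[y, x] = img[y - t.dy, x - t.dx]``.
The translation returned by registration is the one applied to the *target*
image so that it aligns with the reference.  Pixels with no source data are
filled with 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

__all__ = [
    "Translation",
    "TagImagePair",
    "ImageStack",
    "BoundingBox",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "apply_translation",
    "rgb_composite",
    "rms_channel_difference",
    "mosaic_extent",
    "intersection_extent",
    "intersection_slices",
]


@dataclass(frozen=True)
class Translation:
    """A rigid 2-D shift in pixels (real-valued; sub-pixel allowed)."""

    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("translation components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    def __neg__(self) -> "Translation":
        return Translation(-self.dx, -self.dy)

    def __add__(self, other: "Translation") -> "Translation":
        return Translation(self.dx + other.dx, self.dy + other.dy)

    def __sub__(self, other: "Translation") -> "Translation":
        return Translation(self.dx - other.dx, self.dy - other.dy)

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)


@dataclass
class TagImagePair:
    """One tag's phase-contrast and fluorescence image plus metadata."""

    tag_name: str
    phase: np.ndarray
    fluorescence: np.ndarray
    index: int = 0
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.phase.ndim != 2 or self.fluorescence.ndim != 2:
            raise ValueError(f"tag {self.tag_name!r}: images must be 2-D grey arrays")
        if self.phase.shape != self.fluorescence.shape:
            raise ValueError(
                f"tag {self.tag_name!r}: phase {self.phase.shape} and fluorescence "
                f"{self.fluorescence.shape} dimensions differ"
            )
        if 0 in self.phase.shape:
            raise ValueError(f"tag {self.tag_name!r}: empty image")
        if not (np.isfinite(self.phase).all() and np.isfinite(self.fluorescence).all()):
            raise ValueError(f"tag {self.tag_name!r}: non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class ImageStack:
    """An ordered stack of tag image pairs sharing a common frame (h, w)."""

    pairs: list[TagImagePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError(f"a stack needs at least 2 tag images, got {len(self.pairs)}")
        h, w = self.pairs[0].shape
        for p in self.pairs:
            if p.shape != (h, w):
                raise ValueError(
                    f"tag {p.tag_name!r} has shape {p.shape}, expected {(h, w)}"
                )
        names = [p.tag_name for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("tag names must be unique")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pairs[0].shape

    @property
    def tags(self) -> list[str]:
        return [p.tag_name for p in self.pairs]

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i: int) -> TagImagePair:
        return self.pairs[i]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner (x0, y0), width and height in px."""

    x0: float
    y0: float
    width: float
    height: float


# ---------------------------------------------------------------------------
# Raster I/O


def read_image(path: str | os.PathLike) -> tuple[np.ndarray, np.dtype]:
    """Read a single-channel raster (TIFF or PNG) as a float array.

    Returns the image promoted to float64 together with the on-disk dtype so
    callers can round-trip the original bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected a single-channel grey image, got shape {arr.shape}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr.astype(float), arr.dtype


def write_image(path: str | os.PathLike, image: np.ndarray, dtype: np.dtype | None = None) -> None:
    """Write a grey or RGB image, clipping/casting to the requested dtype."""
    path = Path(path)
    arr = np.asarray(image)
    if dtype is not None:
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)


def _manifest_rows(manifest_path: Path) -> list[dict]:
    suffix = manifest_path.suffix.lower()
    if suffix in (".yml", ".yaml"):
        with open(manifest_path) as fh:
            doc = yaml.safe_load(fh)
        rows = doc["tags"] if isinstance(doc, dict) and "tags" in doc else doc
        if not isinstance(rows, list):
            raise ValueError(f"{manifest_path}: YAML manifest must be a list of tag entries")
        return [dict(r) for r in rows]
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(manifest_path, sep=sep)
    required = {"tag", "phase_path", "fluor_path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{manifest_path}: manifest needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return df.to_dict("records")


def read_stack(manifest_path: str | os.PathLike) -> ImageStack:
    """Load an image stack from a manifest.

    The manifest is a CSV/TSV file with columns ``tag, phase_path, fluor_path``
    (or a YAML list of mappings with the same keys); relative paths are
    resolved against the manifest's directory.  Order is preserved.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(str(manifest_path))
    rows = _manifest_rows(manifest_path)
    base = manifest_path.parent
    pairs: list[TagImagePair] = []
    for j, row in enumerate(rows):
        tag = str(row["tag"])
        try:
            phase, dtype = read_image(base / str(row["phase_path"]))
            fluor, _ = read_image(base / str(row["fluor_path"]))
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"tag {tag!r}: missing image file {exc}") from exc
        try:
            pairs.append(
                TagImagePair(tag_name=tag, phase=phase, fluorescence=fluor,
                             index=j + 1, source_dtype=dtype)
            )
        except ValueError as exc:
            raise ValueError(f"tag {tag!r}: {exc}") from exc
    if len(pairs) >= 2:
        h, w = pairs[0].shape
        for p in pairs:
            if p.shape != (h, w):
                raise ValueError(
                    f"tag {p.tag_name!r}: image size {p.shape} differs from first tag {(h, w)}"
                )
    return ImageStack(pairs=pairs)


def write_stack(stack: ImageStack, out_dir: str | os.PathLike,
                suffix: str = ".tif") -> Path:
    """Write every image of a stack plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in stack:
        phase_name = f"{pair.tag_name}_phase{suffix}"
        fluor_name = f"{pair.tag_name}_fluor{suffix}"
        dtype = pair.source_dtype or np.dtype(np.uint16)
        write_image(out_dir / phase_name, pair.phase, dtype=dtype)
        write_image(out_dir / fluor_name, pair.fluorescence, dtype=dtype)
        rows.append({"tag": pair.tag_name, "phase_path": phase_name, "fluor_path": fluor_name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Translation resampling (Keys cubic convolution)

_KEYS_A = -0.5  # Catmull-Rom member of the Keys cubic family


def _keys_weights(u: float) -> np.ndarray:
    """4-tap cubic-convolution weights for fractional offset u in [0, 1).

    Taps cover source offsets {-1, 0, 1, 2} relative to floor(s); weight for
    tap j is k(u - j) with k the Keys kernel (a = -0.5), which interpolates
    and reproduces linear ramps exactly.
    """
    a = _KEYS_A

    def k(t: float) -> float:
        t = abs(t)
        if t <= 1.0:
            return (a + 2.0) * t**3 - (a + 3.0) * t**2 + 1.0
        if t < 2.0:
            return a * t**3 - 5.0 * a * t**2 + 8.0 * a * t - 4.0 * a
        return 0.0

    return np.array([k(u + 1.0), k(u), k(u - 1.0), k(u - 2.0)])


def _int_shift(img: np.ndarray, iy: int, ix: int) -> np.ndarray:
    """Exact integer relocation with zero fill outside the source footprint."""
    h, w = img.shape
    out = np.zeros_like(img)
    if abs(iy) >= h or abs(ix) >= w:
        return out
    ys_dst = slice(max(iy, 0), h + min(iy, 0))
    xs_dst = slice(max(ix, 0), w + min(ix, 0))
    ys_src = slice(max(-iy, 0), h - max(iy, 0))
    xs_src = slice(max(-ix, 0), w - max(ix, 0))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def _split_shift(d: float) -> tuple[int, float]:
    i = int(np.floor(d))
    return i, d - i


def bicubic_shift(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift image content by (dx, dy) using Keys cubic convolution.

    Separable: a 4-tap correlation per axis (edge replication) realises the
    fractional part, then an exact integer relocation with zero fill.  The
    fractional resampling touches at most 2 px of replicated edge, which ends
    up outside the valid footprint for any |shift| >= 1.
    """
    ix, fx = _split_shift(dx)
    iy, fy = _split_shift(dy)
    out = np.asarray(img, dtype=float)
    # correlate1d tap offsets are m - 2 - origin for m in 0..3; origin=-1
    # puts them at {-1, 0, 1, 2} as required by the kernel derivation.
    if fx > 0.0:
        out = ndimage.correlate1d(out, _keys_weights(1.0 - fx), axis=1,
                                  mode="nearest", origin=-1)
        ix += 1
    if fy > 0.0:
        out = ndimage.correlate1d(out, _keys_weights(1.0 - fy), axis=0,
                                  mode="nearest", origin=-1)
        iy += 1
    return _int_shift(out, iy, ix)


def apply_translation(image: np.ndarray, t: Translation,
                      interpolation: str = "bicubic") -> np.ndarray:
    """Apply a translation to an image: ``out[y, x] = image[y - dy, x - dx]``.

    ``interpolation`` is ``"bicubic"`` (Keys cubic convolution; sub-pixel) or
    ``"nearest"`` (shift rounded to whole pixels; exact relocation).  Pixels
    whose source falls outside the image are 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grey image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if interpolation == "nearest":
        return _int_shift(img, int(np.rint(t.dy)), int(np.rint(t.dx)))
    if interpolation != "bicubic":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return bicubic_shift(img, t.dx, t.dy)


# ---------------------------------------------------------------------------
# Composites and diagnostics


def rgb_composite(imgs: Sequence[np.ndarray]) -> np.ndarray:
    """Stack three grey images into an RGB composite.

    Each channel is min-max scaled to [0, 1] independently (a constant
    channel maps to 0).  Misalignment between the channels shows up as
    colour fringes; a perfectly aligned triple of identical images renders
    as shades of grey.
    """
    if len(imgs) != 3:
        raise ValueError("rgb_composite needs exactly 3 grey images")
    arrs = [np.asarray(im, dtype=float) for im in imgs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("channel dimensions differ")
    chans = []
    for a in arrs:
        lo, hi = a.min(), a.max()
        chans.append((a - lo) / (hi - lo) if hi > lo else np.zeros_like(a))
    return np.stack(chans, axis=-1)


def rms_channel_difference(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square pairwise difference between three channel images.

    Averages the squared differences of the three channel pairs (R-G, G-B,
    B-R) over all B pixels:  sqrt( (1/(3B)) * sum[(R-G)^2+(G-B)^2+(B-R)^2] ).
    Zero iff the three channels are identical; invariant under permutation
    of the channels.  Used before/after alignment as a misalignment score.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (r.shape == g.shape == b.shape):
        raise ValueError("channel dimensions differ")
    if r.size == 0:
        raise ValueError("empty images")
    sq = (r - g) ** 2 + (g - b) ** 2 + (b - r) ** 2
    return float(np.sqrt(sq.mean() / 3.0))


def mosaic_extent(stack_dims: tuple[int, int],
                  translations: Iterable[Translation]) -> BoundingBox:
    """Minimal axis-aligned frame containing all translated image footprints.

    Image ``j`` translated by ``t_j`` occupies the rectangle with top-left
    corner ``(t_j.dx, t_j.dy)`` and size ``(w, h)``; the reference image has
    translation (0, 0).  The returned frame is the mosaic canvas that holds
    every aligned image.
    """
    h, w = stack_dims
    ts = list(translations)
    if not ts:
        raise ValueError("need at least one translation")
    x0 = min(t.dx for t in ts)
    y0 = min(t.dy for t in ts)
    x1 = max(t.dx for t in ts) + w
    y1 = max(t.dy for t in ts) + h
    return BoundingBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)


def intersection_extent(stack_dims: tuple[int, int],
                        translations: Iterable[Translation]) -> BoundingBox:
    """Largest frame covered by *every* translated image footprint.

    The counterpart of :func:`mosaic_extent`: the region where all aligned
    images carry genuine signal (no blank fill).  Raises if the footprints
    have no common area.
    """
    h, w = stack_dims
    ts = list(translations)
    if not ts:
        raise ValueError("need at least one translation")
    x0 = max(t.dx for t in ts)
    y0 = max(t.dy for t in ts)
    x1 = min(t.dx for t in ts) + w
    y1 = min(t.dy for t in ts) + h
    if x1 <= x0 or y1 <= y0:
        raise ValueError("translated footprints share no common region")
    return BoundingBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)


def intersection_slices(stack_dims: tuple[int, int],
                        translations: Iterable[Translation],
                        guard: int = 2) -> tuple[slice, slice]:
    """Integer row/column slices of the common footprint, shrunk by ``guard``
    pixels to keep resampling edge effects out of any comparison."""
    box = intersection_extent(stack_dims, translations)
    y0 = int(np.ceil(box.y0)) + guard
    y1 = int(np.floor(box.y0 + box.height)) - guard
    x0 = int(np.ceil(box.x0)) + guard
    x1 = int(np.floor(box.x0 + box.width)) - guard
    if y1 <= y0 or x1 <= x0:
        raise ValueError("common footprint too small for the requested guard")
    return slice(y0, y1), slice(x0, x1)
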