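"""Registration graph completion and reference-image selection.

Registering the N stack images to one arbitrary reference r yields N-1
translations.  Because all transforms are translations, the shift between
any pair (j, k) follows by vector composition,

    Delta_jk = Delta_rk - Delta_rj,

so two N-by-N matrices (x and y components) describe every pairwise shift.
They are skew-symmetric with zero diagonal, and path-independent by
construction — no further registrations are needed.

The Reference Image with Maximal Overlap (RIMO) is the candidate reference
r* minimising the total symmetric-difference distance to all other images,

    r* = argmin_r  sum_j d(C_r, C_j),

with d the non-overlap area of two translated h-by-w frames (closed form in
:mod:`mtalign.shift_metric`; the scaled l1 approximation is available as
``mode="l1"``).  Realigning the whole stack to the RIMO reuses row r* of the
completed matrices, so the core registration never has to run again.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import ImageStack, TagImagePair, Translation, apply_translation
from .shift_metric import shift_distance

__all__ = [
    "ShiftMatrices",
    "RimoResult",
    "build_shift_matrices",
    "rimo_objective",
    "select_rimo",
    "realign_stack",
]


@dataclass
class ShiftMatrices:
    """Completed N x N pairwise shift matrices (x and y components).

    Entry ``[j, k]`` is the translation component applied to image k to
    align it with image j.
    """

    dx: np.ndarray
    dy: np.ndarray
    ref_index: int
    tags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.dx.shape[0]

    def translation(self, j: int, k: int) -> Translation:
        """Translation aligning image k to image j."""
        return Translation(float(self.dx[j, k]), float(self.dy[j, k]))

    def to_csv(self, prefix: str | os.PathLike) -> tuple[Path, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tags = self.tags or [str(i) for i in range(self.n)]
        paths = (prefix.with_name(prefix.name + "_dx.csv"),
                 prefix.with_name(prefix.name + "_dy.csv"))
        for mat, path in zip((self.dx, self.dy), paths):
            pd.DataFrame(mat, index=tags, columns=tags).to_csv(path)
        return paths

    @classmethod
    def from_csv(cls, prefix: str | os.PathLike, ref_index: int = 0) -> "ShiftMatrices":
        prefix = Path(prefix)
        frames = []
        for suffix in ("_dx.csv", "_dy.csv"):
            path = prefix.with_name(prefix.name + suffix)
            if not path.exists():
                raise FileNotFoundError(str(path))
            frames.append(pd.read_csv(path, index_col=0))
        dx, dy = (f.to_numpy(dtype=float) for f in frames)
        if dx.shape != dy.shape or dx.shape[0] != dx.shape[1]:
            raise ValueError("malformed shift-matrix files")
        return cls(dx=dx, dy=dy, ref_index=ref_index,
                   tags=[str(t) for t in frames[0].index])


@dataclass
class RimoResult:
    """Reference selection outcome for one stack."""

    objective: np.ndarray
    rimo_index: int
    per_image_shift_magnitude: np.ndarray
    loss_percent: np.ndarray
    frame_loss_percent: np.ndarray
    flagged_distant: list[int]
    tags: list[str] = field(default_factory=list)
    mode: str = "exact"

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "rimo_index": int(self.rimo_index),
            "rimo_tag": self.tags[self.rimo_index] if self.tags else str(self.rimo_index),
            "mode": self.mode,
            "objective": self.objective.tolist(),
            "per_image_shift_magnitude": self.per_image_shift_magnitude.tolist(),
            "loss_percent": self.loss_percent.tolist(),
            "frame_loss_percent": self.frame_loss_percent.tolist(),
            "flagged_distant": self.flagged_distant,
            "tags": self.tags,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def build_shift_matrices(base: list[Translation], r: int,
                         tags: list[str] | None = None) -> ShiftMatrices:
    """Complete the pairwise shift matrices from N-1 base registrations.

    ``base`` holds, in stack order with image r skipped, the translations
    aligning each non-reference image to reference r.  The upper triangle is
    filled by the composition rule Delta_jk = Delta_rk - Delta_rj and the
    lower triangle is its negated reflection, so skew-symmetry is exact.
    """
    n = len(base) + 1
    if not 0 <= r < n:
        raise ValueError(f"reference index {r} out of range for N={n}")
    if tags is not None and len(tags) != n:
        raise ValueError(f"expected {n} tags, got {len(tags)}")
    to_ref = np.zeros((n, 2))
    others = [j for j in range(n) if j != r]
    for j, t in zip(others, base):
        to_ref[j] = (t.dx, t.dy)
    mats = []
    for c in range(2):
        row = to_ref[:, c]
        upper = np.triu(row[None, :] - row[:, None], k=1)
        mats.append(upper - upper.T)
    return ShiftMatrices(dx=mats[0], dy=mats[1], ref_index=r,
                         tags=list(tags) if tags else [])


def rimo_objective(mats: ShiftMatrices, h: int, w: int,
                   mode: str = "exact") -> np.ndarray:
    """Total non-overlap distance from each candidate reference to the rest.

    ``mode="exact"`` uses the closed-form symmetric-difference area
    (disjoint frames contribute 2*h*w); ``mode="l1"`` drops the cross term.
    """
    adx, ady = np.abs(mats.dx), np.abs(mats.dy)
    if mode == "exact":
        d = 2.0 * (h * adx + w * ady - adx * ady)
        d[(adx >= w) | (ady >= h)] = 2.0 * h * w
    elif mode == "l1":
        d = 2.0 * (h * adx + w * ady)
    else:
        raise ValueError(f"unknown objective mode {mode!r}")
    return d.sum(axis=1)


def select_rimo(mats: ShiftMatrices, h: int, w: int, mode: str = "exact",
                distant_threshold: float = 10.0) -> RimoResult:
    """Pick the reference image with maximal overlap.

    Minimises the summed shift-metric distance over candidate references
    (ties broken by smallest index).  Also reports, for the chosen r*: the
    per-image shift magnitudes, the per-image loss as a percentage of the
    worst case 2*h*w, the percentage of frame area lost to non-overlap, and
    the images whose shift magnitude exceeds ``distant_threshold`` px
    (candidates to set aside as too distant from the reference).
    """
    objective = rimo_objective(mats, h, w, mode=mode)
    r_star = int(np.argmin(objective))  # argmin takes the first minimum
    dxr, dyr = mats.dx[r_star], mats.dy[r_star]
    magnitude = np.hypot(dxr, dyr)
    adx, ady = np.abs(dxr), np.abs(dyr)
    d = 2.0 * (h * adx + w * ady - adx * ady)
    d[(adx >= w) | (ady >= h)] = 2.0 * h * w
    loss_percent = 100.0 * d / (2.0 * h * w)
    overlap = np.clip(w - adx, 0, None) * np.clip(h - ady, 0, None)
    frame_loss_percent = 100.0 * (1.0 - overlap / (h * w))
    flagged = np.nonzero(magnitude > distant_threshold)[0].tolist()
    return RimoResult(objective=objective, rimo_index=r_star,
                      per_image_shift_magnitude=magnitude,
                      loss_percent=loss_percent,
                      frame_loss_percent=frame_loss_percent,
                      flagged_distant=flagged, tags=list(mats.tags), mode=mode)


def realign_stack(stack: ImageStack, mats: ShiftMatrices, rimo_index: int,
                  interpolation: str = "bicubic",
                  ) -> tuple[ImageStack, list[Translation]]:
    """Apply row ``rimo_index`` of the shift matrices to the whole stack.

    Both phase and fluorescence images of every tag receive the translation
    aligning them to the chosen reference; the reference image itself is
    untouched (its translation is exactly zero).
    """
    if stack.n != mats.n:
        raise ValueError(f"stack has {stack.n} images but matrices are {mats.n}x{mats.n}")
    applied: list[Translation] = []
    pairs: list[TagImagePair] = []
    for j, pair in enumerate(stack):
        t = mats.translation(rimo_index, j)
        applied.append(t)
        if j == rimo_index:
            pairs.append(TagImagePair(pair.tag_name, pair.phase.copy(),
                                      pair.fluorescence.copy(), index=pair.index,
                                      source_dtype=pair.source_dtype))
        else:
            pairs.append(TagImagePair(
                pair.tag_name,
                apply_translation(pair.phase, t, interpolation),
                apply_translation(pair.fluorescence, t, interpolation),
                index=pair.index, source_dtype=pair.source_dtype))
    return ImageStack(pairs=pairs), applied
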