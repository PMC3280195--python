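"""Mutual information between image pairs and a pattern-search maximiser.

Registration quality is scored by the mutual information (MI) of the joint
intensity histogram of the overlapping region of a reference image and a
translated target image,

    MI(A, B) = H(A) + H(B) - H(A, B),

where H denotes entropy of the (marginal or joint) binned intensity
distribution.  At correct alignment the joint histogram sharpens towards a
diagonal and MI peaks.  The translation is found with a derivative-free
compass pattern search: poll one mesh step along each axis, move and expand
the mesh on improvement, contract it otherwise, and stop once the step
between consecutive accepted points (the mesh size) falls below a threshold
``theta_dtau``.  Sub-pixel candidates are evaluated with Keys bicubic
resampling of the target.

Entropy is Shannon in bits by default; Hartley entropy (log2 of the number
of occupied bins) is available via ``measure="hartley"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_io import Translation, bicubic_shift

__all__ = [
    "JointHistogram",
    "PatternSearchConfig",
    "PatternSearchResult",
    "joint_histogram",
    "entropy",
    "mutual_information",
    "pattern_search_maximize",
    "pattern_search_register",
]

DEFAULT_BINS = 64


@dataclass
class JointHistogram:
    """2-D histogram of co-located intensity pairs of two equal-size images."""

    counts: np.ndarray
    nb: int

    @property
    def marginal_a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class PatternSearchConfig:
    """Tuning knobs of the compass pattern search (all lengths in pixels)."""

    theta_dtau: float = 0.01
    initial_mesh: float = 4.0
    max_iter: int = 200
    expand_factor: float = 2.0
    contract_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.theta_dtau <= 0:
            raise ValueError("theta_dtau must be positive")
        if not (0 < self.contract_factor < 1 < self.expand_factor):
            raise ValueError("need 0 < contract_factor < 1 < expand_factor")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.initial_mesh <= 0:
            raise ValueError("initial_mesh must be positive")


@dataclass
class PatternSearchResult:
    translation: Translation
    score: float
    converged: bool
    n_evals: int
    trace: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Histograms and entropy


def _bin_indices(arr: np.ndarray, nb: int) -> np.ndarray:
    """Linear binning of an array's own intensity range into nb bins.

    A constant array lands entirely in bin 0 (degenerate but valid)."""
    flat = np.ascontiguousarray(arr, dtype=float).ravel()
    lo = flat.min()
    span = flat.max() - lo
    if span == 0.0:
        return np.zeros(flat.size, dtype=np.int64)
    idx = ((flat - lo) * (nb / span)).astype(np.int64)
    np.clip(idx, 0, nb - 1, out=idx)
    return idx


def joint_histogram(a: np.ndarray, b: np.ndarray, nb: int = DEFAULT_BINS) -> JointHistogram:
    """Joint intensity histogram of two images over co-located pixels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    if nb < 2:
        raise ValueError("need at least 2 bins")
    ia = _bin_indices(a, nb)
    ib = _bin_indices(b, nb)
    counts = np.bincount(ia * nb + ib, minlength=nb * nb).reshape(nb, nb)
    return JointHistogram(counts=counts.astype(float), nb=nb)


def entropy(hist: np.ndarray | JointHistogram, measure: str = "shannon") -> float:
    """Entropy of a histogram in bits.

    ``measure="shannon"`` gives the Shannon entropy of the normalised
    counts (with 0*log 0 := 0); ``measure="hartley"`` gives log2 of the
    number of occupied cells.  Both are 0 iff a single cell is occupied.
    """
    counts = hist.counts if isinstance(hist, JointHistogram) else np.asarray(hist, dtype=float)
    if (counts < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    if measure == "hartley":
        return float(np.log2(np.count_nonzero(counts)))
    if measure != "shannon":
        raise ValueError(f"unknown entropy measure {measure!r}")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _mi_from_joint(counts: np.ndarray, measure: str = "shannon") -> float:
    h_a = entropy(counts.sum(axis=1), measure)
    h_b = entropy(counts.sum(axis=0), measure)
    h_ab = entropy(counts, measure)
    return h_a + h_b - h_ab


# ---------------------------------------------------------------------------
# Mutual information under a candidate translation


def _overlap_slices(shape: tuple[int, int], t: Translation,
                    guard: int = 0) -> tuple[slice, slice]:
    """Region of the frame where the target shifted by t has genuine data.

    ``guard`` extra pixels are trimmed on resampled edges to keep bicubic
    boundary effects out of the histogram.
    """
    h, w = shape
    gx = guard if t.dx != int(t.dx) else 0
    gy = guard if t.dy != int(t.dy) else 0
    x0 = max(0, math.ceil(t.dx) + gx)
    x1 = min(w, w + math.floor(t.dx) - gx)
    y0 = max(0, math.ceil(t.dy) + gy)
    y1 = min(h, h + math.floor(t.dy) - gy)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"translation {t} leaves no overlap on a {shape} frame")
    return slice(y0, y1), slice(x0, x1)


def mutual_information(ref: np.ndarray, tgt: np.ndarray,
                       t: Translation = Translation(0.0, 0.0),
                       nb: int = DEFAULT_BINS,
                       measure: str = "shannon") -> float:
    """MI between ``ref`` and ``tgt`` shifted by ``t``, on their overlap only.

    Restricting to the geometric overlap keeps the statistic comparable as
    the intersection changes with ``t``.  Raises if the overlap is empty.
    """
    ref = np.asarray(ref, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError(f"image dimensions differ: {ref.shape} vs {tgt.shape}")
    ys, xs = _overlap_slices(ref.shape, t, guard=2)
    shifted = tgt if (t.dx == 0.0 and t.dy == 0.0) else bicubic_shift(tgt, t.dx, t.dy)
    hist = joint_histogram(ref[ys, xs], shifted[ys, xs], nb)
    return _mi_from_joint(hist.counts, measure)


# ---------------------------------------------------------------------------
# Pattern search

_COMPASS = ((1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0))


def pattern_search_maximize(objective, t0: Translation, cfg: PatternSearchConfig,
                            bounds: float | None = None,
                            keep_trace: bool = True) -> PatternSearchResult:
    """Maximise ``objective(Translation) -> float`` by compass pattern search.

    Polls the four axis neighbours at distance ``mesh`` from the incumbent
    (opportunistic: the first strict improvement is taken).  A successful
    poll moves the incumbent and multiplies the mesh by ``expand_factor``; a
    failed poll multiplies it by ``contract_factor``.  Iteration stops when
    the mesh — the length of any further accepted move — drops below
    ``cfg.theta_dtau``, or after ``cfg.max_iter`` polls (reported as
    ``converged=False``).  ``bounds`` optionally clamps the search to
    max(|dx|, |dy|) <= bounds; out-of-bound candidates are skipped.
    Candidates for which the objective raises ``ValueError`` (e.g. empty
    overlap) are likewise skipped.
    """
    t = np.array([t0.dx, t0.dy], dtype=float)
    best = objective(Translation(*t))
    n_evals = 1
    mesh = cfg.initial_mesh
    trace: list[dict] = []
    converged = False
    for it in range(cfg.max_iter):
        if mesh < cfg.theta_dtau:
            converged = True
            break
        moved = False
        for sx, sy in _COMPASS:
            cand = t + mesh * np.array([sx, sy])
            if bounds is not None and np.abs(cand).max() > bounds:
                continue
            try:
                val = objective(Translation(cand[0], cand[1]))
            except ValueError:
                continue
            n_evals += 1
            if val > best:
                t, best, moved = cand, val, True
                break
        mesh *= cfg.expand_factor if moved else cfg.contract_factor
        if keep_trace:
            trace.append({"iteration": it, "dx": float(t[0]), "dy": float(t[1]),
                          "score": float(best), "mesh": float(mesh), "moved": moved})
    return PatternSearchResult(translation=Translation(float(t[0]), float(t[1])),
                               score=float(best), converged=converged,
                               n_evals=n_evals, trace=trace)


def pattern_search_register(ref: np.ndarray, tgt: np.ndarray,
                            cfg: PatternSearchConfig | None = None,
                            t0: Translation = Translation(0.0, 0.0),
                            nb: int = DEFAULT_BINS,
                            measure: str = "shannon",
                            bounds: float | None = None) -> PatternSearchResult:
    """Find the translation of ``tgt`` maximising MI against ``ref``."""
    cfg = cfg or PatternSearchConfig()

    def objective(t: Translation) -> float:
        return mutual_information(ref, tgt, t, nb=nb, measure=measure)

    return pattern_search_maximize(objective, t0, cfg, bounds=bounds)
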