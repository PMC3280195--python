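"""Robust pairwise registration from K independent subimage blocks.

A single whole-frame MI optimisation can be trapped by local maxima, by the
changing size of the image intersection, or by local tissue damage.  Instead
K disjoint square blocks of side S are taken from the reference image and
each is registered, independently, inside a co-located larger window (side
S + 2*margin) of the target image.  The K per-block translations are then
reconciled:

* a block whose translation is farther than ``omega`` pixels from *every*
  other block's translation is an outlier (default omega = 1 px);
* if fewer than K/2 blocks are outliers they are excluded and the consensus
  translation is the mean of the remainder; otherwise no exclusion is
  trusted and the pair is retried;
* the scalar standard deviation of the non-outlier translations around
  their mean is the confidence sigma — large sigma means the pair cannot
  be registered reliably.

If the outlier count reaches K/2 or sigma exceeds ``sigma_threshold`` the
registration is repeated once with a deterministically jittered block
layout; a second failure flags the target as unregistrable/poor quality
while still reporting the best-effort consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_io import Translation, bicubic_shift
from .mi_core import (DEFAULT_BINS, PatternSearchConfig, joint_histogram,
                      _mi_from_joint, pattern_search_maximize)

__all__ = [
    "BlockLayout",
    "BlockRegistrationResult",
    "make_block_layout",
    "register_blocks",
    "detect_outliers",
    "consensus_and_confidence",
    "robust_pairwise_register",
]


@dataclass(frozen=True)
class BlockLayout:
    """Placement of K disjoint search windows (side S + 2*margin) in a frame.

    ``window_origins`` holds the (y, x) top-left corner of each target
    window; the reference block of side S sits centred in its window, at
    ``window_origin + margin``.
    """

    K: int
    S: int
    margin: int
    window_origins: tuple[tuple[int, int], ...]

    @property
    def window_side(self) -> int:
        return self.S + 2 * self.margin

    @property
    def centers(self) -> np.ndarray:
        """Block centres as (y, x) pairs."""
        return np.asarray(self.window_origins, dtype=float) + self.window_side / 2.0

    def block_slices(self, k: int) -> tuple[slice, slice]:
        oy, ox = self.window_origins[k]
        m, s = self.margin, self.S
        return slice(oy + m, oy + m + s), slice(ox + m, ox + m + s)

    def window_slices(self, k: int) -> tuple[slice, slice]:
        oy, ox = self.window_origins[k]
        t = self.window_side
        return slice(oy, oy + t), slice(ox, ox + t)


@dataclass
class BlockRegistrationResult:
    """Outcome of one robust pairwise registration."""

    per_block: list[Translation]
    outliers: set[int]
    consensus: Translation
    confidence_sigma: float
    flagged: bool = False
    retried: bool = False
    block_converged: list[bool] = field(default_factory=list)
    layout: BlockLayout | None = None

    def to_record(self, ref_tag: str = "", tgt_tag: str = "") -> dict:
        """JSON-serialisable per-pair record."""
        return {
            "ref_tag": ref_tag,
            "tgt_tag": tgt_tag,
            "per_block": [[t.dx, t.dy] for t in self.per_block],
            "outliers": sorted(self.outliers),
            "consensus": [self.consensus.dx, self.consensus.dy],
            "sigma": self.confidence_sigma,
            "flagged": self.flagged,
            "retried": self.retried,
            "block_converged": list(self.block_converged),
        }


def make_block_layout(h: int, w: int, K: int, S: int, margin: int,
                      jitter: int = 0) -> BlockLayout:
    """Deterministic near-uniform grid placement of K disjoint windows.

    Windows of side S + 2*margin are laid out row-major on a ceil(sqrt(K))
    grid, spread evenly over the frame with a small slack reserve so that a
    positive ``jitter`` can displace the whole layout diagonally (used for
    retries) while keeping every window inside the image.  ``jitter`` is
    clamped to the available reserve.
    """
    if K < 2:
        raise ValueError("need K >= 2 blocks for pairwise distances")
    if S < 2 or margin < 0:
        raise ValueError("invalid block size or margin")
    T = S + 2 * margin
    g_cols = math.ceil(math.sqrt(K))
    g_rows = math.ceil(K / g_cols)
    slack_y, slack_x = h - g_rows * T, w - g_cols * T
    if slack_y < 0 or slack_x < 0:
        raise ValueError(
            f"cannot place {K} disjoint {T}x{T} windows in a {h}x{w} frame"
        )
    reserve = min(slack_y, slack_x) // 2
    jit = max(0, min(int(jitter), reserve))

    def axis_origins(extent: int, g: int) -> list[int]:
        span = extent - T - reserve
        if g == 1:
            return [jit + span // 2]
        return [jit + round(i * span / (g - 1)) for i in range(g)]

    ys = axis_origins(h, g_rows)
    xs = axis_origins(w, g_cols)
    origins = [(y, x) for y in ys for x in xs][:K]
    # grid spacing guarantees disjointness; assert the invariant anyway
    for i, (yi, xi) in enumerate(origins):
        for yj, xj in origins[:i]:
            if abs(yi - yj) < T and abs(xi - xj) < T:
                raise ValueError("window placement produced overlapping windows")
        if not (0 <= yi <= h - T and 0 <= xi <= w - T):
            raise ValueError("window placement left the image frame")
    return BlockLayout(K=K, S=S, margin=margin, window_origins=tuple(origins))


def register_blocks(ref: np.ndarray, tgt: np.ndarray, layout: BlockLayout,
                    cfg: PatternSearchConfig | None = None,
                    nb: int = DEFAULT_BINS, measure: str = "shannon",
                    ) -> tuple[list[Translation], list[bool]]:
    """Register each reference block inside its target window independently.

    Returns the K translations (in global frame coordinates — block windows
    are co-located, so the block-local optimum is the global shift) and a
    per-block convergence flag from the pattern search.
    """
    ref = np.asarray(ref, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError(f"image dimensions differ: {ref.shape} vs {tgt.shape}")
    cfg = cfg or PatternSearchConfig()
    m, s = layout.margin, layout.S
    # keep the sampled centre patch clear of the window border and of the
    # 2-px bicubic support
    bound = max(1.0, m - 3.0)
    shifts: list[Translation] = []
    converged: list[bool] = []
    for k in range(layout.K):
        block = ref[layout.block_slices(k)]
        win = tgt[layout.window_slices(k)]

        def objective(t: Translation, _win=win, _block=block) -> float:
            shifted = bicubic_shift(_win, t.dx, t.dy)
            patch = shifted[m:m + s, m:m + s]
            return _mi_from_joint(joint_histogram(_block, patch, nb).counts, measure)

        res = pattern_search_maximize(objective, Translation(0.0, 0.0), cfg,
                                      bounds=bound, keep_trace=False)
        shifts.append(res.translation)
        converged.append(res.converged)
    return shifts, converged


def detect_outliers(per_block: list[Translation], omega: float = 1.0) -> set[int]:
    """Blocks whose translation is > omega px from every other block's.

    A block with at least one neighbour within omega is never an outlier,
    so two mutually-distant clusters of agreeing blocks mark nobody.
    """
    if len(per_block) < 2:
        raise ValueError("need at least 2 block translations")
    if omega <= 0:
        raise ValueError("omega must be positive")
    pts = np.array([[t.dx, t.dy] for t in per_block])
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return set(np.nonzero(d.min(axis=1) > omega)[0].tolist())


def consensus_and_confidence(per_block: list[Translation],
                             outliers: set[int] | None = None,
                             ) -> tuple[Translation, float]:
    """Mean translation over non-outlier blocks and its scalar spread.

    sigma is the root-mean-square Euclidean deviation of the non-outlier
    shift vectors from their mean (a single scalar combining x and y);
    sigma = 0 when all non-outliers agree exactly.
    """
    outliers = outliers or set()
    keep = [t for k, t in enumerate(per_block) if k not in outliers]
    if not keep:
        raise ValueError("all blocks are outliers; no consensus possible")
    pts = np.array([[t.dx, t.dy] for t in keep])
    mean = pts.mean(axis=0)
    sigma = float(np.sqrt(((pts - mean) ** 2).sum(axis=1).mean()))
    return Translation(float(mean[0]), float(mean[1])), sigma


def _attempt(ref: np.ndarray, tgt: np.ndarray, layout: BlockLayout,
             cfg: PatternSearchConfig, omega: float, nb: int, measure: str,
             ) -> BlockRegistrationResult:
    shifts, conv = register_blocks(ref, tgt, layout, cfg, nb=nb, measure=measure)
    outliers = detect_outliers(shifts, omega=omega)
    K = layout.K
    if len(outliers) >= K / 2:
        # a majority disagreement cannot be trusted as outlier exclusion:
        # keep every block and let the caller retry/flag on sigma
        effective: set[int] = set()
    else:
        effective = outliers
    consensus, sigma = consensus_and_confidence(shifts, effective)
    return BlockRegistrationResult(per_block=shifts, outliers=outliers,
                                   consensus=consensus, confidence_sigma=sigma,
                                   block_converged=conv, layout=layout)


def robust_pairwise_register(ref: np.ndarray, tgt: np.ndarray,
                             K: int = 9, S: int = 200, margin: int = 20,
                             cfg: PatternSearchConfig | None = None,
                             sigma_threshold: float = 1.0,
                             omega: float = 1.0,
                             nb: int = DEFAULT_BINS,
                             measure: str = "shannon",
                             ) -> BlockRegistrationResult:
    """Full robust registration of one target image to one reference image.

    Runs block registration on the default layout; if at least K/2 blocks
    are outliers or the confidence sigma exceeds ``sigma_threshold``, the
    whole procedure is repeated once with the layout displaced diagonally
    by S/4 px (deterministic).  If the retry also fails the result is
    flagged and the attempt with the smaller sigma is returned.
    """
    ref = np.asarray(ref, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    cfg = cfg or PatternSearchConfig()
    h, w = ref.shape

    def bad(r: BlockRegistrationResult) -> bool:
        return len(r.outliers) >= K / 2 or r.confidence_sigma > sigma_threshold

    layout = make_block_layout(h, w, K, S, margin, jitter=0)
    first = _attempt(ref, tgt, layout, cfg, omega, nb, measure)
    if not bad(first):
        return first
    retry_layout = make_block_layout(h, w, K, S, margin, jitter=S // 4)
    second = _attempt(ref, tgt, retry_layout, cfg, omega, nb, measure)
    second.retried = True
    if not bad(second):
        return second
    best = min((first, second), key=lambda r: r.confidence_sigma)
    best.retried = True
    best.flagged = True
    return best
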