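"""Interest-patch selection: the N highest-protein-expression square windows.

Whole IHC images mix stained glands, unstained stroma and background; only
the stained tissue carries localization information.  Patches are scored by
the mean of a Gaussian low-pass of the protein channel over each candidate
window (candidates on a stride grid), then selected greedily by descending
score with a pairwise area-overlap cap (non-maximum suppression).

Defaults follow the optimum found by grid search over patch count/size for
engineered features (205 patches of 75 px); deep-feature extraction uses a
separate convention of 35 patches of 224 px.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .unmixing import StainChannels

logger = logging.getLogger(__name__)

#: optimal engineered-feature patch parameters (count, side in px)
DEFAULT_N_PATCHES = 205
DEFAULT_PATCH_SIZE = 75
#: deep-feature patch parameters
DEEP_N_PATCHES = 35
DEEP_PATCH_SIZE = 224
DEFAULT_MAX_OVERLAP = 0.25

#: grid-search ranges: counts 25..385 step 20, sizes 45..225 step 30
GRID_COUNTS = tuple(range(25, 386, 20))
GRID_SIZES = tuple(range(45, 226, 30))


@dataclass
class PatchSet:
    """Ordered square patch windows from one image (best score first)."""

    image_ref: str
    size: int
    coords: list[tuple[int, int]]
    scores: list[float]
    protein_windows: list[np.ndarray] = field(default_factory=list)
    dna_windows: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.coords)


def score_windows(protein: np.ndarray, size: int, sigma: float | None = None,
                  stride: int | None = None
                  ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Score candidate windows by mean smoothed protein intensity.

    Returns (scores, coords) over the stride grid (default stride size//2),
    scores[i] belonging to the window whose top-left corner is coords[i].
    """
    protein = np.asarray(protein, dtype=np.float64)
    H, W = protein.shape
    if size > min(H, W):
        raise ValueError(f"patch size {size} exceeds image {protein.shape}")
    if sigma is None:
        sigma = size / 8.0
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if stride is None:
        stride = max(1, size // 2)
    smoothed = ndimage.gaussian_filter(protein, sigma)
    # window means via integral image
    ii = np.zeros((H + 1, W + 1))
    ii[1:, 1:] = smoothed.cumsum(0).cumsum(1)
    rows = list(range(0, H - size + 1, stride))
    cols = list(range(0, W - size + 1, stride))
    if rows[-1] != H - size:
        rows.append(H - size)
    if cols[-1] != W - size:
        cols.append(W - size)
    coords = [(r, c) for r in rows for c in cols]
    r = np.array([rc[0] for rc in coords])
    c = np.array([rc[1] for rc in coords])
    sums = ii[r + size, c + size] - ii[r, c + size] - ii[r + size, c] + ii[r, c]
    scores = sums / (size * size)
    return scores, coords


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int], size: int) -> float:
    """Area-overlap fraction of two size x size windows (relative to one window)."""
    dr = size - abs(a[0] - b[0])
    dc = size - abs(a[1] - b[1])
    if dr <= 0 or dc <= 0:
        return 0.0
    return (dr * dc) / float(size * size)


def select_patches(channels: StainChannels, n: int, size: int,
                   max_overlap: float = DEFAULT_MAX_OVERLAP,
                   sigma: float | None = None, stride: int | None = None,
                   image_ref: str = "") -> PatchSet:
    """Greedy top-N window selection with pairwise overlap suppression.

    Candidates are ranked by descending score with (row, col) lexicographic
    tie-break; a candidate is accepted iff its area-overlap fraction with
    every already-accepted window is <= ``max_overlap``.  Deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= max_overlap < 1.0):
        raise ValueError("max_overlap must be in [0, 1)")
    protein = channels.protein
    if not np.any(protein):
        logger.warning("empty protein channel; patches selected by tie-break order")
    scores, coords = score_windows(protein, size, sigma, stride)
    order = sorted(range(len(coords)), key=lambda i: (-scores[i], coords[i]))
    chosen: list[int] = []
    for i in order:
        if len(chosen) >= n:
            break
        if all(_overlap_fraction(coords[i], coords[j], size) <= max_overlap
               for j in chosen):
            chosen.append(i)
    if len(chosen) < n:
        logger.warning("only %d of %d requested patches available", len(chosen), n)
    sel_coords = [coords[i] for i in chosen]
    sel_scores = [float(scores[i]) for i in chosen]
    pw = [protein[r:r + size, c:c + size].copy() for r, c in sel_coords]
    dw = [channels.dna[r:r + size, c:c + size].copy() for r, c in sel_coords]
    return PatchSet(image_ref=image_ref, size=size, coords=sel_coords,
                    scores=sel_scores, protein_windows=pw, dna_windows=dw)


def patch_grid_search(evaluate, counts=GRID_COUNTS, sizes=GRID_SIZES):
    """Accuracy grid over (n_patches, patch_size) pairs.

    ``evaluate(count, size) -> float`` runs the feature+classifier
    cross-validation for one cell and returns its accuracy; a cell that
    raises is recorded as missing (NaN) and the search continues.  Returns
    (table, best) where ``table`` is a list of (count, size, accuracy) and
    ``best`` the argmax pair with ties to smaller size then smaller count.
    """
    counts = list(counts)
    sizes = list(sizes)
    if not counts or not sizes:
        raise ValueError("grids must be non-empty")
    table = []
    for count in counts:
        for size in sizes:
            try:
                acc = float(evaluate(count, size))
            except Exception as exc:
                logger.warning("grid cell (n=%d, size=%d) failed: %s", count, size, exc)
                acc = float("nan")
            table.append((count, size, acc))
    valid = [t for t in table if np.isfinite(t[2])]
    if not valid:
        raise RuntimeError("every grid cell failed")
    best = max(valid, key=lambda t: (t[2], -t[1], -t[0]))
    return table, (best[0], best[1])
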