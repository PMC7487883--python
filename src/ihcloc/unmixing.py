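"""Stain separation of RGB IHC images into DAB (protein) and hematoxylin (DNA) maps.

Brightfield stains attenuate light multiplicatively, so stain contributions
are approximately additive in optical density (Beer-Lambert law):

    OD(x) = -log10(I(x) / I0) = sum_s c_s(x) * v_s

where ``v_s`` is the unit color vector of stain ``s`` in OD space and
``c_s(x)`` the local stain concentration.  Two separation routes are
provided:

* **LIN** — linear spectral unmixing with one fixed empirical color basis
  shared by all images (default: the standard Ruifrok-Johnston
  hematoxylin/DAB vectors), solved per pixel by pseudo-inverse projection
  with negative concentrations clipped to zero.
* **NMF** — blind per-image separation: a rank-2 non-negative factorization
  of the (pixels x 3) OD matrix estimates an image-specific basis, whose
  rows are then matched to a reference basis by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from .core_io import IHCImage, StainBasis

logger = logging.getLogger(__name__)

#: Ruifrok-Johnston optical-density color vectors (rows: hematoxylin, DAB).
RUIFROK_HEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_DAB = (0.268, 0.570, 0.776)

#: eps added to pixel values before the log transform, in gray levels
OD_EPS = 1.0
#: maximum basis condition number accepted by unmix_linear
MAX_CONDITION = 1e8


class DegenerateImageError(ValueError):
    """Raised when an image has too little color structure to factorize."""


@dataclass
class StainChannels:
    """Paired single-stain concentration maps from one image."""

    protein: np.ndarray
    dna: np.ndarray
    basis_used: StainBasis
    method: str  # "LIN" | "NMF"

    def __post_init__(self) -> None:
        if self.protein.shape != self.dna.shape:
            raise ValueError("protein and dna channels must share a shape")
        if self.method not in ("LIN", "NMF"):
            raise ValueError(f"unknown unmixing method {self.method!r}")


def default_basis() -> StainBasis:
    """The standard published hematoxylin/DAB OD color basis, rows unit-norm."""
    return StainBasis(matrix=np.array([RUIFROK_HEMATOXYLIN, RUIFROK_DAB]))


def od_transform(image: IHCImage | np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to optical density: OD = -log10((p + 1)/255), clipped at 0.

    The +1 offset avoids log of zero; the clip removes the slightly negative
    value the offset would give at p = 255.  Float RGB arrays (un-quantized
    synthetic renderings) are accepted unchanged through the same formula.
    """
    px = image.pixels if isinstance(image, IHCImage) else np.asarray(image)
    od = -np.log10((px.astype(np.float64) + OD_EPS) / 255.0)
    return np.maximum(od, 0.0)


def od_inverse(od: np.ndarray) -> np.ndarray:
    """Map an OD array back to 8-bit RGB (inverse of :func:`od_transform`)."""
    px = 255.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - OD_EPS
    return np.clip(np.round(px), 0, 255).astype(np.uint8)


def unmix_od(od: np.ndarray, basis: StainBasis) -> tuple[np.ndarray, np.ndarray]:
    """Project an HxWx3 OD map onto the two basis rows; clip negatives.

    Returns (dna, protein) concentration maps in basis row order.
    """
    B = basis.matrix
    if np.linalg.cond(B @ B.T) > MAX_CONDITION:
        raise np.linalg.LinAlgError("stain basis is near-singular")
    pinv = np.linalg.pinv(B)  # 3x2
    conc = np.asarray(od, dtype=np.float64) @ pinv
    conc = np.maximum(conc, 0.0)
    return conc[..., 0], conc[..., 1]


def unmix_linear(image: IHCImage | np.ndarray, basis: StainBasis | None = None) -> StainChannels:
    """Fixed-basis linear spectral unmixing (LIN) of one image."""
    basis = basis or default_basis()
    dna, protein = unmix_od(od_transform(image), basis)
    return StainChannels(protein=protein, dna=dna, basis_used=basis, method="LIN")


def match_channels(fitted_basis: StainBasis, reference: StainBasis) -> tuple[int, int]:
    """Row permutation of ``fitted_basis`` best matching ``reference``.

    Maximizes the sum of row-wise cosine similarities over the two possible
    permutations; ties break to the identity.
    """
    F, R = fitted_basis.matrix, reference.matrix
    cos = F @ R.T  # rows unit-norm, so dot = cosine
    identity_score = cos[0, 0] + cos[1, 1]
    swap_score = cos[0, 1] + cos[1, 0]
    return (0, 1) if identity_score >= swap_score else (1, 0)


def _extreme_angle_init(V: np.ndarray, od_floor: float = 0.15,
                        percentile: float = 1.0) -> np.ndarray | None:
    """Initial 2x3 basis from the extreme angular directions of the OD cloud.

    Background pixels (OD norm below ``od_floor``) are dropped, the rest are
    projected onto their best-fit SVD plane, and the directions at the
    ``percentile`` / ``100 - percentile`` angle quantiles become the two
    initial stain vectors.  Without this a rank-2 factorization is free to
    pick any cone containing the data and routinely lands on one wider than
    the true stain cone.  Returns None when too few stained pixels exist.
    """
    Vf = V[(V ** 2).sum(axis=1) > od_floor ** 2]
    if len(Vf) < 16:
        return None
    _, _, vt = np.linalg.svd(Vf, full_matrices=False)
    plane = vt[:2]
    for k in range(2):
        if plane[k].sum() < 0:
            plane[k] = -plane[k]
    proj = Vf @ plane.T
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [percentile, 100.0 - percentile])
    H0 = np.vstack([
        np.cos(lo) * plane[0] + np.sin(lo) * plane[1],
        np.cos(hi) * plane[0] + np.sin(hi) * plane[1],
    ])
    H0 = np.maximum(H0, 1e-6)
    return H0 / np.linalg.norm(H0, axis=1, keepdims=True)


def unmix_nmf(image: IHCImage | np.ndarray, seed: int = 0, *,
              reference: StainBasis | None = None,
              max_iter: int = 500, tol: float = 1e-5,
              on_od: bool = True) -> StainChannels:
    """Blind per-image stain separation by rank-2 NMF of the OD matrix.

    The factorization ``OD ≈ W·H`` (W: pixels x 2 concentrations, H: 2x3
    basis) is solved by coordinate descent, initialized at the extreme
    angular directions of the stained-pixel OD cloud (deterministic;
    non-negative double-SVD fallback when the image has too few stained
    pixels).  The fitted basis rows are unit-normalized and matched against
    ``reference`` (default: the shared empirical basis) so the returned
    channels are in (dna, protein) order.

    Identifiability caveat: the fitted basis row of a stain is only
    recoverable when some pixels carry that stain alone; purely co-located
    stains (e.g. nuclear protein on hematoxylin) leave the basis
    under-determined even though the reconstruction stays exact.

    ``on_od=False`` factorizes inverted raw intensities (255 - RGB) instead
    of OD; OD is the default convention of the stain-separation literature.
    """
    reference = reference or default_basis()
    px = image.pixels if isinstance(image, IHCImage) else np.asarray(image)
    H_, W_ = px.shape[0], px.shape[1]
    if on_od:
        V = od_transform(image).reshape(-1, 3)
    else:
        V = (255.0 - px.astype(np.float64)).reshape(-1, 3)
    # degenerate-image guard: need at least 2 distinct non-white colors
    nonwhite = V[(V > 1e-3).any(axis=1)]
    if len(nonwhite) == 0 or len(np.unique(nonwhite.round(6), axis=0)) < 2:
        raise DegenerateImageError(
            "image has fewer than 2 distinct non-white colors; NMF is degenerate"
        )
    H0 = _extreme_angle_init(V)
    if H0 is not None:
        model = NMF(n_components=2, init="custom", solver="cd", tol=tol,
                    max_iter=max_iter, random_state=int(seed))
        W0 = np.maximum(V @ np.linalg.pinv(H0), 0.0)
        fit_kwargs = {"W": W0, "H": H0}
    else:
        model = NMF(n_components=2, init="nndsvda", solver="cd", tol=tol,
                    max_iter=max_iter, random_state=int(seed))
        fit_kwargs = {}
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(V, **fit_kwargs)
    Hmat = model.components_
    if model.n_iter_ >= max_iter:
        logger.warning("NMF did not converge in %d iterations; best iterate used", max_iter)
    norms = np.linalg.norm(Hmat, axis=1)
    norms[norms == 0] = 1.0
    Hn = Hmat / norms[:, None]
    W = W * norms[None, :]  # keep W·H invariant under row normalization
    fitted = StainBasis(matrix=Hn)
    perm = match_channels(fitted, reference)
    W = W[:, list(perm)]
    fitted = StainBasis(matrix=fitted.matrix[list(perm)])
    dna = W[:, 0].reshape(H_, W_)
    protein = W[:, 1].reshape(H_, W_)
    return StainChannels(protein=protein, dna=dna, basis_used=fitted, method="NMF")
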