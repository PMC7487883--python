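"""Per-patch engineered features: 16 DNA + 576 Haralick-on-wavelet + 256 LBP = 848.

The engineered descriptor follows the subcellular-location-feature (SLF)
tradition for IHC images:

* **DNA features (16)** — overlap, intensity-ratio, colocalization and
  nearest-neighbor distance statistics relating the protein channel to the
  DNA (nuclear) channel; they carry most of the nucleus-vs-cytoplasm signal.
* **Haralick features (576)** — the protein channel is decomposed by a
  2-D multilevel discrete wavelet transform (Daubechies db1..db10, 5 levels,
  periodization) into 16 subbands (deepest approximation + LH/HL/HH per
  level); each subband is min-max quantized to 32 gray levels and 9 Haralick
  statistics are computed from symmetric normalized co-occurrence matrices
  at the 4 unit-distance offsets: 16 x 4 x 9 = 576.
* **LBP features (256)** — the histogram of classic 8-neighbor radius-1
  local binary pattern codes of the protein channel.

Feature vectors are deterministic, NaN-free (degenerate statistics are
imputed: zero-variance correlations -> 0, zero-denominator ratios -> 0,
empty-mask distance statistics -> the window diagonal), and carry
block-prefixed column names (``dna.``, ``har.dbK.``, ``lbp.``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

N_DNA = 16
N_HARALICK = 576
N_LBP = 256
N_ENGINEERED = N_DNA + N_HARALICK + N_LBP  # 848

HARALICK_STAT_NAMES = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "sum_average", "entropy", "sum_entropy", "difference_entropy",
)
#: unit-distance GLCM offsets (dr, dc) at 0, 45, 90, 135 degrees
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class HaralickConfig:
    """Configuration of the Haralick-on-wavelet block."""

    wavelet_filter: str = "db4"
    levels: int = 5
    gray_levels: int = 32
    offsets: tuple = GLCM_OFFSETS
    stats: tuple = HARALICK_STAT_NAMES

    def __post_init__(self) -> None:
        if not (self.wavelet_filter.startswith("db")
                and self.wavelet_filter[2:].isdigit()
                and 1 <= int(self.wavelet_filter[2:]) <= 10):
            raise ValueError("wavelet_filter must be db1..db10")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")

    @property
    def n_subbands(self) -> int:
        return 3 * self.levels + 1

    @property
    def n_features(self) -> int:
        return self.n_subbands * len(self.offsets) * len(self.stats)


@dataclass
class FeatureMatrix:
    """Rows = patches or images, columns = named features with block provenance."""

    values: np.ndarray
    row_ids: list[str]
    column_names: list[str]
    block_index: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape[0] != len(self.row_ids) or v.shape[1] != len(self.column_names):
            raise ValueError("values shape inconsistent with row/column names")
        if not np.isfinite(v).all():
            raise ValueError("feature matrix contains NaN/Inf")
        if self.block_index:
            total = sum(b - a for a, b in self.block_index.values())
            if total != v.shape[1]:
                raise ValueError("block index does not cover all columns")
        self.values = v

    @classmethod
    def from_rows(cls, rows: list[np.ndarray], row_ids: list[str],
                  column_names: list[str],
                  block_index: dict[str, tuple[int, int]] | None = None):
        return cls(values=np.vstack(rows), row_ids=list(row_ids),
                   column_names=list(column_names), block_index=block_index or {})


def _binarize(window: np.ndarray) -> np.ndarray:
    """Otsu threshold mask; global-mean fallback for unimodal windows."""
    w = np.asarray(window, dtype=np.float64)
    if np.ptp(w) == 0:
        return np.zeros(w.shape, dtype=bool)
    try:
        t = threshold_otsu(w)
    except ValueError:
        t = w.mean()
    return w > t


def _safe_ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else 0.0


def _mask_distance_stats(src: np.ndarray, dst: np.ndarray, diag: float) -> list[float]:
    """mean/median/std/max of distances from src-mask pixels to the nearest
    dst-mask pixel, normalized by the window diagonal; empty masks -> 1."""
    if not src.any() or not dst.any():
        return [1.0, 1.0, 1.0, 1.0]
    dist_to_dst = ndimage.distance_transform_edt(~dst)
    d = dist_to_dst[src] / diag
    return [float(d.mean()), float(np.median(d)), float(d.std()), float(d.max())]


def dna_features(patch_protein: np.ndarray, patch_dna: np.ndarray) -> np.ndarray:
    """The 16 DNA/protein overlap, intensity and distance features.

    Fixed order:
      0  area(D)/area(P)
      1  |P∩D|/|P|
      2  |P∩D|/|D|
      3  total DNA intensity / total protein intensity
      4  Manders M1: protein intensity inside D / total protein intensity
      5  Manders M2: DNA intensity inside P / total DNA intensity
      6  Pearson correlation of the two intensity maps over P∪D
      7  distance between intensity-weighted centroids / window diagonal
      8-11  mean, median, std, max nearest-neighbor distance P -> D (/diag)
      12-15 the same, D -> P
    """
    p = np.asarray(patch_protein, dtype=np.float64)
    d = np.asarray(patch_dna, dtype=np.float64)
    if p.shape != d.shape:
        raise ValueError("protein and DNA windows must share a shape")
    P = _binarize(p)
    D = _binarize(d)
    inter = P & D
    union = P | D
    diag = float(np.hypot(*p.shape))
    f = np.zeros(N_DNA)
    f[0] = _safe_ratio(D.sum(), P.sum())
    f[1] = _safe_ratio(inter.sum(), P.sum())
    f[2] = _safe_ratio(inter.sum(), D.sum())
    f[3] = _safe_ratio(d.sum(), p.sum())
    # Manders split coefficients use the standard >0 support masks (not the
    # Otsu masks), so perfectly colocalized channels score exactly 1
    f[4] = _safe_ratio(p[d > 0].sum(), p.sum())
    f[5] = _safe_ratio(d[p > 0].sum(), d.sum())
    if union.sum() >= 2:
        pu, du = p[union], d[union]
        if pu.std() > 0 and du.std() > 0:
            f[6] = float(np.corrcoef(pu, du)[0, 1])
    if p.sum() > 0 and d.sum() > 0:
        idx = np.indices(p.shape).reshape(2, -1)
        cp = (idx * p.ravel()).sum(axis=1) / p.sum()
        cd = (idx * d.ravel()).sum(axis=1) / d.sum()
        f[7] = float(np.linalg.norm(cp - cd) / diag)
    f[8:12] = _mask_distance_stats(P, D, diag)
    f[12:16] = _mask_distance_stats(D, P, diag)
    return f


def wavelet_subbands(channel: np.ndarray, wavelet: str = "db4",
                     levels: int = 5) -> list[np.ndarray]:
    """Multilevel 2-D DWT subbands with periodization extension.

    Returns 3*levels + 1 maps in fixed order: deepest approximation first,
    then (LH, HL, HH) from the deepest to the shallowest level.
    """
    ch = np.asarray(channel, dtype=np.float64)
    min_side = 2 ** levels
    if min(ch.shape) < min_side:
        raise ValueError(
            f"window side {min(ch.shape)} < minimum {min_side} for {levels} levels"
        )
    import warnings

    with warnings.catch_warnings():
        # periodization keeps deep levels valid on small windows; pywt's
        # boundary-effect warning is expected and harmless here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(ch, wavelet, mode="periodization", level=levels)
    out = [coeffs[0]]
    for detail in coeffs[1:]:  # deepest level first in pywt ordering
        cH, cV, cD = detail
        out.extend([cH, cV, cD])  # LH, HL, HH
    return out


def glcm(quantized: np.ndarray, offset: tuple[int, int],
         gray_levels: int) -> np.ndarray:
    """Symmetric normalized gray-level co-occurrence matrix at one offset.

    ``quantized`` holds integer levels in [0, gray_levels); pairs are counted
    at displacement (dr, dc), symmetrized, and normalized to sum 1.
    """
    q = np.asarray(quantized)
    if q.min() < 0 or q.max() >= gray_levels:
        raise ValueError("quantized values outside [0, gray_levels)")
    dr, dc = offset
    H, W = q.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValueError(f"window {q.shape} smaller than offset span {offset}")
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * gray_levels + b, minlength=gray_levels * gray_levels)
    P = counts.reshape(gray_levels, gray_levels).astype(np.float64)
    P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with 0·log0 := 0."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 9 Haralick statistics of a normalized GLCM, in fixed order.

    energy, contrast, correlation, variance, homogeneity (inverse difference
    moment), sum average, entropy, sum entropy, difference entropy.
    Logarithms are base 2; zero-variance correlation is imputed as 0.
    """
    P = np.asarray(P, dtype=np.float64)
    G = P.shape[0]
    i = np.arange(G, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py for symmetric P
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    energy = float((P ** 2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if var > 0:
        correlation = float((((ii - mu) * (jj - mu) * P).sum()) / var)
    else:
        correlation = 0.0
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    # sum / difference distributions over i+j and |i-j|
    s = (ii + jj).astype(int).ravel()
    dd = np.abs(ii - jj).astype(int).ravel()
    p_sum = np.bincount(s, weights=P.ravel(), minlength=2 * G - 1)
    p_diff = np.bincount(dd, weights=P.ravel(), minlength=G)
    sum_average = float((np.arange(2 * G - 1) * p_sum).sum())
    entropy = _entropy2(P.ravel())
    sum_entropy = _entropy2(p_sum)
    difference_entropy = _entropy2(p_diff)
    return np.array([energy, contrast, correlation, var, homogeneity,
                     sum_average, entropy, sum_entropy, difference_entropy])


def _quantize(x: np.ndarray, gray_levels: int) -> np.ndarray:
    """Per-array min-max quantization to integer levels; constant -> all 0."""
    x = np.asarray(x, dtype=np.float64)
    rng = np.ptp(x)
    if rng == 0:
        return np.zeros(x.shape, dtype=np.intp)
    q = np.floor((x - x.min()) / rng * gray_levels).astype(np.intp)
    return np.minimum(q, gray_levels - 1)


def haralick_features(patch_protein: np.ndarray,
                      cfg: HaralickConfig | None = None) -> np.ndarray:
    """The 576 Haralick-on-wavelet features in (subband, offset, stat) order."""
    cfg = cfg or HaralickConfig()
    subbands = wavelet_subbands(patch_protein, cfg.wavelet_filter, cfg.levels)
    out = np.empty(cfg.n_features)
    k = 0
    n_stats = len(cfg.stats)
    for sb in subbands:
        q = _quantize(sb, cfg.gray_levels)
        for off in cfg.offsets:
            if min(q.shape) <= max(abs(off[0]), abs(off[1])):
                # subband too small to pair pixels at this offset (deepest
                # level of a 2^levels-sided window); impute the degenerate
                # single-entry co-occurrence matrix
                P = np.zeros((cfg.gray_levels, cfg.gray_levels))
                P[0, 0] = 1.0
            else:
                P = glcm(q, off, cfg.gray_levels)
            out[k:k + n_stats] = haralick_stats(P)
            k += n_stats
    return out


#: clockwise 8-neighbor offsets starting at top-left; bit b of the LBP code
#: is set iff neighbor b >= center.
LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_features(patch_protein: np.ndarray) -> np.ndarray:
    """Normalized 256-bin histogram of classic radius-1 LBP codes.

    Codes are computed per interior pixel; a constant window therefore maps
    every pixel to code 255 (all neighbors >= center).
    """
    w = np.asarray(patch_protein, dtype=np.float64)
    if w.shape[0] < 3 or w.shape[1] < 3:
        raise ValueError("LBP needs a window of at least 3x3")
    center = w[1:-1, 1:-1]
    code = np.zeros(center.shape, dtype=np.intp)
    for bit, (dr, dc) in enumerate(LBP_OFFSETS):
        nb = w[1 + dr:w.shape[0] - 1 + dr, 1 + dc:w.shape[1] - 1 + dc]
        code |= (nb >= center).astype(np.intp) << bit
    hist = np.bincount(code.ravel(), minlength=N_LBP).astype(np.float64)
    return hist / hist.sum()


def engineered_column_names(cfg: HaralickConfig | None = None) -> list[str]:
    cfg = cfg or HaralickConfig()
    names = [f"dna.{i:02d}" for i in range(N_DNA)]
    for sb in range(cfg.n_subbands):
        for o, off in enumerate(cfg.offsets):
            for stat in cfg.stats:
                names.append(f"har.{cfg.wavelet_filter}.s{sb:02d}.o{o}.{stat}")
    names.extend(f"lbp.{i:03d}" for i in range(N_LBP))
    return names


def engineered_block_index(cfg: HaralickConfig | None = None) -> dict[str, tuple[int, int]]:
    cfg = cfg or HaralickConfig()
    return {
        "dna": (0, N_DNA),
        f"har.{cfg.wavelet_filter}": (N_DNA, N_DNA + cfg.n_features),
        "lbp": (N_DNA + cfg.n_features, N_DNA + cfg.n_features + N_LBP),
    }


def featurize_patch(patch_protein: np.ndarray, patch_dna: np.ndarray,
                    cfg: HaralickConfig | None = None) -> np.ndarray:
    """Concatenated [dna(16) | haralick(576) | lbp(256)] = 848 features."""
    cfg = cfg or HaralickConfig()
    vec = np.concatenate([
        dna_features(patch_protein, patch_dna),
        haralick_features(patch_protein, cfg),
        lbp_features(patch_protein),
    ])
    if not np.isfinite(vec).all():  # pragma: no cover - guarded upstream
        raise AssertionError("engineered feature vector contains NaN/Inf")
    return vec


def featurize_image(patches, cfg: HaralickConfig | None = None) -> np.ndarray:
    """Image-level vector: element-wise mean of per-patch vectors."""
    if len(patches) == 0:
        raise ValueError("cannot featurize an empty PatchSet")
    cfg = cfg or HaralickConfig()
    vecs = [featurize_patch(p, d, cfg)
            for p, d in zip(patches.protein_windows, patches.dna_windows)]
    return np.mean(vecs, axis=0)
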