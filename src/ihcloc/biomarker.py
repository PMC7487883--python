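"""Translocation-biomarker screening from classifier score vectors.

A protein whose subcellular compartment differs between normal and cancer
tissue shifts the class-score vectors its images receive.  Each image is
scored by seven single classifiers (one per feature route: engineered
features combined with each backbone's deep features), giving a 21-dim
vector (7 classifiers x 3 class scores).  With m normal-tissue and n
cancer-tissue image vectors, an independent two-sample t-test per dimension
yields a 21-long P-value vector; the protein is flagged as a location
biomarker iff any P value falls below alpha (default 0.05, uncorrected — a
deliberately liberal min-p rule; Bonferroni/BH and Hotelling's T^2 are
available behind flags).

Two control analyses accompany the screen: a null control that splits a
protein's normal images in half and tests half against half (true
translocations cannot appear there), and an intensity-distance control that
fits gamma distributions to protein-channel histogram distances of detected
vs undetected proteins (similar fits indicate detection is not driven by
raw pixel-distribution shifts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import TrainedModel, predict_scores, protein_vote
from .core_io import INT_TO_LABEL

logger = logging.getLogger(__name__)

N_CLASSIFIERS = 7
SCORE_DIM = N_CLASSIFIERS * 3  # 21
DEFAULT_ALPHA = 0.05


@dataclass
class TranslocationReport:
    """Per-protein screening outcome."""

    protein_id: str
    predicted_normal_location: str
    predicted_cancer_location: str
    p_values: np.ndarray
    is_biomarker: bool
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=np.float64)
        if self.p_values.shape != (SCORE_DIM,):
            raise ValueError(f"expected {SCORE_DIM} p-values")
        assert self.is_biomarker == bool(self.p_values.min() < self.alpha)


def image_score_vector(models: list[TrainedModel], feature_sets: list[np.ndarray]
                       ) -> np.ndarray:
    """Concatenate the 7 classifiers' 3-score outputs for one image.

    ``feature_sets[k]`` is the image-level feature vector for classifier k
    (classifiers ordered as the backbone order).  Each consecutive score
    triple sums to 1.
    """
    if len(models) != N_CLASSIFIERS or len(feature_sets) != N_CLASSIFIERS:
        raise ValueError(f"need exactly {N_CLASSIFIERS} models and feature sets")
    parts = []
    for model, feats in zip(models, feature_sets):
        scores = predict_scores(model, np.atleast_2d(feats))[0]
        parts.append(scores)
    return np.concatenate(parts)


def translocation_test(normal: np.ndarray, cancer: np.ndarray,
                       variant: str = "student") -> np.ndarray:
    """Per-dimension two-sided independent two-sample t-test P values.

    ``variant='student'`` pools variances (the classical default here);
    ``'welch'`` drops the equal-variance assumption.  Dimensions with zero
    pooled variance are imputed: P = 1 when the group means agree, else 0.
    """
    normal = np.atleast_2d(np.asarray(normal, dtype=np.float64))
    cancer = np.atleast_2d(np.asarray(cancer, dtype=np.float64))
    if normal.shape[0] < 2 or cancer.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    if normal.shape[1] != cancer.shape[1]:
        raise ValueError("dimension mismatch between groups")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be student or welch")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical groups trip scipy's precision warning; the
        # degenerate-dimension imputation below handles those cases
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(normal, cancer, axis=0, equal_var=(variant == "student"))
        p = np.asarray(res.pvalue, dtype=np.float64)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance dimensions imputed", int(degenerate.sum()))
        same = np.isclose(normal.mean(axis=0), cancer.mean(axis=0))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return np.clip(p, 0.0, 1.0)


def flag_biomarker(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA,
                   correction: str | None = None) -> bool:
    """True iff the smallest (optionally corrected) P value is below alpha.

    No multiplicity correction by default; ``correction`` may be
    ``'bonferroni'`` or ``'bh'`` (Benjamini-Hochberg).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=np.float64)
    if correction == "bonferroni":
        return bool(p.min() * p.size < alpha)
    if correction == "bh":
        order = np.sort(p)
        thresh = alpha * np.arange(1, p.size + 1) / p.size
        return bool((order <= thresh).any())
    if correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return bool(p.min() < alpha)


def hotelling_t2_test(normal: np.ndarray, cancer: np.ndarray) -> float:
    """Single multivariate P value (Hotelling's T^2 with pooled covariance).

    Offered as the alternative reading of 'the mean vectors are the same';
    requires m + n - 2 > dimension, so it is only usable on reduced score
    spaces.
    """
    X = np.atleast_2d(normal)
    Y = np.atleast_2d(cancer)
    m, d = X.shape
    n = Y.shape[0]
    if m + n - 2 <= d:
        raise ValueError("too few samples for a full-rank pooled covariance")
    diff = X.mean(axis=0) - Y.mean(axis=0)
    S = ((m - 1) * np.cov(X.T) + (n - 1) * np.cov(Y.T)) / (m + n - 2)
    t2 = (m * n) / (m + n) * diff @ np.linalg.solve(S, diff)
    f = t2 * (m + n - d - 1) / (d * (m + n - 2))
    return float(stats.f.sf(f, d, m + n - d - 1))


def null_control(normal: np.ndarray, seed: int = 0,
                 variant: str = "student") -> np.ndarray:
    """Half-split control: t-test between two random halves of the normal rows.

    A protein that does not translocate should rarely produce small P values
    here.  Split sizes differ by at most one; deterministic given ``seed``.
    """
    normal = np.atleast_2d(np.asarray(normal, dtype=np.float64))
    m = normal.shape[0]
    if m < 4:
        raise ValueError("null control needs at least 4 normal images")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    half = m // 2
    a, b = normal[perm[:half]], normal[perm[half:]]
    return translocation_test(a, b, variant=variant)


def screen_protein(protein_id: str, normal_vectors: np.ndarray,
                   cancer_vectors: np.ndarray, alpha: float = DEFAULT_ALPHA,
                   variant: str = "student") -> TranslocationReport:
    """Full screen of one protein from its per-image 21-dim score vectors.

    Location calls use majority voting over the final-classifier score
    triple (the last block, the gapnet-combined classifier, by convention
    the integrated model's output is the mean over the seven blocks' votes;
    here the vote pools all seven blocks' argmax calls per image).
    """
    normal_vectors = np.atleast_2d(normal_vectors)
    cancer_vectors = np.atleast_2d(cancer_vectors)

    def _vote(vectors: np.ndarray) -> str:
        votes = []
        for v in vectors:
            triples = v.reshape(N_CLASSIFIERS, 3)
            mean_scores = triples.mean(axis=0)
            votes.append((int(mean_scores.argmax()), mean_scores))
        return INT_TO_LABEL[protein_vote(votes)]

    p = translocation_test(normal_vectors, cancer_vectors, variant=variant)
    return TranslocationReport(
        protein_id=protein_id,
        predicted_normal_location=_vote(normal_vectors),
        predicted_cancer_location=_vote(cancer_vectors),
        p_values=p,
        is_biomarker=flag_biomarker(p, alpha),
        alpha=alpha,
    )


def intensity_histogram(protein_channel: np.ndarray, bins: int = 64) -> np.ndarray:
    """Normalized intensity histogram of a protein channel (sums to 1)."""
    ch = np.asarray(protein_channel, dtype=np.float64).ravel()
    hi = ch.max()
    hist, _ = np.histogram(ch, bins=bins, range=(0.0, hi if hi > 0 else 1.0))
    return hist / hist.sum()


def intensity_distance_control(normal_hists: dict[str, list[np.ndarray]],
                               cancer_hists: dict[str, list[np.ndarray]],
                               detected_flags: dict[str, bool]
                               ) -> dict[str, tuple[float, float]]:
    """Gamma fits of pooled normal-vs-cancer histogram distances per flag group.

    For each protein, Euclidean distances between all normal x cancer
    histogram pairs are pooled into the 'detected' or 'undetected' group by
    its flag; each pool is fitted by maximum-likelihood gamma (shape k,
    scale theta, location fixed at 0).  Similar (k, theta) pairs for the two
    groups indicate that detection is not explained by raw intensity-
    distribution differences.
    """
    pools: dict[str, list[float]] = {"detected": [], "undetected": []}
    for pid, flag in detected_flags.items():
        nh = normal_hists.get(pid, [])
        ch = cancer_hists.get(pid, [])
        group = "detected" if flag else "undetected"
        for a in nh:
            for b in ch:
                pools[group].append(float(np.linalg.norm(np.asarray(a) - np.asarray(b))))
    out = {}
    for group, dists in pools.items():
        if not dists:
            raise ValueError(f"no proteins in the {group!r} group")
        d = np.asarray(dists)
        if np.allclose(d, 0.0):
            raise ValueError(f"degenerate {group!r} distances (all zero); gamma fit rejected")
        k, _loc, theta = stats.gamma.fit(d[d > 0], floc=0.0)
        out[group] = (float(k), float(theta))
    return out


def fit_gamma(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape k, scale theta) with location 0."""
    d = np.asarray(samples, dtype=np.float64)
    if np.allclose(d, 0.0):
        raise ValueError("degenerate samples (all zero)")
    k, _loc, theta = stats.gamma.fit(d[d > 0], floc=0.0)
    return float(k), float(theta)
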