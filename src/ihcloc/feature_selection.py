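"""Stepwise discriminant analysis (SDA) for feature-subset selection.

SDA greedily builds a feature subset by partial-F tests on Wilks' lambda,

    Lambda(S) = det(W_S) / det(T_S),

the ratio of within-class to total scatter determinants restricted to the
subset S.  Small Lambda means strong class separation.  At each step the
candidate with the largest F-to-enter joins the subset if it exceeds
``f_enter``; entered features whose F-to-remove has dropped below
``f_remove`` are then discarded.  The candidate scan uses bordered-
determinant Schur complements, so one step costs O(d·k^2) rather than
O(d·k^3) determinant evaluations, which keeps SDA usable on the
7104-dimensional combined feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_F_ENTER = 3.84
DEFAULT_F_REMOVE = 2.71
RIDGE_FACTOR = 1e-8


@dataclass
class SDAResult:
    """Outcome of one stepwise selection run."""

    selected: list[int] = field(default_factory=list)
    wilks_trace: list[float] = field(default_factory=list)
    f_enter: float = DEFAULT_F_ENTER
    f_remove: float = DEFAULT_F_REMOVE


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class scatter W and total scatter T (d x d)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in classes:
        g = X[y == c]
        if len(g) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        gc = g - g.mean(axis=0)
        W += gc.T @ gc
    return W, T


def _ridge(M: np.ndarray) -> np.ndarray:
    tr = np.trace(M)
    lam = RIDGE_FACTOR * (tr if tr > 0 else 1.0)
    return M + lam * np.eye(M.shape[0])


def _logdet_ratio(W: np.ndarray, T: np.ndarray, subset) -> float:
    idx = np.asarray(subset, dtype=np.intp)
    Ws = W[np.ix_(idx, idx)]
    Ts = T[np.ix_(idx, idx)]
    sW, ldW = np.linalg.slogdet(Ws)
    sT, ldT = np.linalg.slogdet(Ts)
    if sW <= 0 or sT <= 0:
        logger.warning("singular scatter on subset; ridge-stabilized")
        sW, ldW = np.linalg.slogdet(_ridge(Ws))
        sT, ldT = np.linalg.slogdet(_ridge(Ts))
    lam = float(np.exp(ldW - ldT))
    return min(lam, 1.0)


def wilks_lambda(X: np.ndarray, y, subset) -> float:
    """Wilks' Lambda = det(W)/det(T) restricted to ``subset`` columns.

    Lies in (0, 1]; 1 means no discrimination.  Singular scatter is
    ridge-stabilized (lambda = 1e-8 * trace) with a warning.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    W, T = _scatter_matrices(X, y)
    return _logdet_ratio(W, T, subset)


def _schur_all(M: np.ndarray, subset: list[int]) -> np.ndarray:
    """Schur complements M_jj - M_jS M_SS^-1 M_Sj for every column j."""
    d = M.shape[0]
    diag = np.diag(M).copy()
    if not subset:
        return diag
    S = np.asarray(subset, dtype=np.intp)
    MSS = M[np.ix_(S, S)]
    MSd = M[np.ix_(S, np.arange(d))]
    try:
        A = np.linalg.solve(MSS, MSd)
    except np.linalg.LinAlgError:
        A = np.linalg.solve(_ridge(MSS), MSd)
    quad = np.einsum("kd,kd->d", MSd, A)
    return diag - quad


def sda_select(X: np.ndarray, y, f_enter: float = DEFAULT_F_ENTER,
               f_remove: float = DEFAULT_F_REMOVE,
               max_k: int | None = None) -> SDAResult:
    """Forward-with-backward stepwise selection on Wilks' Lambda partial-F.

    At each step the feature with the largest F-to-enter joins the subset if
    its F exceeds ``f_enter`` (ties break to the lower column index); then
    any entered feature whose F-to-remove is below ``f_remove`` leaves,
    provided the removal keeps the Lambda trace strictly decreasing.  Stops
    when no entry is possible or ``max_k`` features are selected.
    Deterministic.
    """
    if not (f_enter > f_remove > 0):
        raise ValueError("need f_enter > f_remove > 0")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, d = X.shape
    g = len(np.unique(y))
    if max_k is None:
        max_k = min(200, max(1, n // 3), d)
    max_k = min(max_k, d)
    W, T = _scatter_matrices(X, y)
    result = SDAResult(f_enter=f_enter, f_remove=f_remove)
    selected: list[int] = []
    lam_current = 1.0
    while len(selected) < max_k:
        p = len(selected)
        dof = n - g - p
        if dof < 1:
            logger.warning("degrees of freedom exhausted at %d features", p)
            break
        sW = _schur_all(W, selected)
        sT = _schur_all(T, selected)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((sW > 1e-12) & (sT > 1e-12), sT / sW, 1.0)
        ratio = np.maximum(ratio, 1.0)
        F = (ratio - 1.0) * dof / (g - 1)
        F[selected] = -np.inf
        best = int(np.argmax(F))  # argmax takes the first (lowest) index on ties
        if not np.isfinite(F[best]) or F[best] <= f_enter:
            if p == 0:
                logger.warning("no feature passes f_enter; empty selection")
            break
        selected.append(best)
        lam_current = lam_current * float(sW[best] / sT[best])
        result.wilks_trace.append(lam_current)
        # backward pass
        removed = True
        while removed and len(selected) > 1:
            removed = False
            S = np.asarray(selected, dtype=np.intp)
            try:
                Winv = np.linalg.inv(W[np.ix_(S, S)])
                Tinv = np.linalg.inv(T[np.ix_(S, S)])
            except np.linalg.LinAlgError:
                Winv = np.linalg.inv(_ridge(W[np.ix_(S, S)]))
                Tinv = np.linalg.inv(_ridge(T[np.ix_(S, S)]))
            p_now = len(selected)
            dof_r = n - g - p_now + 1
            # Lambda(S\j)/Lambda(S) = (W^-1)_jj / (T^-1)_jj
            lam_ratio = np.diag(Winv) / np.diag(Tinv)
            Fr = (lam_ratio - 1.0) * dof_r / (g - 1)
            j = int(np.argmin(Fr))
            if selected[j] != best and Fr[j] < f_remove:
                new_lam = lam_current * float(lam_ratio[j])
                if not result.wilks_trace[:-1] or new_lam < result.wilks_trace[-2]:
                    lam_current = new_lam
                    del selected[j]
                    result.wilks_trace[-1] = lam_current
                    removed = True
                else:
                    logger.debug("removal skipped to keep Lambda trace decreasing")
    result.selected = selected
    return result
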