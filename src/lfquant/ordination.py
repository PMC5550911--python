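"""Ordination: PCA with variance-explained reporting and Pearson clustering.

PCA treats samples as observations and proteins as variables; protein
profiles are centered (and by default unit-scaled, i.e. correlation-matrix
PCA, the common SPSS-style default) before a thin SVD. Variance fractions
are always reported from the unrotated eigenvalues — oblique (promax)
rotation, when requested, re-expresses loadings for interpretability but
does not partition variance, so it never changes the reported fractions.

Heatmap ordering uses hierarchical agglomerative clustering with distance
1 - Pearson correlation and average linkage on both proteins (rows) and
samples (columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .assemble import QuantMatrix

__all__ = ["OrdinationError", "PcaResult", "ClusterOrder", "pca", "pearson_cluster"]

log = logging.getLogger(__name__)


class OrdinationError(ValueError):
    pass


@dataclass
class PcaResult:
    """PCA output: sample scores, protein loadings, percent variance.

    ``scores`` is samples x components, ``loadings`` proteins x components;
    ``scores @ loadings.T`` reconstructs the centered/scaled data when all
    components are retained. ``rotated_loadings``/``rotated_scores`` are
    populated only when promax rotation was requested and are for
    presentation; ``variance_pct`` always refers to the unrotated solution.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_pct: np.ndarray
    rotation: str = "none"
    rotated_loadings: pd.DataFrame | None = None
    rotated_scores: pd.DataFrame | None = None


@dataclass
class ClusterOrder:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _impute_within_condition(matrix: QuantMatrix) -> pd.DataFrame:
    """Mean-impute missing cells within their condition (ordination only —
    statistical testing never sees imputed values)."""
    data = matrix.data.copy()
    if not data.isna().any().any():
        return data
    for cond in matrix.condition_labels:
        cols = matrix.samples_for(cond)
        block = data[cols]
        means = block.mean(axis=1)
        if means.isna().any():
            bad = sorted(data.index[means.isna()])
            raise OrdinationError(f"proteins with no observations in {cond}: {bad}")
        data[cols] = block.apply(lambda col: col.fillna(means))
    return data


def _varimax(L: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation matrix for loadings L (vars x comps)."""
    p, k = L.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p))
        R = u @ vt
        new = s.sum()
        if new <= var * (1 + tol):
            break
        var = new
    return R


def _promax(L: np.ndarray, power: int = 4) -> np.ndarray:
    """Oblique promax-rotated loadings (Kaiser-normalized varimax target)."""
    # Kaiser normalization: rows scaled to unit communality before varimax
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    Ln = L / h[:, None]
    V = Ln @ _varimax(Ln)
    P = np.sign(V) * np.abs(V) ** power
    T, *_ = np.linalg.lstsq(V, P, rcond=None)
    # scale transform columns so factor variances stay 1
    d = np.sqrt(np.diag(np.linalg.inv(T.T @ T)))
    T = T * d
    return (V @ T) * h[:, None]


def pca(
    matrix: QuantMatrix,
    scope: str = "all",
    de_proteins: list[str] | None = None,
    scale: bool = True,
    rotate: bool = False,
) -> PcaResult:
    """Principal components of the sample-space protein-profile covariance.

    ``scope`` is ``"all"`` or ``"de_only"`` (restrict to ``de_proteins``).
    With ``scale=True`` proteins are centered and unit-scaled
    (correlation-matrix PCA); ``scale=False`` uses covariance. ``rotate``
    additionally reports promax-rotated loadings/scores.
    """
    if scope not in ("all", "de_only"):
        raise OrdinationError(f"unknown scope {scope!r}")
    if scope == "de_only":
        if not de_proteins:
            raise OrdinationError("scope='de_only' requires de_proteins")
        missing = [p for p in de_proteins if p not in matrix.data.index]
        if missing:
            raise OrdinationError(f"de_proteins not in matrix: {missing}")
        matrix = QuantMatrix(matrix.data.loc[list(de_proteins)], matrix.conditions.copy(), matrix.log10)
    data = _impute_within_condition(matrix)
    samples = list(data.columns)
    if len(samples) < 3:
        raise OrdinationError("PCA requires at least 3 samples")

    X = data.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # drop numerically-zero components (rank <= n_samples - 1 after centering)
    nz = S > max(S.max(), 1.0) * 1e-12 if S.size else S > 0
    U, S, Vt = U[:, nz], S[nz], Vt[nz]
    var = S**2
    variance_pct = 100.0 * var / var.sum()

    comp_ids = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=samples, columns=comp_ids)
    loadings = pd.DataFrame(Vt.T, index=data.index, columns=comp_ids)

    result = PcaResult(scores, loadings, variance_pct)
    if rotate:
        # rotate the eigenvalue-weighted loading pattern, SPSS-style
        A = Vt.T * (S / np.sqrt(max(len(samples) - 1, 1)))
        k = min(2, A.shape[1]) if A.shape[1] >= 2 else A.shape[1]
        rot = _promax(A[:, :k])
        result.rotation = "promax"
        result.rotated_loadings = pd.DataFrame(rot, index=data.index, columns=comp_ids[:k])
        # scores on rotated axes via least squares
        rs, *_ = np.linalg.lstsq(rot, X.T, rcond=None)
        result.rotated_scores = pd.DataFrame(rs.T, index=samples, columns=comp_ids[:k])
    return result


def pearson_cluster(matrix: QuantMatrix) -> ClusterOrder:
    """Average-linkage clustering of rows and columns at 1 - Pearson r.

    Imputes single within-condition missing values (as for PCA), requires
    every row and column to have nonzero variance (Pearson distance is
    undefined otherwise), and returns deterministic leaf orders.
    """
    data = _impute_within_condition(matrix)
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise OrdinationError("clustering requires >= 2 rows and >= 2 columns")
    for axis, what in ((1, "rows"), (0, "columns")):
        if np.any(np.std(X, axis=axis) == 0):
            raise OrdinationError(f"constant {what} have undefined Pearson distance")

    def _link(M: np.ndarray) -> np.ndarray:
        d = np.clip(pdist(M, metric="correlation"), 0.0, None)
        return hierarchy.linkage(d, method="average")

    row_link = _link(X)
    col_link = _link(X.T)
    row_order = [data.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [data.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterOrder(row_order, col_order, row_link, col_link)
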