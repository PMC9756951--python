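"""Per-cell TR activity scoring from the raw overlap matrix.

The chain, applied in order:

1. optional kNN smoothing of the sparse cell profiles (union of each cell's
   binary peak profile with its k nearest neighbors in LSI space);
2. ``M' = M / (D x Q)`` — divide each overlap count by the product of the
   reference dataset's peak count D_j and the cell's accessible base pairs
   per 1e8 (Q_i), removing both dataset-size and cell-depth bias;
3. ``M'' = M' − mean_cells(M')`` per dataset — centers each reference
   dataset so different TRs are comparable;
4. deduplication: for each factor keep, per cell, the best-scoring dataset
   (the "best match"), yielding the TR-by-cell matrix Y;
5. per-TR z-score followed by a logistic sigmoid, compressing outliers into
   (0, 1);
6. per-cell z-score so every cell's activity profile has mean 0 / std 1.

All standard deviations use the population (n) denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from screg.intervals import ReferenceIndex, overlap_matrix
from screg.matrix import CellPeakMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "knn_smooth_cells",
    "normalize_overlaps",
    "center_by_dataset",
    "deduplicate",
    "sigmoid_scale",
    "cell_zscore",
    "ActivityResult",
    "score_activity",
]


def _lsi_embedding(binary: sp.spmatrix, n_components: int, seed: int) -> np.ndarray:
    """TF-IDF + truncated SVD of the binary feature-by-cell matrix, the
    standard latent-semantic-indexing reduction for scATAC data."""
    from sklearn.decomposition import TruncatedSVD
    from sklearn.feature_extraction.text import TfidfTransformer

    # cells as documents, features as terms
    tfidf = TfidfTransformer(norm="l2", sublinear_tf=False)
    X = tfidf.fit_transform(binary.T.tocsr())
    n_components = min(n_components, min(X.shape) - 1)
    if n_components < 1:
        return np.asarray(X.todense())
    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    return svd.fit_transform(X)


def knn_smooth_cells(
    cells: CellPeakMatrix,
    k: int = 20,
    seed: int = 0,
    n_components: int = 50,
) -> CellPeakMatrix:
    """Impute sparse cell profiles by pooling each cell with its k nearest
    neighbor cells.

    Neighbors are found by cosine distance in an LSI (TF-IDF + truncated SVD)
    embedding of the binarised matrix; each cell's profile becomes the binary
    union of itself and its neighbors.  ``k=0`` is the identity.
    """
    if k == 0:
        return cells
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= cells.n_cells:
        raise ValueError(f"k={k} but only {cells.n_cells} cells")

    from sklearn.neighbors import NearestNeighbors

    binary = cells.binarized()
    emb = _lsi_embedding(binary, n_components=n_components, seed=seed)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine")
    nn.fit(emb)
    _, nbr = nn.kneighbors(emb)  # includes self in column 0 (or a duplicate)
    # union of binary profiles over {cell} ∪ neighbors
    pool = sp.lil_matrix((cells.n_cells, cells.n_cells), dtype=np.int8)
    for i in range(cells.n_cells):
        pool[np.append(nbr[i, : k + 1], i), i] = 1
    smoothed = binary @ pool.tocsc()
    smoothed.data = np.ones_like(smoothed.data)
    return CellPeakMatrix(cells.features, cells.barcodes, smoothed)


def normalize_overlaps(M: np.ndarray, D: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """M'[j, i] = M[j, i] / (D_j * Q_i).

    D is the per-dataset reference peak count; Q the per-cell accessible bp
    per 1e8.  Zero entries in D or Q make the quotient undefined and raise.
    """
    M = np.asarray(M, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64).ravel()
    Q = np.asarray(Q, dtype=np.float64).ravel()
    if M.shape != (D.size, Q.size):
        raise ValueError(f"M is {M.shape}, expected ({D.size}, {Q.size})")
    bad_d = np.flatnonzero(D <= 0)
    if bad_d.size:
        raise ValueError(f"dataset(s) {bad_d.tolist()} have zero peak count D")
    bad_q = np.flatnonzero(Q <= 0)
    if bad_q.size:
        raise ValueError(f"cell(s) {bad_q.tolist()} have zero covered bp Q")
    return M / np.outer(D, Q)


def center_by_dataset(M_prime: np.ndarray) -> np.ndarray:
    """M''[j, :] = M'[j, :] − mean over cells of M'[j, :]."""
    M_prime = np.asarray(M_prime, dtype=np.float64)
    return M_prime - M_prime.mean(axis=1, keepdims=True)


def deduplicate(
    M_dd: np.ndarray,
    dataset_ids: list[str],
    factor_map: dict[str, str],
    strategy: str = "max",
) -> tuple[np.ndarray, list[str], pd.DataFrame | None]:
    """Collapse datasets of the same factor to one TR score per cell.

    With ``strategy='max'`` (default) each (cell, TR) keeps the largest
    centered score and records the winning dataset as the cell's best match
    (ties broken by lowest dataset id).  ``strategy='average'`` takes the
    per-factor mean; no best match is defined then.

    Returns ``(Y, factors, best_match)`` where Y is TR-by-cell and
    ``best_match`` is a long-format frame (cell index, factor, dataset_id)
    or None for the average strategy.
    """
    if strategy not in ("max", "average"):
        raise ValueError(f"unknown strategy {strategy!r}")
    M_dd = np.asarray(M_dd, dtype=np.float64)
    missing = [d for d in dataset_ids if d not in factor_map]
    if missing:
        raise ValueError(f"datasets without a factor mapping: {missing}")

    factors: list[str] = []
    for d in dataset_ids:
        f = factor_map[d]
        if f not in factors:
            factors.append(f)

    n_cells = M_dd.shape[1]
    Y = np.empty((len(factors), n_cells))
    best_rows = []
    for ki, factor in enumerate(factors):
        # rows in ascending dataset-id order → argmax's first-hit rule is the
        # lowest-id tie-break
        rows = sorted(
            (j for j, d in enumerate(dataset_ids) if factor_map[d] == factor),
            key=lambda j: dataset_ids[j],
        )
        block = M_dd[rows, :]
        if strategy == "average":
            Y[ki] = block.mean(axis=0)
        else:
            win = np.argmax(block, axis=0)
            Y[ki] = block[win, np.arange(n_cells)]
            for i in range(n_cells):
                best_rows.append((i, factor, dataset_ids[rows[win[i]]]))
    best = (
        pd.DataFrame(best_rows, columns=["cell", "factor", "dataset_id"])
        if strategy == "max"
        else None
    )
    return Y, factors, best


def _pop_std(x: np.ndarray, axis: int) -> np.ndarray:
    return np.std(x, axis=axis, ddof=0)


def sigmoid_scale(Y: np.ndarray) -> np.ndarray:
    """Per-TR z-score followed by the logistic sigmoid; output in (0, 1).

    A TR with zero variance across cells gets z = 0 everywhere (score 0.5).
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[1] < 2:
        raise ValueError("need >= 2 cells to z-score per TR")
    mu = Y.mean(axis=1, keepdims=True)
    sd = _pop_std(Y, axis=1)[:, None]
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        logger.warning("%d TR(s) constant across cells; sigmoid set to 0.5", flat.size)
    z = np.divide(Y - mu, sd, out=np.zeros_like(Y), where=sd > 0)
    return expit(z)


def cell_zscore(Y: np.ndarray) -> np.ndarray:
    """Per-cell z-score: each cell column ends with mean 0 and (when
    non-constant) std 1; a constant cell gets all zeros."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] < 2:
        raise ValueError("need >= 2 TRs to z-score per cell")
    mu = Y.mean(axis=0, keepdims=True)
    sd = _pop_std(Y, axis=0)[None, :]
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        logger.warning("%d cell(s) constant across TRs; scores set to 0", flat.size)
    return np.divide(Y - mu, sd, out=np.zeros_like(Y), where=sd > 0)


@dataclass
class ActivityResult:
    """Final TR activity scores plus intermediates and provenance."""

    activity: pd.DataFrame  # TR x cell, after sigmoid + per-cell z-score
    best_match: pd.DataFrame | None  # (cell barcode, factor, dataset_id)
    overlap: pd.DataFrame  # raw M, dataset x cell
    normalized: pd.DataFrame  # M'' centered, dataset x cell
    q: pd.Series  # per-cell Q

    def to_anndata(self):
        """Cells-by-TR AnnData of the final activity (cells as observations,
        the single-cell convention)."""
        import anndata as ad

        return ad.AnnData(
            X=self.activity.T.to_numpy(),
            obs=pd.DataFrame(index=self.activity.columns),
            var=pd.DataFrame(index=self.activity.index),
        )


def score_activity(
    cells: CellPeakMatrix,
    index: ReferenceIndex,
    strategy: str = "max",
    knn: int = 0,
    seed: int = 0,
) -> ActivityResult:
    """Run the full activity-scoring chain and return an
    :class:`ActivityResult`.

    ``knn > 0`` smooths the cell profiles before any scoring.  Deterministic
    given (inputs, knn, seed).
    """
    if knn:
        cells = knn_smooth_cells(cells, k=knn, seed=seed)
    M = overlap_matrix(cells, index)
    D = index.peak_counts
    Q = cells.q_vector()
    M_prime = normalize_overlaps(M, D, Q)
    M_dd = center_by_dataset(M_prime)
    Y, factors, best = deduplicate(M_dd, index.dataset_ids, index.factor_map, strategy)
    Y = sigmoid_scale(Y)
    Y = cell_zscore(Y)
    barcodes = cells.barcodes
    if best is not None:
        best = best.assign(cell=[barcodes[i] for i in best["cell"]])
    return ActivityResult(
        activity=pd.DataFrame(Y, index=factors, columns=barcodes),
        best_match=best,
        overlap=pd.DataFrame(M, index=index.dataset_ids, columns=barcodes),
        normalized=pd.DataFrame(M_dd, index=index.dataset_ids, columns=barcodes),
        q=pd.Series(Q, index=barcodes, name="q"),
    )
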