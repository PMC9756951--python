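"""The feature-by-cell accessibility matrix.

scATAC-seq counts arrive as a sparse peak-by-cell or fixed-width-bin-by-cell
matrix.  All enrichment math binarises it (a feature is either accessible in a
cell or not) and needs, per cell, the total accessible base pairs Q_i — the
summed widths of the cell's nonzero features, expressed per 100 million bp.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

from screg.intervals import GenomicInterval, PeakSet

__all__ = ["CellPeakMatrix"]

BP_SCALE = 1e8  # Q is covered bp per 100 million


class CellPeakMatrix:
    """Sparse non-negative feature-by-cell count matrix with genomic features.

    Parameters
    ----------
    features
        One :class:`GenomicInterval` per matrix row (peaks or bins).
    barcodes
        One cell barcode per matrix column.
    counts
        ``(n_features, n_cells)`` sparse or dense non-negative counts.
    """

    def __init__(
        self,
        features: Sequence[GenomicInterval],
        barcodes: Sequence[str],
        counts,
    ):
        counts = sp.csc_matrix(counts)
        if counts.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"count matrix is {counts.shape} but there are "
                f"{len(features)} features and {len(barcodes)} barcodes"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative counts")
        self.features: list[GenomicInterval] = list(features)
        self.barcodes: list[str] = list(barcodes)
        self.counts: sp.csc_matrix = counts

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def __repr__(self) -> str:
        return f"CellPeakMatrix({self.n_features} features x {self.n_cells} cells)"

    def binarized(self) -> sp.csc_matrix:
        """Feature-by-cell 0/1 matrix (count > 0)."""
        b = self.counts.copy()
        b.data = np.ones_like(b.data)
        b.eliminate_zeros()
        return b

    @property
    def feature_widths(self) -> np.ndarray:
        return np.asarray([iv.width for iv in self.features], dtype=np.int64)

    def covered_bp(self) -> np.ndarray:
        """Per-cell total width of accessible (count>0) features, in bp."""
        return np.asarray(
            self.binarized().T @ self.feature_widths.astype(np.float64)
        ).ravel()

    def q_vector(self) -> np.ndarray:
        """Q: per-cell covered bp per 100 million."""
        return self.covered_bp() / BP_SCALE

    def cell_peaks(self, i: int) -> PeakSet:
        """The accessible features of cell ``i`` as a :class:`PeakSet`."""
        col = self.counts.getcol(i)
        rows = col.indices[col.data > 0]
        return PeakSet([self.features[r] for r in np.sort(rows)])

    def subset_cells(self, idx: Sequence[int]) -> "CellPeakMatrix":
        idx = list(idx)
        return CellPeakMatrix(
            self.features,
            [self.barcodes[i] for i in idx],
            self.counts[:, idx],
        )
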