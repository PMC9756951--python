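"""Genomic intervals, peak sets and exact overlap counting.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base
pair, so abutting intervals (``a.end == b.start``) do not overlap.  Overlaps
are counted as intersecting *pairs* — one query interval hitting three
reference intervals contributes three — matching the row semantics of
``bedtools intersect``.  Strand is ignored everywhere.

The search structure is a per-chromosome pair of sorted start/end arrays.
For a query ``[s, e)`` the number of reference intervals it intersects is::

    #{starts < e}  −  #{ends ≤ s}

which two ``np.searchsorted`` calls give in O(log n); exactness against a
nested-loop oracle is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "ReferenceIndex",
    "count_overlaps",
    "intersect_peaks",
    "overlap_matrix",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered collection of :class:`GenomicInterval` with optional per-peak
    attributes (e.g. fold enrichment, scan p-value).

    Internally column-oriented (numpy arrays grouped by chromosome once
    sorted), which keeps overlap queries vectorised.  Reference peak sets may
    contain mutually overlapping or duplicate intervals; both are retained and
    each counts as its own pair in overlap math.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        attrs: Mapping[str, Sequence] | None = None,
        sorted_: bool = False,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.attrs: dict[str, np.ndarray] = {
            k: np.asarray(v) for k, v in (attrs or {}).items()
        }
        for name, col in self.attrs.items():
            if len(col) != len(self.intervals):
                raise ValueError(
                    f"attribute {name!r} has {len(col)} values for "
                    f"{len(self.intervals)} intervals"
                )
        self.sorted = sorted_
        self._chrom_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        attrs: Mapping[str, Sequence] | None = None,
    ) -> "PeakSet":
        ivs = [GenomicInterval(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends)]
        return cls(ivs, attrs=attrs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PeakSet":
        """Build from a frame with ``chrom``/``start``/``end`` columns; any
        further columns become attributes."""
        extra = [c for c in df.columns if c not in ("chrom", "start", "end")]
        return cls.from_arrays(
            df["chrom"].tolist(),
            df["start"].tolist(),
            df["end"].tolist(),
            attrs={c: df[c].to_numpy() for c in extra} or None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )
        for name, col in self.attrs.items():
            df[name] = col
        return df

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(n={len(self)}, sorted={self.sorted})"

    @property
    def total_width(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def subset(self, idx: Sequence[int]) -> "PeakSet":
        """New PeakSet with the intervals at ``idx`` (order preserved)."""
        idx = list(idx)
        return PeakSet(
            [self.intervals[i] for i in idx],
            attrs={k: v[idx] for k, v in self.attrs.items()} or None,
        )

    def sort(self) -> "PeakSet":
        """Return a copy ordered by (chrom, start, end)."""
        order = sorted(range(len(self)), key=lambda i: self.intervals[i])
        out = self.subset(order)
        out.sorted = True
        return out

    # -- search ------------------------------------------------------------
    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted starts, sorted ends); built lazily."""
        if self._chrom_index is None:
            by_chrom: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.intervals:
                s, e = by_chrom.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._chrom_index = {
                c: (np.sort(np.asarray(s, dtype=np.int64)), np.sort(np.asarray(e, dtype=np.int64)))
                for c, (s, e) in by_chrom.items()
            }
        return self._chrom_index

    def count_overlapping(self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """For each query interval, the number of intervals in this set that
        share ≥1 bp with it (pair counts)."""
        index = self._index()
        out = np.zeros(len(starts), dtype=np.int64)
        chroms = np.asarray(chroms)
        for chrom in np.unique(chroms):
            entry = index.get(str(chrom))
            if entry is None:
                continue
            ref_starts, ref_ends = entry
            mask = chroms == chrom
            q_start = np.asarray(starts)[mask]
            q_end = np.asarray(ends)[mask]
            n_start_before = np.searchsorted(ref_starts, q_end, side="left")
            n_end_before = np.searchsorted(ref_ends, q_start, side="right")
            out[mask] = n_start_before - n_end_before
        return out


def _as_query_arrays(peaks: PeakSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    return (
        [iv.chrom for iv in peaks],
        np.asarray([iv.start for iv in peaks], dtype=np.int64),
        np.asarray([iv.end for iv in peaks], dtype=np.int64),
    )


def count_overlaps(query: PeakSet, reference: PeakSet) -> int:
    """Number of (query, reference) interval pairs sharing at least one bp.

    Symmetric in its arguments; duplicates on either side each count.
    """
    if len(query) == 0 or len(reference) == 0:
        return 0
    chroms, starts, ends = _as_query_arrays(query)
    return int(reference.count_overlapping(chroms, starts, ends).sum())


def intersect_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Intervals of ``a`` overlapping ≥1 interval of ``b``, each reported once
    with its original coordinates (``bedtools intersect -u`` semantics)."""
    if len(a) == 0 or len(b) == 0:
        return PeakSet([])
    chroms, starts, ends = _as_query_arrays(a)
    hits = b.count_overlapping(chroms, starts, ends) > 0
    return a.subset(np.flatnonzero(hits))


@dataclass
class ReferenceDataset:
    """One reference interval set (a TR ChIP-seq peak set or a motif
    pseudo-peak set) with its metadata."""

    dataset_id: str
    factor: str
    peaks: PeakSet
    metadata: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


class ReferenceIndex:
    """A searchable collection of reference datasets grouped by factor.

    Datasets are stored in ascending ``dataset_id`` order, which fixes the
    deterministic argmax tie-break downstream.  ``D`` is the per-dataset peak
    count vector used by the enrichment normalisation.
    """

    def __init__(self, datasets: Iterable[ReferenceDataset]):
        self.datasets: list[ReferenceDataset] = sorted(
            datasets, key=lambda d: d.dataset_id
        )
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate dataset ids: {dupes}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self) -> Iterator[ReferenceDataset]:
        return iter(self.datasets)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    @property
    def factors(self) -> list[str]:
        """Distinct factors, in first-appearance (dataset-id) order."""
        seen: dict[str, None] = {}
        for d in self.datasets:
            seen.setdefault(d.factor, None)
        return list(seen)

    @property
    def factor_map(self) -> dict[str, str]:
        """dataset_id → factor."""
        return {d.dataset_id: d.factor for d in self.datasets}

    @property
    def peak_counts(self) -> np.ndarray:
        """D: per-dataset peak counts, aligned with :attr:`dataset_ids`."""
        return np.asarray([d.n_peaks for d in self.datasets], dtype=np.int64)

    def get(self, dataset_id: str) -> ReferenceDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def datasets_for_factor(self, factor: str) -> list[ReferenceDataset]:
        hits = [d for d in self.datasets if d.factor == factor]
        if not hits:
            raise KeyError(f"factor {factor!r} has no datasets in the index")
        return hits


def overlap_matrix(cells: "CellPeakMatrix", index: ReferenceIndex) -> np.ndarray:
    """Dataset-by-cell matrix M of pair-overlap counts.

    ``M[j, i]`` is the number of (cell-peak, reference-peak) pairs sharing
    ≥1 bp between cell *i*'s accessible features and dataset *j*.  Computed as
    ``C.T @ B`` where ``C[f, j]`` counts dataset-*j* intervals overlapping
    feature *f* and ``B`` is the binarised feature-by-cell matrix — exact
    because a cell's peak set is a subset of the shared feature list.
    """
    import logging
    import scipy.sparse as sp

    if len(index) == 0:
        raise ValueError("empty reference index")
    chroms = [iv.chrom for iv in cells.features]
    starts = np.asarray([iv.start for iv in cells.features], dtype=np.int64)
    ends = np.asarray([iv.end for iv in cells.features], dtype=np.int64)
    C = np.empty((len(cells.features), len(index)), dtype=np.int64)
    for j, ds in enumerate(index):
        C[:, j] = ds.peaks.count_overlapping(chroms, starts, ends)
    B = cells.binarized()  # feature x cell sparse
    M = np.asarray((sp.csr_matrix(C.T) @ B).todense(), dtype=np.int64)
    empty = np.flatnonzero(np.asarray(B.sum(axis=0)).ravel() == 0)
    if empty.size:
        logging.getLogger(__name__).warning(
            "%d cell(s) have no accessible features; their overlap rows are zero",
            empty.size,
        )
    return M
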