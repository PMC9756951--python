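"""Curation of raw ChIP-seq peak sets and motif scans into the TR reference.

The builder applies the curation rules to arbitrary user-supplied BED peak
sets plus a QC table; it never downloads anything.  ChIP-seq datasets are
filtered on seven library/peak QC metrics, reduced to high-confidence
(>= 5-fold enrichment) peaks, and dropped when fewer than 1000 peaks remain.
Motif scan hits are restricted to open/regulatory chromatin (ccRE or union
DHS), purged of blacklist overlaps, standardised to 340 bp pseudo-peaks (the
average ChIP peak width) and capped at the 25 000 most significant sites per
motif.  Surviving ChIP and motif sets are compiled together into a
:class:`~screg.intervals.ReferenceIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from screg.intervals import GenomicInterval, PeakSet, ReferenceDataset, ReferenceIndex

__all__ = [
    "DatasetQC",
    "QC_THRESHOLDS",
    "apply_qc_filters",
    "filter_peaks_by_fold",
    "drop_small_datasets",
    "build_motif_pseudo_peaks",
    "build_index",
    "save_index",
    "load_index",
]

PSEUDO_PEAK_WIDTH = 340
MOTIF_SITE_CAP = 25_000

#: metric -> strict lower bound; a dataset is retained only if every metric
#: is strictly above its bound.
QC_THRESHOLDS: dict[str, float] = {
    "median_quality": 25.0,
    "unique_map_frac": 0.5,
    "pbc": 0.8,
    "fold10_peaks": 100.0,
    "frip": 0.01,
    "top5k_dhs_frac": 0.7,
}


@dataclass(frozen=True)
class DatasetQC:
    """Quality metrics of one ChIP-seq dataset.

    median_quality: median raw-sequence Phred quality; unique_map_frac:
    fraction of uniquely mapped reads; pbc: PCR bottleneck coefficient;
    fold10_peaks: number of peaks with >= 10-fold enrichment; frip: fraction
    of reads in peaks; top5k_dhs_frac: fraction of the top 5000 peaks
    overlapping the union DHS list.
    """

    dataset_id: str
    median_quality: float
    unique_map_frac: float
    pbc: float
    fold10_peaks: int
    frip: float
    top5k_dhs_frac: float

    def __post_init__(self) -> None:
        for name in ("unique_map_frac", "pbc", "frip", "top5k_dhs_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{self.dataset_id}: {name}={v} outside [0, 1]")
        if self.fold10_peaks < 0:
            raise ValueError(f"{self.dataset_id}: negative fold10_peaks")

    def passes(self) -> bool:
        return all(
            getattr(self, metric) > bound for metric, bound in QC_THRESHOLDS.items()
        )


def apply_qc_filters(qc: Sequence[DatasetQC | Mapping]) -> list[str]:
    """Dataset ids passing every QC criterion (all bounds strict), in input
    order.  Mapping rows must carry all metric fields; a missing one raises
    naming the field."""
    retained = []
    for row in qc:
        if isinstance(row, Mapping):
            missing = [k for k in ("dataset_id", *QC_THRESHOLDS) if k not in row]
            if missing:
                raise KeyError(
                    f"QC row missing metric(s): {missing} "
                    f"(dataset {row.get('dataset_id', '?')})"
                )
            row = DatasetQC(**{k: row[k] for k in ("dataset_id", *QC_THRESHOLDS)})
        if row.passes():
            retained.append(row.dataset_id)
    return retained


def filter_peaks_by_fold(peaks: PeakSet, min_fold: float = 5.0) -> PeakSet:
    """Keep peaks with fold enrichment >= ``min_fold`` (inclusive), order
    preserved.  Requires a ``fold`` attribute."""
    if "fold" not in peaks.attrs:
        raise ValueError("peak set has no 'fold' attribute")
    keep = np.flatnonzero(np.asarray(peaks.attrs["fold"], dtype=float) >= min_fold)
    return peaks.subset(keep)


def drop_small_datasets(
    datasets: Mapping[str, PeakSet], min_peaks: int = 1000
) -> dict[str, PeakSet]:
    """Drop datasets with fewer than ``min_peaks`` peaks (applied after the
    fold filter)."""
    return {k: v for k, v in datasets.items() if len(v) >= min_peaks}


def _extend_to_width(iv: GenomicInterval, width: int) -> GenomicInterval:
    """Symmetric extension about the midpoint to ``width`` bp, extra bp going
    left when the needed extension is odd; clipped at position 0.  Intervals
    already >= width are returned unchanged."""
    extra = width - iv.width
    if extra <= 0:
        return iv
    left = (extra + 1) // 2
    start = max(0, iv.start - left)
    end = iv.end + (extra - left)
    return GenomicInterval(iv.chrom, start, end)


def build_motif_pseudo_peaks(
    sites: PeakSet,
    ccre: PeakSet,
    dhs: PeakSet,
    blacklist: PeakSet,
    width: int = PSEUDO_PEAK_WIDTH,
    cap: int = MOTIF_SITE_CAP,
) -> PeakSet:
    """Standardise one motif's scan hits into ChIP-comparable pseudo-peaks.

    Pipeline: keep sites overlapping ccRE or union DHS; drop blacklist
    overlaps; extend survivors to ``width`` bp about their midpoints (clipped
    at 0), re-dropping any extension that now touches the blacklist; if more
    than ``cap`` remain, keep the ``cap`` smallest scan p-values.  Scan
    p-values travel with the sites via the ``pvalue`` attribute and are
    required whenever the cap binds.
    """
    if len(sites) == 0:
        return PeakSet([])
    open_regions = PeakSet(list(ccre) + list(dhs))
    kept = np.flatnonzero(
        open_regions.count_overlapping(
            [iv.chrom for iv in sites],
            np.asarray([iv.start for iv in sites]),
            np.asarray([iv.end for iv in sites]),
        )
        > 0
    )
    sites = sites.subset(kept)
    if len(sites) == 0:
        return PeakSet([])

    def _blacklist_free(ps: PeakSet) -> PeakSet:
        if len(blacklist) == 0 or len(ps) == 0:
            return ps
        hits = blacklist.count_overlapping(
            [iv.chrom for iv in ps],
            np.asarray([iv.start for iv in ps]),
            np.asarray([iv.end for iv in ps]),
        )
        return ps.subset(np.flatnonzero(hits == 0))

    sites = _blacklist_free(sites)
    extended = PeakSet(
        [_extend_to_width(iv, width) for iv in sites],
        attrs={k: v for k, v in sites.attrs.items()} or None,
    )
    extended = _blacklist_free(extended)
    if len(extended) > cap:
        if "pvalue" not in extended.attrs:
            raise ValueError(
                f"{len(extended)} sites exceed the {cap} cap but carry no "
                "'pvalue' attribute to rank by"
            )
        pv = np.asarray(extended.attrs["pvalue"], dtype=float)
        order = np.argsort(pv, kind="stable")[:cap]
        extended = extended.subset(np.sort(order))
    return extended


def build_index(
    tr_peaksets: Mapping[str, PeakSet],
    metadata: Mapping[str, Mapping] | pd.DataFrame,
    motif_peaksets: Mapping[str, PeakSet] | None = None,
) -> ReferenceIndex:
    """Compile retained ChIP peak sets and motif pseudo-peak sets into a
    searchable index.

    ``metadata`` maps dataset id to at least a ``factor`` field (cell type,
    species etc. are carried through).  ChIP and motif sets for the same
    factor may coexist; duplicate dataset ids raise.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = metadata.set_index("dataset_id").to_dict("index") \
            if "dataset_id" in metadata.columns else metadata.to_dict("index")
    all_sets: dict[str, PeakSet] = dict(tr_peaksets)
    for k, v in (motif_peaksets or {}).items():
        if k in all_sets:
            raise ValueError(f"duplicate dataset id {k!r}")
        all_sets[k] = v
    datasets = []
    for ds_id, peaks in all_sets.items():
        if ds_id not in metadata:
            raise KeyError(f"no metadata for dataset {ds_id!r}")
        meta = dict(metadata[ds_id])
        factor = meta.pop("factor", None)
        if not factor:
            raise ValueError(f"dataset {ds_id!r} has no factor in its metadata")
        datasets.append(
            ReferenceDataset(ds_id, str(factor), peaks.sort(), metadata=meta)
        )
    return ReferenceIndex(datasets)


# ---------------------------------------------------------------------------
# persistence: a directory of sorted bed.gz files + metadata/factor-map TSVs

def save_index(index: ReferenceIndex, path: str | Path) -> Path:
    """Persist an index as a directory: one sorted ``<id>.bed.gz`` per
    dataset, a ``metadata.tsv`` (id, factor, peak count, extra fields) and a
    ``factor_map.tsv``."""
    from screg.io import write_bed

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    extra_keys = sorted({k for d in index for k in d.metadata})
    for d in index:
        write_bed(d.peaks, path / f"{d.dataset_id}.bed.gz")
        row = {
            "dataset_id": d.dataset_id,
            "factor": d.factor,
            "n_peaks": d.n_peaks,
        }
        for k in extra_keys:
            row[k] = d.metadata.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(d.dataset_id, d.factor) for d in index],
        columns=["dataset_id", "factor"],
    ).to_csv(path / "factor_map.tsv", sep="\t", index=False)
    return path


def load_index(path: str | Path) -> ReferenceIndex:
    """Load an index directory written by :func:`save_index`."""
    from screg.io import read_bed

    path = Path(path)
    meta = pd.read_csv(path / "metadata.tsv", sep="\t", dtype={"dataset_id": str})
    datasets = []
    for _, row in meta.iterrows():
        ds_id = row["dataset_id"]
        bed = path / f"{ds_id}.bed.gz"
        if not bed.exists():
            bed = path / f"{ds_id}.bed"
        peaks = read_bed(bed)
        extra = {
            k: row[k]
            for k in meta.columns
            if k not in ("dataset_id", "factor", "n_peaks")
        }
        if len(peaks) != int(row["n_peaks"]):
            raise ValueError(
                f"dataset {ds_id}: metadata says {row['n_peaks']} peaks, "
                f"bed file has {len(peaks)}"
            )
        datasets.append(ReferenceDataset(ds_id, str(row["factor"]), peaks, extra))
    return ReferenceIndex(datasets)
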