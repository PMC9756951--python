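"""TR target-gene scoring with the regulatory-potential (RP) model.

Once the enrichment step has picked, per (cell, TR), a best-matched ChIP-seq
dataset, the TR's binding sites in that cell are imputed as the dataset peaks
that overlap the cell's accessible regions.  A gene's RP score then sums an
exponential distance decay over those imputed sites::

    S_g = sum_i 2^(-d_i / d0)

where d_i is the distance from the i-th peak's center to the gene's TSS and
d0 the half-decay distance.  Sites beyond 15*d0 are skipped (each would
contribute < 0.0005).  d0 defaults to "auto": TRs with more than 20% of
their peaks in promoter windows (1 kb around the TSS) are promoter-type and
use d0 = 1 kb, all others are enhancer-type and use d0 = 10 kb.

The enhanced variant additionally (a) replaces the decay term with
1/(total exon kb of the gene) for peaks inside the gene's own exons and
(b) zeroes peaks lying in the promoter or exons of a *different* gene.

On top of per-cell RP matrices the module ranks targets, calls differential
targets between cell groups (ln-normalised, per-cell scaled, two-sided
rank-sum, |logFC| >= 0.25 and P <= 0.01), and assembles TR->gene regulatory
networks from the top-RP cells of each cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from screg.intervals import GenomicInterval, PeakSet, ReferenceIndex, intersect_peaks
from screg.matrix import CellPeakMatrix

__all__ = [
    "GeneModel",
    "classify_tr_type",
    "auto_half_decay",
    "impute_tr_peaks",
    "rp_score",
    "rp_matrix",
    "rank_targets",
    "differential_targets",
    "build_grn",
]

PROMOTER_FLANK = 1000  # bp either side of the TSS
PROMOTER_TYPE_D0 = 1_000
ENHANCER_TYPE_D0 = 10_000
PROMOTER_FRACTION_CUTOFF = 0.20  # strictly greater -> promoter-type
DEFAULT_CUTOFF_MULTIPLIER = 15  # peaks beyond this many d0 are dropped


@dataclass(frozen=True)
class GeneModel:
    """A gene annotation reduced to what the RP model needs.

    The promoter window spans ``PROMOTER_FLANK`` bp on both sides of the TSS
    (2001 bp unless clipped at position 0).  ``tss`` already accounts for
    strand (txEnd for minus-strand genes).
    """

    symbol: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"{self.symbol}: negative TSS")

    @property
    def total_exon_length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def promoter(self) -> GenomicInterval:
        start = max(0, self.tss - PROMOTER_FLANK)
        return GenomicInterval(self.chrom, start, self.tss + PROMOTER_FLANK + 1)


def _promoter_set(genes: Sequence[GeneModel]) -> PeakSet:
    return PeakSet([g.promoter for g in genes])


def classify_tr_type(
    tr_peaks: PeakSet, genes: Sequence[GeneModel]
) -> tuple[str, int]:
    """Classify a TR as promoter- or enhancer-type from where its peaks fall.

    The fraction of peaks overlapping any promoter window must exceed 20%
    (strictly) for the promoter type; returns ``(type, d0)`` with d0 = 1000
    or 10000 bp.
    """
    if len(tr_peaks) == 0:
        raise ValueError("cannot classify a TR with no peaks")
    if not genes:
        raise ValueError("no gene models supplied")
    promoters = _promoter_set(genes)
    hits = promoters.count_overlapping(
        [iv.chrom for iv in tr_peaks],
        np.asarray([iv.start for iv in tr_peaks]),
        np.asarray([iv.end for iv in tr_peaks]),
    )
    fraction = float(np.count_nonzero(hits)) / len(tr_peaks)
    if fraction > PROMOTER_FRACTION_CUTOFF:
        return "promoter", PROMOTER_TYPE_D0
    return "enhancer", ENHANCER_TYPE_D0


def auto_half_decay(tr_peaks: PeakSet, genes: Sequence[GeneModel]) -> int:
    """The half-decay distance selected by :func:`classify_tr_type`."""
    return classify_tr_type(tr_peaks, genes)[1]


def impute_tr_peaks(
    cell_peaks: PeakSet,
    best_dataset: PeakSet,
    extended: bool = False,
    all_best_datasets: Iterable[PeakSet] | None = None,
) -> PeakSet:
    """Impute a TR's binding sites in one cell.

    Default: the best-matched ChIP dataset's peaks that overlap >= 1 of the
    cell's accessible regions.  ``extended=True`` pools every dataset that is
    best match for at least one cell of this TR (``all_best_datasets``)
    before intersecting, recovering sites a thin single dataset would miss.
    """
    if extended:
        if all_best_datasets is None:
            raise ValueError("extended mode requires all_best_datasets")
        pooled: list[GenomicInterval] = []
        for ds in all_best_datasets:
            pooled.extend(ds)
        reference = PeakSet(pooled)
    else:
        reference = best_dataset
    return intersect_peaks(reference, cell_peaks)


def _decay_terms(centers: np.ndarray, tss: int, d0: float, cutoff: float) -> np.ndarray:
    d = np.abs(centers - tss)
    d = d[d <= cutoff]
    return np.power(2.0, -d / d0)


def rp_score(
    tr_peaks: PeakSet,
    genes: Sequence[GeneModel],
    d0: float,
    model: str = "simple",
    cutoff_multiplier: float = DEFAULT_CUTOFF_MULTIPLIER,
) -> pd.Series:
    """Regulatory-potential score of every gene for one peak set (one cell).

    Simple model: for each gene, sum ``2**(-d/d0)`` over peaks whose centers
    lie within ``cutoff_multiplier * d0`` of the TSS.  Enhanced model applies
    the exon and nearby-gene rules documented in the module docstring; it
    reduces exactly to the simple model when neither rule fires.
    """
    if model not in ("simple", "enhanced"):
        raise ValueError(f"unknown RP model {model!r}")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    cutoff = cutoff_multiplier * d0

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in tr_peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    centers = {
        c: np.asarray([iv.center for iv in ivs]) for c, ivs in by_chrom.items()
    }

    scores = pd.Series(0.0, index=[g.symbol for g in genes], name="rp")
    if model == "simple":
        for g in genes:
            cs = centers.get(g.chrom)
            if cs is None:
                continue
            scores[g.symbol] = float(_decay_terms(cs, g.tss, d0, cutoff).sum())
        return scores

    # enhanced model: per-gene peak walk with the exon / nearby-gene rules
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for g in genes:
        peaks_here = by_chrom.get(g.chrom, [])
        if not peaks_here:
            continue
        others = [o for o in genes_by_chrom.get(g.chrom, []) if o.symbol != g.symbol]
        total = 0.0
        for iv in peaks_here:
            d = abs(iv.center - g.tss)
            if d > cutoff:
                continue
            if any(iv.overlaps(e) for e in g.exons):
                exon_kb = g.total_exon_length / 1000.0
                if exon_kb <= 0:
                    raise ValueError(
                        f"{g.symbol}: exon rule fired but total exon length is 0"
                    )
                total += 1.0 / exon_kb
                continue
            foreign = any(
                iv.overlaps(o.promoter) or any(iv.overlaps(e) for e in o.exons)
                for o in others
            )
            if foreign:
                continue
            total += 2.0 ** (-d / d0)
        scores[g.symbol] = total
    return scores


def rp_matrix(
    cells: CellPeakMatrix,
    index: ReferenceIndex,
    best_match: pd.DataFrame,
    factor: str,
    genes: Sequence[GeneModel],
    d0: float | str = "auto",
    model: str = "simple",
    extended: bool = False,
    cutoff_multiplier: float = DEFAULT_CUTOFF_MULTIPLIER,
) -> pd.DataFrame:
    """Gene-by-cell RP matrix for one TR.

    ``best_match`` is the long-format (cell, factor, dataset_id) table from
    the enrichment step; each cell's binding sites are imputed from its own
    best-matched dataset.  ``d0='auto'`` classifies the TR from the pooled
    best-match reference peaks.
    """
    bm = best_match.loc[best_match["factor"] == factor]
    if bm.empty:
        raise ValueError(f"no best-match assignments for factor {factor!r}")
    bm = bm.set_index("cell")["dataset_id"]
    missing = [b for b in cells.barcodes if b not in bm.index]
    if missing:
        raise ValueError(
            f"missing best-match assignment for {len(missing)} cell(s), "
            f"e.g. {missing[:3]}"
        )
    used_ids = sorted(set(bm.loc[cells.barcodes]))
    used_sets = {ds_id: index.get(ds_id).peaks for ds_id in used_ids}
    if d0 == "auto":
        pooled = PeakSet([iv for ds_id in used_ids for iv in used_sets[ds_id]])
        d0 = auto_half_decay(pooled, genes)
    d0 = float(d0)

    cols = {}
    all_sets = list(used_sets.values())
    for i, barcode in enumerate(cells.barcodes):
        cell_peaks = cells.cell_peaks(i)
        imputed = impute_tr_peaks(
            cell_peaks,
            used_sets[bm[barcode]],
            extended=extended,
            all_best_datasets=all_sets if extended else None,
        )
        cols[barcode] = rp_score(
            imputed, genes, d0, model=model, cutoff_multiplier=cutoff_multiplier
        )
    out = pd.DataFrame(cols)
    out.index.name = "gene"
    return out


def rank_targets(
    rp: pd.DataFrame | pd.Series, top_n: int, agg: str = "mean"
) -> list[str]:
    """Top target genes by aggregate RP (descending; ties by gene symbol).

    Genes with zero aggregate RP are never reported, so the result may be
    shorter than ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if isinstance(rp, pd.DataFrame):
        scores = rp.mean(axis=1) if agg == "mean" else rp.max(axis=1)
    else:
        scores = rp
    scores = scores[scores > 0]
    ranked = scores.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[:top_n].tolist()


def differential_targets(
    rp_group_a: pd.DataFrame,
    rp_group_b: pd.DataFrame,
    logfc_cutoff: float = 0.25,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Differential TR targets between two cell groups.

    RP scores are ln(1+x)-normalised; each cell is then scaled to mean 0 /
    unit variance.  Per gene, a two-sided rank-sum test compares the scaled
    values between groups and the log fold change is the difference of the
    ln-scale group means.  A gene is significant when |logFC| >= 0.25 and
    P <= 0.01 (both inclusive).  Genes with zero RP in every cell of both
    groups are removed first.
    """
    for name, g in (("A", rp_group_a), ("B", rp_group_b)):
        if g.shape[1] < 3:
            raise ValueError(f"group {name} has {g.shape[1]} cells; need >= 3")
    common = rp_group_a.index
    if not common.equals(rp_group_b.index):
        raise ValueError("the two RP matrices index different genes")

    nonzero = (rp_group_a.sum(axis=1) + rp_group_b.sum(axis=1)) > 0
    a = np.log1p(rp_group_a.loc[nonzero].to_numpy(dtype=float))
    b = np.log1p(rp_group_b.loc[nonzero].to_numpy(dtype=float))

    def _scale_cells(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=0, keepdims=True)
        return np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)

    a_s, b_s = _scale_cells(a), _scale_cells(b)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        pvals[i] = ranksums(a_s[i], b_s[i]).pvalue
    out = pd.DataFrame(
        {
            "gene": common[nonzero],
            "logFC": logfc,
            "p": pvals,
            "significant": (np.abs(logfc) >= logfc_cutoff) & (pvals <= p_cutoff),
        }
    ).set_index("gene")
    return out


@dataclass
class GRN:
    """A weighted TR -> target-gene edge set with cell-type context."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tr", "gene", "weight", "context"])
    )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> list[str]:
        return sorted(self.edges["gene"].unique())

    @property
    def trs(self) -> list[str]:
        return sorted(self.edges["tr"].unique())


def build_grn(
    rp_matrices: Mapping[str, pd.DataFrame],
    cell_labels: pd.Series | Mapping[str, str],
    top_cells: int = 500,
    top_n: int = 1000,
    agg: str = "max",
) -> GRN:
    """Cell-type-contextual GRN from per-TR RP matrices.

    Per (TR, cell type): keep the ``top_cells`` cells with the highest total
    RP (all of them when fewer), aggregate gene scores across those cells
    (``max`` default, ``mean`` optional), and emit the ``top_n`` ranked
    targets as weighted edges.  Every cell in every RP matrix must be
    labelled.
    """
    labels = pd.Series(cell_labels)
    rows = []
    for tr, rp in rp_matrices.items():
        unknown = [c for c in rp.columns if c not in labels.index]
        if unknown:
            raise ValueError(
                f"{len(unknown)} cell(s) of TR {tr!r} have no label, "
                f"e.g. {unknown[:3]}"
            )
        for ctype in sorted(labels.loc[rp.columns].unique()):
            sub = rp.loc[:, labels.loc[rp.columns] == ctype]
            keep = (
                sub.sum(axis=0)
                .sort_values(ascending=False, kind="stable")
                .index[: min(top_cells, sub.shape[1])]
            )
            sub = sub.loc[:, keep]
            scores = sub.max(axis=1) if agg == "max" else sub.mean(axis=1)
            for gene in rank_targets(scores, top_n):
                rows.append((tr, gene, float(scores[gene]), ctype))
    edges = pd.DataFrame(rows, columns=["tr", "gene", "weight", "context"])
    return GRN(edges)
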