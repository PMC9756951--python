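"""Seeded generators for toy regulatory worlds.

The generator plants the statistical structure the method assumes: each cell
type is driven by one transcription regulator whose binding sites are open
preferentially in cells of that type.  A toy genome of two 10-Mb chromosomes
carries per-factor disjoint "true" binding-site sets; each factor gets one or
more reference ChIP-like datasets drawn from its true sites; cells of a type
open their factor's sites at a high signal rate and everything else at a
strictly lower background rate.  Gene models with TSSs and exons are laid
down on the same genome so the RP machinery is exercised end to end.

Everything is derived from one integer seed; regeneration with the same
parameters and seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from screg.intervals import GenomicInterval, PeakSet, ReferenceIndex
from screg.matrix import CellPeakMatrix
from screg.reference import QC_THRESHOLDS, build_index
from screg.targets import GeneModel

__all__ = ["ToyWorld", "make_toy_world", "make_qc_table", "make_rp_groups"]

DEFAULT_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}


@dataclass
class ToyWorld:
    """A self-contained synthetic dataset with known ground truth."""

    genome: dict[str, int]
    genes: list[GeneModel]
    index: ReferenceIndex
    cells: CellPeakMatrix
    cell_types: pd.Series  # barcode -> planted type
    factor_of_type: dict[str, str]  # planted type -> driving factor
    seed: int
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        """Write every piece in its on-disk exchange format (matrix dir,
        index dir, gene TSV, ground-truth TSV/JSON)."""
        from screg.io import write_cell_matrix
        from screg.reference import save_index

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_cell_matrix(self.cells, path / "matrix")
        save_index(self.index, path / "index")
        with open(path / "genes.tsv", "w") as fh:
            for g in self.genes:
                ex_s = ",".join(str(e.start) for e in g.exons) + ","
                ex_e = ",".join(str(e.end) for e in g.exons) + ","
                tx_start = min((e.start for e in g.exons), default=g.tss)
                tx_end = max((e.end for e in g.exons), default=g.tss + 1)
                fh.write(
                    f"{g.symbol}\t{g.chrom}\t{g.strand}\t{tx_start}\t{tx_end}"
                    f"\t{ex_s}\t{ex_e}\n"
                )
        self.cell_types.rename("cell_type").to_csv(
            path / "cell_types.tsv", sep="\t", header=True, index_label="barcode"
        )
        with open(path / "truth.json", "w") as fh:
            json.dump(
                {
                    "factor_of_type": self.factor_of_type,
                    "seed": self.seed,
                    "params": self.params,
                    "genome": self.genome,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return path


def _plant_sites(
    rng: np.random.Generator,
    genome: dict[str, int],
    n_factors: int,
    sites_per_factor: int,
    site_width: int,
) -> list[list[GenomicInterval]]:
    """Disjoint per-factor site sets laid out on a jittered grid so no two
    factors' sites ever overlap."""
    chroms = list(genome)
    total = n_factors * sites_per_factor
    pitch = sum(genome.values()) // total
    if pitch <= site_width + 2:
        raise ValueError(
            f"infeasible geometry: {total} sites of {site_width} bp do not fit "
            f"a {sum(genome.values())} bp genome"
        )
    slots = []
    offset = 0
    for chrom in chroms:
        n_here = genome[chrom] // pitch
        for s in range(n_here):
            slots.append((chrom, s * pitch))
        offset += n_here
    slots = slots[:total]
    order = rng.permutation(len(slots))
    sites: list[list[GenomicInterval]] = [[] for _ in range(n_factors)]
    for rank, slot_i in enumerate(order):
        chrom, base = slots[slot_i]
        jitter = int(rng.integers(0, max(1, pitch - site_width - 1)))
        iv = GenomicInterval(chrom, base + jitter, base + jitter + site_width)
        sites[rank % n_factors].append(iv)
    return [sorted(s) for s in sites]


def make_toy_world(
    n_cell_types: int = 3,
    cells_per_type: int = 50,
    peaks_per_dataset: int = 300,
    noise_rate: float = 0.1,
    signal_rate: float = 0.6,
    datasets_per_factor: int = 2,
    n_genes: int = 60,
    site_width: int = 500,
    genome: dict[str, int] | None = None,
    seed: int = 0,
) -> ToyWorld:
    """Generate a seeded toy world with planted cell-type-specific TR signal.

    Each of ``n_cell_types`` planted types is driven by one factor; every
    factor receives ``datasets_per_factor`` reference datasets subsampled
    from its true sites.  Cells open their own factor's sites with
    probability ``signal_rate`` and all other features with probability
    ``noise_rate`` (which must be strictly smaller).
    """
    if not (0 <= noise_rate < 1):
        raise ValueError("noise_rate must be in [0, 1)")
    if noise_rate >= signal_rate:
        raise ValueError("background noise_rate must be < signal_rate")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)

    factors = [f"TF{chr(ord('A') + t)}" for t in range(n_cell_types)]
    site_sets = _plant_sites(
        rng, genome, n_cell_types, peaks_per_dataset, site_width
    )

    # reference datasets: subsamples of each factor's true sites
    tr_peaksets: dict[str, PeakSet] = {}
    metadata: dict[str, dict] = {}
    for t, factor in enumerate(factors):
        for r in range(datasets_per_factor):
            frac = 1.0 if r == 0 else 0.8
            n_keep = max(1, int(round(frac * len(site_sets[t]))))
            keep = np.sort(
                rng.choice(len(site_sets[t]), size=n_keep, replace=False)
            )
            ds_id = f"{factor}_ds{r}"
            tr_peaksets[ds_id] = PeakSet([site_sets[t][i] for i in keep])
            metadata[ds_id] = {
                "factor": factor,
                "cell_type": f"type{t}",
                "species": "toy",
            }
    index = build_index(tr_peaksets, metadata)

    # feature space: all planted sites (disjoint by construction)
    features: list[GenomicInterval] = sorted(
        iv for sites in site_sets for iv in sites
    )
    feat_factor = np.empty(len(features), dtype=int)
    site_lookup = {iv: t for t, sites in enumerate(site_sets) for iv in sites}
    for i, iv in enumerate(features):
        feat_factor[i] = site_lookup[iv]

    barcodes: list[str] = []
    types: list[str] = []
    cols = []
    for t in range(n_cell_types):
        own = feat_factor == t
        for c in range(cells_per_type):
            p = np.where(own, signal_rate, noise_rate)
            col = (rng.random(len(features)) < p).astype(np.int8)
            cols.append(col)
            barcodes.append(f"type{t}_cell{c:03d}")
            types.append(f"type{t}")
    counts = sp.csc_matrix(np.stack(cols, axis=1))
    cells = CellPeakMatrix(features, barcodes, counts)

    # gene models along the genome: TSS near planted sites so RP scores are
    # non-trivial; two exons per gene
    genes: list[GeneModel] = []
    flat_sites = features
    pick = rng.choice(len(flat_sites), size=min(n_genes, len(flat_sites)), replace=False)
    for gi, si in enumerate(np.sort(pick)):
        anchor = flat_sites[si]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = max(0, anchor.start + int(rng.integers(-2000, 2000)))
        exon1 = GenomicInterval(anchor.chrom, tss + 200, tss + 400)
        exon2 = GenomicInterval(anchor.chrom, tss + 1200, tss + 1500)
        genes.append(GeneModel(f"gene{gi:03d}", anchor.chrom, strand, tss, (exon1, exon2)))

    return ToyWorld(
        genome=genome,
        genes=genes,
        index=index,
        cells=cells,
        cell_types=pd.Series(types, index=barcodes, name="cell_type"),
        factor_of_type={f"type{t}": factors[t] for t in range(n_cell_types)},
        seed=seed,
        params={
            "n_cell_types": n_cell_types,
            "cells_per_type": cells_per_type,
            "peaks_per_dataset": peaks_per_dataset,
            "noise_rate": noise_rate,
            "signal_rate": signal_rate,
            "datasets_per_factor": datasets_per_factor,
        },
    )


_QC_PASS = {
    "median_quality": 30.0,
    "unique_map_frac": 0.8,
    "pbc": 0.9,
    "fold10_peaks": 500,
    "frip": 0.2,
    "top5k_dhs_frac": 0.9,
}
_QC_FAIL = {
    "median_quality": 20.0,
    "unique_map_frac": 0.4,
    "pbc": 0.5,
    "fold10_peaks": 50,
    "frip": 0.005,
    "top5k_dhs_frac": 0.5,
}


def make_qc_table(spec: dict[str, str | None]) -> pd.DataFrame:
    """Synthesize a QC table from ``{dataset_id: failing_metric_or_None}``.

    Each requested failing metric is set strictly below its threshold and all
    other metrics strictly above theirs, so the retention pattern under the
    QC filter is exactly the datasets mapped to ``None``.
    """
    rows = []
    for ds_id, fail in spec.items():
        if fail is not None and fail not in QC_THRESHOLDS:
            raise ValueError(f"unknown QC metric {fail!r} for {ds_id}")
        row = {"dataset_id": ds_id, **_QC_PASS}
        if fail is not None:
            row[fail] = _QC_FAIL[fail]
        rows.append(row)
    return pd.DataFrame(rows)


def make_rp_groups(
    n_genes: int = 200,
    n_shifted: int = 20,
    n_cells: int = 50,
    fold: float = 2.0,
    n_zero: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two gene-by-cell RP matrices with a planted fold shift.

    Baseline per-gene RP levels are gamma-distributed; the first
    ``n_shifted`` genes are scaled by ``fold`` in group A only, and
    ``n_zero`` genes are zero everywhere (they must be dropped by the
    differential test).  Returns ``(rp_a, rp_b, shifted_gene_names)``.
    """
    rng = np.random.default_rng(seed)
    names = [f"g{i:03d}" for i in range(n_genes + n_zero)]
    base = rng.gamma(shape=4.0, scale=1.0, size=n_genes)
    noise = lambda n: rng.gamma(shape=8.0, scale=1.0 / 8.0, size=(n_genes, n))
    a = base[:, None] * noise(n_cells)
    b = base[:, None] * noise(n_cells)
    a[:n_shifted] *= fold
    zeros = np.zeros((n_zero, n_cells))
    cols_a = [f"a{i:02d}" for i in range(n_cells)]
    cols_b = [f"b{i:02d}" for i in range(n_cells)]
    rp_a = pd.DataFrame(np.vstack([a, zeros]), index=names, columns=cols_a)
    rp_b = pd.DataFrame(np.vstack([b, zeros]), index=names, columns=cols_b)
    return rp_a, rp_b, names[:n_shifted]
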