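"""Readers and writers for the standard formats the pipeline consumes.

BED (gzip-transparent), Matrix Market cell-matrix directories, dense TSV
matrices, refGene-style gene tables and GTF.  Feature identifiers in matrix
files may use ``chr:start-end``, ``chr_start_end`` or three-column TSV; all
are normalised to 0-based half-open intervals internally.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Sequence

import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from screg.intervals import GenomicInterval, PeakSet
from screg.matrix import CellPeakMatrix
from screg.targets import GeneModel

__all__ = [
    "read_bed",
    "write_bed",
    "parse_feature_string",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_refgene",
    "read_gtf",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, extra_names: Sequence[str] | None = None) -> PeakSet:
    """Read a BED3+ file (gzip transparent); comment/track/browser lines are
    skipped.  Columns beyond the third become attributes, named ``col4``,
    ``col5``, ... unless ``extra_names`` supplies names (e.g. ``["fold"]``
    for a peak file whose 4th column is fold enrichment)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    extras: list[list[str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {parts[1]!r}/{parts[2]!r}"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: malformed interval {parts[0]}:{start}-{end}"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            extras.append(parts[3:])
    attrs = None
    n_extra = max((len(e) for e in extras), default=0)
    if n_extra:
        cols = {}
        for i in range(n_extra):
            col = [e[i] if len(e) > i else "" for e in extras]
            try:
                col = [float(v) for v in col]
            except ValueError:
                pass
            name = (
                extra_names[i]
                if extra_names is not None and i < len(extra_names)
                else f"col{i + 4}"
            )
            cols[name] = col
        attrs = cols
    return PeakSet.from_arrays(chroms, starts, ends, attrs=attrs)


def write_bed(peaks: PeakSet, path: str | Path) -> Path:
    """Write a PeakSet as sorted BED (gzip when the path ends in .gz); extra
    attributes become additional columns in their dict order."""
    path = Path(path)
    peaks = peaks.sort()
    attr_names = list(peaks.attrs)
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(peaks):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            cols += [str(peaks.attrs[a][i]) for a in attr_names]
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# cell matrices

_FEATURE_RE = re.compile(
    r"^(?P<chrom>[^:_]+)[:_](?P<start>\d+)[-_](?P<end>\d+)$"
)


def parse_feature_string(s: str) -> GenomicInterval:
    """Parse ``chr:start-end`` or ``chr_start_end`` into an interval."""
    m = _FEATURE_RE.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse feature identifier {s!r}")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


def _read_features_file(path: Path) -> list[GenomicInterval]:
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    features = []
    for lineno, ln in enumerate(lines, 1):
        parts = ln.split("\t")
        if len(parts) >= 3:
            try:
                features.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                )
                continue
            except ValueError:
                pass
        features.append(parse_feature_string(parts[0]))
    return features


def read_cell_matrix(path: str | Path) -> CellPeakMatrix:
    """Read a cell matrix.

    ``path`` may be a directory holding ``matrix.mtx(.gz)`` +
    ``peaks.bed``/``features.tsv`` + ``barcodes.tsv``, or a dense TSV whose
    row index is a feature identifier and whose columns are barcodes.
    """
    path = Path(path)
    if path.is_dir():
        mtx = next(
            (path / n for n in ("matrix.mtx", "matrix.mtx.gz") if (path / n).exists()),
            None,
        )
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx(.gz) in {path}")
        feats = next(
            (
                path / n
                for n in ("peaks.bed", "features.tsv", "features.tsv.gz", "peaks.bed.gz")
                if (path / n).exists()
            ),
            None,
        )
        if feats is None:
            raise FileNotFoundError(f"no peaks.bed / features.tsv in {path}")
        barcodes_path = next(
            (path / n for n in ("barcodes.tsv", "barcodes.tsv.gz") if (path / n).exists()),
            None,
        )
        if barcodes_path is None:
            raise FileNotFoundError(f"no barcodes.tsv in {path}")
        counts = sp.csc_matrix(sio.mmread(str(mtx)))
        features = _read_features_file(feats)
        with _open_text(barcodes_path) as fh:
            barcodes = [ln.strip() for ln in fh if ln.strip()]
        if counts.shape[0] != len(features) or counts.shape[1] != len(barcodes):
            raise ValueError(
                f"dimension mismatch: matrix is {counts.shape}, "
                f"{len(features)} features, {len(barcodes)} barcodes"
            )
        return CellPeakMatrix(features, barcodes, counts)
    df = pd.read_csv(path, sep="\t", index_col=0)
    features = [parse_feature_string(s) for s in df.index]
    return CellPeakMatrix(features, list(df.columns), sp.csc_matrix(df.to_numpy()))


def write_cell_matrix(cells: CellPeakMatrix, path: str | Path) -> Path:
    """Write a matrix directory (matrix.mtx + peaks.bed + barcodes.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(path / "matrix.mtx"), cells.counts.tocoo())
    with open(path / "peaks.bed", "w") as fh:
        for iv in cells.features:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(cells.barcodes) + "\n")
    return path


# ---------------------------------------------------------------------------
# gene annotation

def read_refgene(path: str | Path) -> list[GeneModel]:
    """Read a refGene-style TSV: name, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated lists).  The TSS is txStart for
    plus-strand genes and txEnd for minus-strand genes.  One model per gene
    symbol (first occurrence wins)."""
    seen: dict[str, GeneModel] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns")
            name, chrom, strand = parts[0], parts[1], parts[2]
            tx_start, tx_end = int(parts[3]), int(parts[4])
            ex_starts = [int(x) for x in parts[5].rstrip(",").split(",") if x]
            ex_ends = [int(x) for x in parts[6].rstrip(",").split(",") if x]
            exons = tuple(
                GenomicInterval(chrom, s, e) for s, e in zip(ex_starts, ex_ends)
            )
            tss = tx_start if strand == "+" else tx_end
            seen.setdefault(name, GeneModel(name, chrom, strand, tss, exons))
    return list(seen.values())


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF: TSS from the gene/transcript extent,
    exons from exon features, grouped by ``gene_name`` (``gene_id``
    fallback)."""
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    tx: dict[str, dict] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs_s = parts[:9]
            attrs = dict(attr_re.findall(attrs_s))
            name = attrs.get("gene_name") or attrs.get("gene_id")
            if name is None:
                continue
            rec = tx.setdefault(
                name,
                {"chrom": chrom, "strand": strand, "lo": None, "hi": None, "exons": []},
            )
            lo, hi = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature in ("gene", "transcript"):
                rec["lo"] = lo if rec["lo"] is None else min(rec["lo"], lo)
                rec["hi"] = hi if rec["hi"] is None else max(rec["hi"], hi)
            elif feature == "exon":
                rec["exons"].append(GenomicInterval(chrom, lo, hi))
                rec["lo"] = lo if rec["lo"] is None else min(rec["lo"], lo)
                rec["hi"] = hi if rec["hi"] is None else max(rec["hi"], hi)
    genes = []
    for name, rec in tx.items():
        if rec["lo"] is None:
            continue
        tss = rec["lo"] if rec["strand"] == "+" else rec["hi"]
        genes.append(
            GeneModel(name, rec["chrom"], rec["strand"], tss, tuple(rec["exons"]))
        )
    return genes
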