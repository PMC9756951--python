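# Methods

## Problem and model

Single-cell ATAC-seq measures chromatin accessibility, not the binding of
specific transcription regulators (TRs).  `screg` infers per-cell TR activity
by asking, for every cell, how strongly its accessible regions overlap each
peak set in a curated reference of TR ChIP-seq experiments and motif-derived
pseudo-peak sets, and then identifies each TR's candidate target genes with a
distance-decay regulatory-potential (RP) model applied to the TR's imputed
binding sites in that cell.

### Overlap counting

All coordinates are BED-convention 0-based half-open intervals.  Two
intervals overlap iff they share at least one base pair; abutting intervals
do not.  The overlap count between a cell's peaks and a reference dataset is
the number of intersecting *pairs* (one cell peak hitting three reference
peaks contributes three), the row semantics of `bedtools intersect`.
Duplicate reference intervals are retained and each counts.  Strand is
ignored.

The engine stores, per chromosome, sorted arrays of reference starts and
ends; a query `[s, e)` intersects exactly `#{starts < e} − #{ends ≤ s}`
reference intervals, which two binary searches provide.  The full
dataset-by-cell matrix `M` is assembled as `C.T @ B`, where `C[f, j]` is the
pair count of feature `f` against dataset `j` and `B` the binarised
feature-by-cell matrix; this is exact because every cell's peak set is a
subset of the shared feature list.  Exactness is enforced in the test suite
against a quadratic all-pairs oracle and cross-checked against
`bedtools intersect -c`.

### Reference curation

ChIP-seq datasets are retained only if all quality metrics strictly exceed
their bounds: median raw-sequence quality > 25, uniquely-mapped fraction
> 0.5, PCR bottleneck coefficient > 0.8, number of 10-fold peaks > 100,
FRiP > 0.01, and > 70% of the top-5000 peaks overlapping union DHS.  Within
a retained dataset only peaks with fold enrichment ≥ 5 are kept (a "5-fold
peak" passes its own definition, so the bound is inclusive), and datasets
left with fewer than 1000 peaks are dropped.

Motif scan hits are converted to ChIP-comparable pseudo-peaks: a hit is kept
if it overlaps ENCODE ccRE **or** union DHS (OR maximises retention; the
source procedure does not state AND vs OR), dropped if it touches the
blacklist, then extended symmetrically about its midpoint to 340 bp — the
average ChIP peak width — with the extra base pair going left when the
required extension is odd, clipped at position 0.  Because extension can
move a site into the blacklist, the blacklist is re-checked after extension.
Sites already ≥ 340 bp are left unchanged (real scan hits are 6–25 bp;
shrinking would discard evidence).  If more than 25 000 sites survive, the
25 000 with smallest scan p-values are kept; the cap is applied after the
region filters, so it reflects the sites that can actually contribute.
Filtering happens on the original scanned coordinates and extension
afterwards, so extension cannot retroactively create qualifying overlaps.

### Activity scoring

With `M[j, i]` the overlap count of cell *i* against dataset *j*:

1. **Depth/size normalisation.**  `M'[j, i] = M[j, i] / (D_j · Q_i)`, where
   `D_j` is dataset *j*'s peak count and `Q_i` the cell's accessible base
   pairs per 10⁸ (summed widths of its nonzero features — binarisation at
   count > 0, not read counts).
2. **Per-dataset centering.**  `M''[j, ·] = M'[j, ·] − mean_cells(M'[j, ·])`,
   making different TR datasets comparable.
3. **Deduplication.**  For each factor, each cell keeps the dataset with the
   largest centered score (its *best match*; ties go to the lowest dataset
   id for determinism).  An `average` strategy is provided; it defines no
   best match.
4. **Sigmoid compression.**  Per TR, scores are z-scored across cells and
   passed through the logistic sigmoid, mapping into (0, 1); a
   zero-variance TR falls back to 0.5 with a warning.
5. **Per-cell z-score.**  Each cell's TR profile is scaled to mean 0 /
   std 1, giving all cells the same dynamic range.

All standard deviations use the population (n) denominator.  A useful
consequence, covered by a test: rescaling every `D_j` by a constant shifts
`M'` uniformly and leaves the final activity unchanged.

Optionally, before any scoring, each cell's sparse binary profile is pooled
with its k nearest neighbor cells (binary union).  Neighbors are found by
cosine distance in a TF-IDF + truncated-SVD (LSI, 50 components) embedding
of the binarised matrix — the standard scATAC reduction.  The original
procedure does not publish its smoothing parameters; k = 20, cosine/LSI and
union aggregation are this package's defaults and are all configurable.
Smoothing precedes the whole scoring chain, and `Q` is recomputed from the
smoothed profiles.

### Target genes: the regulatory-potential model

For one cell and one TR, binding sites are imputed as the peaks of the
cell's best-matched dataset that overlap ≥ 1 of the cell's accessible
regions (an `extended` mode pools every dataset that is best match for at
least one cell of the TR before intersecting).  A gene's RP is

    S_g = Σ_i 2^(−d_i / d0)

summing over imputed sites whose centers lie within `15·d0` of the gene's
TSS, with `d_i` the center-to-TSS distance.  A site beyond `15·d0` would
contribute < 2⁻¹⁵ ≈ 3·10⁻⁵ < 0.0005, so the truncation is numerically
irrelevant; the bound is asserted in the tests.  `d0` is the half-decay
distance: `auto` (default) classifies the TR by the fraction of its
reference peaks overlapping promoter windows (TSS ± 1 kb, 2001 bp unless
clipped at 0) — strictly more than 20% makes it promoter-type with
`d0 = 1 kb`, otherwise enhancer-type with `d0 = 10 kb`.  The fraction
counts peaks *overlapping* promoters (not centers inside them), and the
auto classification uses the pooled best-match reference peaks so the
choice is stable across cells.

The **enhanced** model adds two rules: a site inside one of the gene's own
exons contributes `1 / (total exon length of the gene in kb)` instead of
the decay term (the kb unit keeps magnitudes comparable to decay
contributions; configurable), and a site inside the promoter or exons of a
*different* gene within the same `15·d0` window contributes 0.  When
neither rule fires the enhanced model equals the simple one exactly.  The
simple model with `auto` half-decay is the default.

### Differential targets and GRNs

Given per-TR RP matrices for two cell groups (≥ 3 cells each), genes with
zero RP in every cell of both groups are removed, scores are ln(1+x)
transformed and each cell is scaled to zero mean / unit variance.  Per
gene, a two-sided Wilcoxon rank-sum test compares the scaled values; the
log fold change is the difference of ln-scale group means (before per-cell
scaling, so it keeps its fold interpretation).  A gene is significant when
|logFC| ≥ 0.25 and P ≤ 0.01, both inclusive.

GRNs are built per (TR, cell type): the 500 cells with the highest total RP
are retained (all of them when fewer), gene scores are aggregated across
those cells (max by default — a pile-up-style summary — with mean as an
option), and the top 1000 ranked targets become weighted TR→gene edges
annotated with the cell-type context.  Ranking is by descending aggregate
RP with ties broken alphabetically; zero-RP genes are never reported.

## Synthetic data

`screg.simulate.make_toy_world` generates the structure the method assumes:
a 2 × 10 Mb toy genome; per planted cell type one driving factor with 300
disjoint 500-bp true binding sites (sites of different factors never
overlap, placed on a jittered grid); two reference datasets per factor
subsampled from its true sites (100% and 80%); 50 cells per type opening
their own factor's sites with probability 0.6 and every other feature at a
background rate of 0.1; and 60 two-exon gene models anchored near planted
sites so RP scores are non-trivial.  Everything derives from one integer
seed and regenerates bit-identically.

What the toy world does *not* emulate: fragment-level properties (Tn5
sequence bias, duplication), peak-calling noise, overlapping reference
peaks across factors, doublets, or realistic genome scale.  Passing the
planted-recovery tests therefore shows that the statistical chain separates
factor-specific signal from uniform background noise at these rates; it
does not certify performance on real scATAC-seq data.

`make_rp_groups` simulates gene-by-cell RP matrices directly (per-gene
gamma baselines, multiplicative gamma noise, a 2-fold shift planted in 20
genes, 50 cells per group, plus all-zero genes that must be dropped) to
exercise the differential-target procedure against known truth.

## Numerical choices and edge cases

- Degenerate intervals (end ≤ start) and negative starts are rejected at
  construction, naming the offending record.
- Empty cells produce zero overlap rows and a logged warning, not an error;
  zero `D_j` or `Q_i` raise, naming the dataset/cell, because the
  normalisation quotient is undefined.
- Constant TRs (sigmoid) and constant cells (final z-score) fall back to
  0.5 and 0 respectively, with warnings.
- Argmax ties in deduplication go to the lowest dataset id; target-rank
  ties go to the alphabetically first gene symbol.
- TSVs are written with a fixed `%.10g` float format so identical seeds
  yield byte-identical outputs.

## Problem sizes

The bundled tests and the acceptance script run entirely on synthetic data:
overlap exactness on 50 random instances of up to 1000 intervals per side,
activity recovery on a 150-cell / 6-dataset world, differential recovery on
200 genes × 100 cells.  These sizes were chosen so the whole suite
completes in seconds while still exercising multi-chromosome indexing,
clipping and sparse-matrix paths; the engine itself is vectorised and
scales to realistically sized matrices.

## Known limitations

- QC metrics are consumed, not computed: the builder expects the seven
  metrics per dataset and does not derive them from reads.
- PWM scanning is out of scope; the motif pipeline starts from already
  scanned sites with p-values.
- The package performs no clustering, embedding, pseudotime or GO analysis
  of its outputs; the activity and RP matrices are meant to feed standard
  single-cell tooling.
- Best-match selection is winner-takes-all per cell; cells mixing two
  tissue states inherit a single dataset's peak set.
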