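# Methods

This note documents the models behind `clonetrace`, the parameters that
matter, the design choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Barcode evidence model

The unit of evidence is the **triple** (cell barcode, UMI, lineage barcode)
with a read count: one transcript molecule from the barcode transgene,
sequenced some number of times. Extraction from read-2 FASTQ trims the
sequence left and right of the lineage barcode by exact flank matching (a
Hamming tolerance is available, default 0, since barcode chemistry gives no
principled mismatch budget) and discards inserts shorter than **37 bp** —
shorter inserts are truncation artefacts, not library barcodes. The cell
barcode and UMI ride in the read name, and only cells present in the
expression dataset's whitelist are kept.

Filtering order is fixed and documented because it is not forced by the
definitions: extract → length filter → aggregate identical observations →
**≥ 10 reads per triple** → **≥ 6 distinct UMIs per cell–barcode pair**.
The read rule removes PCR/sequencing noise at the molecule level; the UMI
rule demands independent molecular evidence before a barcode is credited to
a cell. UMIs are counted as distinct strings with no 1-mismatch collapse
(no UMI error model is assumed). Both thresholds are parameters and every
stage logs in/out counts. Raising either threshold can only shrink the
surviving pair set (a property test).

## Clone calling

Cells are partitioned by agglomerative **average linkage** on **Jaccard
distance** between barcode sets, cutting the dendrogram at `cut_height`
(default 0.5). A founder typically carries several independent integrations,
so cells of one clone share a multi-barcode set; 0.5 merges cells sharing
the majority of their integrations (including partial-capture subsets at
distance exactly 0.5) while keeping single-barcode coincidences between
multi-barcode clones apart. No published cut height exists for this assay,
so `cut_height` is treated as the principal sensitivity parameter and is
logged with every run.

The agglomerator is implemented in the package rather than delegated to
`scipy.cluster.hierarchy.linkage` for one reason: determinism under ties.
Jaccard distances between small barcode sets are small-denominator rationals
and exact ties are the norm, and the contract here is that ties break by
lexicographic cell ID. Numerical choices that make this sound:

- cluster-pair distances are maintained as exact sums of the original
  pairwise distances divided by the pair count, so they equal the
  from-scratch average regardless of merge history;
- distances are rounded to 9 decimals before comparison, so mathematically
  equal averages compare equal across summation orders (distinct cluster
  distances on realistic instances differ by far more than 1e-9);
- two groups at distance exactly 1 (no shared barcode at all) never merge.
  Consequently `cut_height → 0` recovers the partition by exact barcode-set
  equality and `cut_height = 1` the connected components of the similarity
  graph.

Tests verify the implementation against an exhaustive-recomputation brute
force on random small matrices and against scipy on tie-free distance
matrices. Clones are called per dataset (per 10x reaction) by default —
barcodes are delivered per embryo, so identical barcodes in different
animals are library collisions; a cross-dataset mode exists but warns.

## Lineage coupling

A clone is **shared** between states a and b when it contains at least
`min_cells = 2` cells of each; the diagonal (a = a) counts clones with ≥ 2
cells of the state and carries the self-renewal/expansion signal. The null
distribution of the shared-count matrix comes from shuffling the cell→state
label vector uniformly over all cells (clone structure and marginal label
counts fixed), `n_permutations = 10,000` by default; z-scores are
(O − μ)/σ element-wise. Pairs whose permutation spread is zero are reported
as Z = 0 with an explicit mask. A stratified option shuffles within a
chosen column (e.g. dataset) instead of globally; global is the default.

Correlations between z-score rows use Pearson (Spearman available); for a
pair (a, b) the correlated vectors exclude the self-coupling entries, which
would otherwise trivially inflate similarity. Average-linkage clustering of
z-rows (Euclidean) provides the heatmap ordering. Results carry the seed,
the permutation count and the Monte-Carlo standard error σ/√n of each μ.

Two calibration facts, measured with the i.i.d. null generator and worth
knowing before interpreting real data:

- **Distinct-state pairs are well calibrated** when every state is common
  enough for shared counts to be non-degenerate (mean Z ≈ 0, var ≈ 1,
  |Z| > 1.96 in ≈ 5% of pairs). With rare states the null counts are tiny
  integers and Z is too discrete for normal-theory thresholds; the
  calibration experiments in the test suite therefore use a balanced
  six-state design (`null_calibration_config`, ~1,000 clones).
- **Self-coupling z-scores are over-dispersed under an i.i.d. null**
  (measured var ≈ 1.3, rejection ≈ 9%): the permutation null conditions on
  the observed label margins, while an unconditional null also varies the
  margins — and the diagonal is the statistic most sensitive to its own
  margin. Diagonal z-scores are reported (the expansion signal is real) but
  excluded from calibration checks and from correlation vectors.

## Clone composition

Composition summaries use presence thresholds at the clone level: a clone
"contains" a state given ≥ `presence_min` cells (default 1 — contents, not
coupling; the ≥ 2 rule applies only to shared-clone counts, and both are
explicit parameters). Three summaries:

- **Restricted vs mixed fractions**: among clones containing an anchor
  group (e.g. astrocytes), the fraction containing only that group vs also
  containing each combination of other groups. The anchor defines the
  denominator, matching the "astrocyte-only vs neuron + astrocyte mix"
  style of quantification.
- **Exclusive fate classification**: an ordered precedence list of
  (category, defining states) assigns each clone exactly one category, with
  a fallback (default `self_renewing`) for clones containing only
  progenitors. Precedence is user-supplied because exclusive categories
  that sum to 100% require a resolution rule the assay itself does not fix;
  the default order is astrocyte lineages before neurons so that rare
  astrocyte output is not hidden behind abundant neurons.
- **UpSet intersections**: clone counts per observed presence combination;
  counts sum to the number of eligible clones.

## Expression statistics

**Normalization**: x → ln(1 + s·x/total) per cell with s = 10,000. The
conservation identity Σ(exp(x′) − 1) = s per cell is asserted to 1e-9 in
tests. All-zero cells are an error naming the cell.

**PCA distance**: principal components are computed once on the whole
(per-gene standardized) log-normalized matrix; no highly-variable-gene
selection by default (available as an option), `n_components = 30`. The
subtype drift statistic D is the mean *pairwise* Euclidean distance in PC
space between reference-time cells and later-time cells of the subtype —
pairwise rather than centroid because centroid distance vanishes under pure
dispersal, which is exactly the kind of change the statistic should see; a
centroid mode is provided. The normalizer D_s is the mean cross-half
distance over `n_scrambles = 20` random halvings of the full dataset
(1 reproduces a literal single split; 20 averages away split noise). R =
D/D_s: ≈ 1 for i.i.d. groups, increasing in injected drift (both are
acceptance properties). Degenerate inputs (identical cells, groups < 2
cells, too many components) raise errors rather than returning NaN.

**Module score**: the standard binned-control score — genes ranked by mean
expression into `n_bins = 24` equal-occupancy bins; for each set gene,
`n_ctrl = 100` controls sampled from its bin (with replacement, excluding
the gene); score = mean(set) − mean(pooled controls) per cell. Seeded and
deterministic. A set indistinguishable from its expression-matched controls
scores ≈ 0; simulated marker sets rank their cell type with AUC > 0.9 at
the generator's default effect size.

## The synthetic-data generator

The generator emulates a dual-progenitor barcoding experiment and is the
ground-truth oracle for every stage. Generative model, in order:

1. **Founders**: configurable count per progenitor subtype (default
   250 + 250). Each founder draws k ≥ 1 integration barcodes (zero-truncated
   Poisson, mean 2 — the transposase gives no published copy distribution,
   so this is an explicit modeling choice) **with replacement** from a
   library of 10⁵ sequences (length 40 ≥ 37, so the length filter is
   exercisable), which makes inter-clone barcode collisions occur at the
   analytic birthday rate (~5 colliding pairs per 1,000 single-integration
   founders; a test checks the binomial interval).
2. **Clone fate**: drawn at the clone level from the subtype's fate profile
   (defaults above: the 90/5/5 and 50/34/16/0 structure), because exclusive
   clone-level categories are what downstream classification recovers.
   Member cell types then come from a category mixture: a clone of size ≥ 2
   always contains its residual progenitor and ≥ 1 cell of the defining
   lineage type (a size-1 clone is the single defining cell, or the
   progenitor for self-renewing clones); remaining cells are defining-type
   vs progenitor with `residual_progenitor_frac = 0.4`. That weight was set
   so the encoded RGC_2→Olig2 coupling is strong enough to stand out
   robustly (Z well above 3 at 500 clones) while neuron-linked clones stay
   neuron-dominated.
3. **Clone sizes**: zero-truncated Poisson with post-truncation mean 4.5
   (solved numerically for the rate).
4. **Capture noise**: a cell emits triples with probability 0.75
   (recovery); per recovered cell–barcode pair the UMI count is
   zero-truncated NB (mean 20, shape 10 — a highly expressed transgene
   yields tens of molecules); per-triple reads are zero-truncated NB (mean
   25, shape 2), placed so that ~15–20% of triples fall below the 10-read
   threshold and the filters do real work.
5. **Expression**: negative-binomial counts (shape 2) over log-normal gene
   means with log-normal cell depth (σ = 0.3); each cell type elevates its
   marker block by e^effect (effect 1.0). Minimal, but sufficient for the
   PCA-distance and module-score statistics.

`simulate_null` reuses the identical clone/barcode/noise machinery and then
redraws every cell's type i.i.d. from the pooled empirical type
frequencies, severing all clone–type association.

What the generator does **not** model: ambient RNA, doublets, PCR chimeras,
barcode sequencing errors (off by default; no error-correction procedure is
defined downstream), UMI errors, batch effects, or realistic transcriptome
structure beyond marker blocks. Passing recovery tests therefore shows the
statistics recover a known clonal structure under calibrated capture noise —
not that they are robust to every artefact of real libraries.

## Problem sizes and determinism

Default test/analysis sizes — 500–1,000 founders (~2,000–4,500 cells),
10,000 permutations, 30 PCs — were chosen so each statistic operates in the
regime where its asymptotics hold while any stage completes in seconds on a
laptop. Every stochastic operation takes an explicit integer seed, uses its
own `numpy` Generator, and fixes internal orderings (cells sorted
lexicographically, states sorted) so that a fixed seed reproduces every
output byte-for-byte; the pipeline manifest records the resolved config,
seeds and SHA-256 checksums of all outputs.

## Known limitations

- No probabilistic clone assignment or barcode error correction; a cell
  whose barcodes were all filtered out simply leaves the clonal analysis
  (reported in the drop count).
- No multiple-testing correction across state pairs; z-scores are
  descriptive screening statistics, as is conventional for this assay.
- The permutation null conditions on label margins (see the self-coupling
  caveat above).
- Cross-dataset clone calling is supported only with a collision warning;
  no inter-animal collision model is fitted.
- The eligibility rule for "clones of subtype X" (≥ 1 cell vs ≥ 2) is a
  parameter; with partial capture the choice measurably shifts exclusive
  fate fractions.
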