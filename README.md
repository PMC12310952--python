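# clonetrace

Clonal lineage-tracing analysis for barcoded single-cell transcriptomics.

`clonetrace` takes lineage-barcode evidence from a TrackerSeq-style
experiment — a piggyBac transposon library that stamps each progenitor with a
heritable semi-random oligonucleotide read out alongside the transcriptome —
and turns it into clone assignments and clonal-fate statistics. It is aimed at
developmental biologists asking *which progenitors make which cell types*:
for example, whether distinct radial-glia (RGC) subtypes feed distinct
astrocyte lineages in the developing cortex.

The package covers the full path:

1. **Barcode extraction and filtering** — read-2 FASTQ (or pre-extracted
   Cell–UMI–barcode triple tables) → flank trimming, a ≥ 37 bp barcode length
   filter, aggregation into triples, a ≥ 10-reads-per-triple rule and a
   ≥ 6-distinct-UMIs-per-cell–barcode-pair rule → a sparse binary
   cell × barcode matrix.
2. **Clone calling** — agglomerative average-linkage clustering of cells on
   Jaccard distance between barcode sets, cut at height 0.5, giving one
   CloneID per cell.
3. **Lineage coupling** — for every pair of cell states (a, b), the observed
   number of *shared clones* O(a, b) (clones with ≥ 2 cells of each state) is
   standardized against a permutation null that shuffles the cell → state
   labels (default 10,000 permutations):

   Z(a, b) = (O(a, b) − μ_perm(a, b)) / σ_perm(a, b)

   Positive Z = coupled states, negative Z = anti-coupled. Pearson
   correlations between z-score rows and an average-linkage ordering give the
   clustered coupling heatmap.
4. **Clone composition** — restricted vs mixed clone fractions
   ("astrocyte-only" vs "neuron + astrocyte mix"), exclusive clone-fate
   classification, and UpSet-style intersection counts.
5. **Expression statistics** — depth normalization
   x → ln(1 + 10⁴·x / total), binned-control gene-set module scores, and a
   scrambled-normalized PCA-distance statistic
   R = D / D_s, where D is the mean distance in the first 30 principal
   components between a subtype's cells at a reference timepoint and a later
   one, and D_s is the mean cross-half distance over random splits of the
   whole dataset (R ≈ 1 ⇒ transcriptionally stable, R > 1 ⇒ divergence).
6. **A synthetic-data generator** — a dual-RGC experiment with configurable
   fate profiles (defaults: RGC_1 → 90% neuron-linked clones, 5% per
   astrocyte lineage; RGC_2 → 50% Olig2-lineage, 34% self-renewing, 16%
   neuron-linked, 0% S100a11), ~4.5 cells per clone, a 10⁵-barcode library
   with multiple integrations per founder, and 75% barcode recovery — so the
   entire pipeline runs, and is tested, against known ground truth without
   any download.

## Worked example

```python
import clonetrace as ct

cfg = ct.SimulationConfig(seed=1)              # dual-RGC defaults, 500 founders
sim = ct.simulate_experiment(cfg)

pairs, report = ct.filter_triples(sim.triples)            # 10-read / 6-UMI rules
matrix = ct.build_matrix(pairs, whitelist=sim.annotations["cell_id"])
clones = ct.attach_annotations(ct.call_clones(matrix), sim.annotations)
stats = ct.clone_size_stats(clones)

print(f"{report.n_triples_in} triples -> {report.n_triples_read_pass} pass the 10-read rule; "
      f"{report.n_pairs_umi_pass} cell-barcode pairs pass the 6-UMI rule")
print(f"matrix: {matrix.shape[0]} cells x {matrix.shape[1]} barcodes "
      f"({matrix.n_dropped_cells} cells without barcodes dropped)")
print(f"called {stats.n_clones} clones, mean size {stats.mean_size:.2f}")

res = ct.LineageCoupling(clones).fit(n_permutations=10_000, seed=1)
print(res.summary())
```

This prints (abridged):

```
67438 triples -> 54640 pass the 10-read rule; 3287 cell-barcode pairs pass the 6-UMI rule
matrix: 1652 cells x 984 barcodes (573 cells without barcodes dropped)
called 486 clones, mean size 3.40

Lineage coupling (permutation null)
  states: 5   permutations: 10000   seed: 1   min_cells: 2

pair                               observed      mean       sd        z
Ex_neuron ~ RGC_1                        63     22.81     3.93    10.23
Ex_neuron ~ RGC_2                        14     35.37     4.52    -4.72
Olig2_astro ~ RGC_2                      29     12.35     3.06     5.43
RGC_1 ~ RGC_2                             0     23.33     3.93    -5.93
RGC_1 ~ S100a11_astro                     4      0.06     0.23    16.79
RGC_2 ~ S100a11_astro                     0      0.10     0.30    -0.31
...
clustered ordering: Olig2_astro, RGC_2, RGC_1, Ex_neuron, S100a11_astro
```

Reading the numbers: ~25% of simulated cells yield no barcode and are dropped
(the configured recovery rate); 63 clones contain ≥ 2 excitatory neurons *and*
≥ 2 RGC_1 cells where chance predicts 22.8 ± 3.9, so RGC_1 is strongly
neuron-coupled (Z = 10.2); RGC_2 couples to Olig2-lineage astrocytes
(Z = 5.4) and shares no clone with S100a11 astrocytes — recovering the fate
structure the generator encoded.

The same chain runs from the shell:

```bash
clonetrace --seed 1 --outdir out all          # simulate→filter→clones→coupling→composition
clonetrace --config my.yaml --outdir out clones
```

Every run writes a `manifest.json` with the resolved configuration, seeds and
SHA-256 checksums of all outputs; reruns with the same seed are
byte-identical.

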