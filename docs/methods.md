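# Methods

## Problem and representation

`ltrtrace` clusters intact LTR retrotransposons (LTR-RTs) of one lineage at
sublineage resolution. Full-length nucleotide alignment distances blur at
this scale because elements share long stretches of common ancestry; the
discriminative signal lives in *structural* composition. The package
therefore represents each element as a **module sequence**:

1. All elements are compared pairwise (self-comparison). Each local
   alignment contributes two *sections* — the aligned spans on query and
   subject.
2. An undirected homology graph connects two sections when (a) they form an
   alignment pair with e-value below `evalue_max` (default 1e-5), or (b)
   they lie on the same element and their mutual positional overlap (the
   minimum of the two per-interval overlap ratios) reaches
   `min_mutual_overlap` (default 0.8; recommended band 0.80–0.99).
3. Connected components — found with a disjoint-set structure, cross-checked
   against a breadth-first-search oracle in the tests — become **modules**.
   Within a component, overlapping sections of one element are fused into a
   single member section. Fusion uses the *containment* ratio
   (overlap / shorter length) so that nested sections collapse to one
   member; without this, stacked nested sections emit runs of duplicate
   symbols that drown the edit-distance signal in detection noise. Graph
   edges keep the stricter symmetric criterion.
4. Modules are ranked by *spread* (number of distinct elements containing
   them); the `top_mod_num` (default 30) most widespread are retained, and
   each element becomes the ordered list of its retained module ids. The
   coverage curve (fraction of elements with at least L modules, L = 1..10)
   is the tuning diagnostic for `top_mod_num` and `min_mutual_overlap`: the
   coverage at length 1 should stay within about twofold of the coverage at
   length 10, and the curve should rise smoothly.

### Internal matcher

Pairwise alignments may be supplied as standard 12-column tabular records
(1-based inclusive coordinates, converted to 0-based half-open at the I/O
boundary; the reference external invocation is
`blastn -evalue 1e-5 -outfmt 6 -max_target_seqs 10000`). The built-in
matcher makes the package self-contained: exact 12-mer seeds (2-bit packed,
vectorized), drift-tolerant diagonal chaining (query gap ≤ 200 nt, diagonal
step ≤ 60 nt between consecutive seeds — indels shift the diagonal
gradually, so long alignments survive while structural breakpoints split
chains), edlib global alignment of each chained segment for identity, and a
blastn-like bit-score e-value proxy. Both strands are searched; subject
coordinates are always reported forward plus a strand flag, and module
membership is strand-agnostic. All element pairs are aligned up to roughly
300 elements (sampled partners beyond that): pair subsampling measurably
injects module-membership noise on benchmark-sized inputs.

## Embedding and clustering

Pairwise Levenshtein distances over module sequences (unit costs, module
ids as symbols; edlib bit-parallel with a pure dynamic-program fallback
past 255 distinct ids, both checked against a brute-force DP oracle) are
reduced to 3D with t-SNE (Barnes-Hut, fixed seed — the exact-gradient
solver of scikit-learn is not run-to-run reproducible, Barnes-Hut is).
Identical module sequences are collapsed to one point before embedding and
re-expanded at assignment; effective perplexity is
min(`perplexity`, n/8, (n−1)/3) so small sub-layers remain feasible.

The method's geometric assumption is radial: older elements carry shorter
module sequences and small mutual distances, collecting near the center,
while recent elements from different branches point outward. The
**radial diagnostic** is the Spearman correlation between module-sequence
length and distance from the embedding centroid (the "center"; a t-SNE
origin is arbitrary, so the centroid is the only parameter-free choice).

Each clustering pass works on two candidate views:

- **angular distances** relative to the center (entries in [0, π]; points at
  the exact center are excluded and flagged low-confidence) — the primary
  view, used when the radial diagnostic reaches `assumption_min_corr`
  (default 0.1);
- the module-distance matrix itself (ward linkage) as the fallback view.

For each view a hierarchical dendrogram is cut at its strongest natural
scale: the *jump ratio* at k is the merge height that reduces k clusters to
k−1 divided by the preceding merge height, and the largest k in
[`k_min`, `k_max`] whose jump reaches `split_jump` (default 1.5) is taken.
Every candidate partition must then pass a soundness check on module
distances — every cluster pair needs inter-cluster distances exceeding
intra-cluster ones (fold change > 1, one-sided rank-sum p < `alpha`).
Among sound candidates the one with the larger minimum fold wins, with the
angular view preferred on ties; if nothing validates, the elements stay in
one cluster. This automates the adjust-and-refine loop that the identity
validation is designed to support. The silhouette-based
`agglomerative_cluster` (average/complete linkage on angular distances)
remains available as a standalone operation.

An **elastic principal tree** (nodes initialized at cluster centroids,
edges from the minimum spanning tree on centroids, node positions
iteratively minimizing squared point-to-node distance plus an edge-stretch
penalty λ = 0.05·n/k) reconstructs the trajectory layout; points are
reassigned to the cluster of their nearest branch segment (closer endpoint
wins). Refinement is accepted only when the refined partition stays sound
and does not lower the minimum fold — in degenerate embeddings the 3D
proximity rule can otherwise undo a clean partition.

### Layering, confidence, validation

Layer 0 clusters everything. Clusters failing validation against a sibling
(fold ≤ 1 or p ≥ `alpha`) with at least `min_split_size` (50) members are
re-encoded against the module spread within the subset, re-embedded and
re-clustered; recursion stops at `max_depth` (3), when the sub-embedding's
radial diagnostic drops below `assumption_min_corr`, or when clusters get
too small. Labels concatenate ("A.2"). Intermediate layers are diagnostic
output only.

The lowest `origin_quantile` (default 0.5) of centered norms is flagged
low-confidence (origin-proximal: old, short module sequences carry little
angular information); low-confidence elements are excluded from validation
sampling. Validation draws up to `n_sample` (20) elements per cluster,
computes pairwise nucleotide distances as 1 − identity over the aligned
columns of an edlib global alignment, and reports fold change and one-sided
Wilcoxon rank-sum p for every cluster pair (raw p-values; no
multiple-testing correction, as the per-pair values are reported
individually). Intra/inter samples are capped at 60 pairs per comparison.

## Simulator

The generator grows independent evolutionary paths from one ancestral
sequence (real FASTA or uniform-random, default length 8000 nt):

- **founder divergence**: each path's founder receives 200 random
  substitutions plus 6 structural events. Substitutions barely perturb
  module sequences, so the structural dose carries the path signal; with
  the within-path structural rate below (≈1.2 events per surviving
  lineage), 6 founder events put the between-path signal roughly three
  times above the within-path noise — the regime in which deeply diverged
  real sublineages sit, and in which path recovery is meaningfully
  testable. A smaller dose (the same order as the noise) makes paths
  unrecoverable for any module-composition method.
- per generation: every active copy spawns `burst_copies_per_gen` (2)
  children; each child receives per-site substitutions (`p_sub` = 0.02),
  small indels (`p_indel_te` = 0.002/site, geometric lengths, p = 0.5) and
  at most one structural event with probability `p_sv` = 0.3 (insertion of
  random sequence, deletion, or inversion — reverse complement — with
  length uniform in 100–2000 nt, a typical internal LTR-RT scale); then
  every copy is eliminated with `p_elim` = 0.1.
- 4 generations by default → ≈50 surviving copies per path, a desk-scale
  dataset.

Every copy's mutation log is recorded (positions in the sequence state at
application time), so replaying the genealogy from the ancestor reproduces
each emitted sequence byte-exactly — the simulator's central invariant.
Eliminated copies stay in the truth table with `alive = 0`. The benchmark
grid is 3 random ancestors × {2, 3, 4} paths = 9 labeled datasets with
seeds derived from one master seed.

What the simulator does *not* model: host flanking sequence, target-site
duplications, nested insertions, selection, or realistic age structure —
all surviving copies are at most 4 generations old, so the radial age
gradient of real data is weak in simulation. Passing benchmarks therefore
demonstrate structural-path recovery, not the age-stratified geometry of
real genomes.

## Genome scan and quantification

Sublineage-discriminative modules are ranked by **diffScore** — the range
(max − min) of per-cluster occurrence fractions, selection threshold 0.8.
For a module, up to 10 member sections are drawn with a fixed RNG seed and
searched against the genome; hits below 50% of seed length are dropped;
positionally overlapping hits from different seeds are chained
(single-linkage) and merged to the median of member starts and median of
member ends; merged copies overlapping the intact-element annotation are
labeled intact, others truncated. Modules whose copies show a median
overlap above 0.2 with a longer retained module's copies are removed
(strictly greater than). The **elimination rate** is the truncated fraction
of a module's copies — more truncation means more decayed, eliminated
elements. Copies export to GTF (1-based inclusive; exact round trip).
Expression uses FPKM = count / (median length × total count) × 1e9 on a
supplied count table; read alignment and TE-aware counting are out of
scope.

## Numerical choices and degenerate inputs

- All intervals are 0-based half-open internally; writers convert at the
  boundary (tabular alignments and GTF 1-based inclusive, BED unchanged).
- Module ids are "b" + rank by descending member count (ties by smallest
  member section), so runs are diffable.
- Hit-list truncation keeps lowest e-values, ties by higher bit score, then
  input order.
- Degenerate clustering inputs: identical directions → one cluster with a
  warning; points at the exact center → excluded from angles, assigned to
  the nearest centroid, flagged low-confidence; single-member clusters →
  excluded from validation with a note.
- Median of an even number of merged starts/ends truncates to integer.
- All randomness flows from explicit seeds (`numpy` `SeedSequence`);
  reruns are byte-identical.

## Problem sizes

Default test/benchmark sizes: 9 datasets of ≈70–230 elements (8-kb
ancestors, 4 generations), all-pairs self-comparison, and a 1-Mb synthetic
genome with planted copies for the scan experiments. These sizes keep the
full suite in the tens of minutes on one core while leaving each dataset
large enough for the statistics (≥50 elements per path, ≥10 cluster pairs
in the validation checks).

## Known limitations

- The internal matcher is a toy: no affine gap model, no X-drop extension,
  heuristic e-values. It is calibrated for the package's own workflows
  (self-comparison of one lineage; planted-copy scans), not as a general
  aligner; supply external tabular alignments for large or distant
  searches.
- Hierarchical sub-labels ("A.2") are diagnostic; only the final partition
  is validated.
- The jump-ratio scale selection assumes the group scale is separated from
  the within-group scale by the `split_jump` factor; continuous gradients
  of divergence (no clean burst structure) will yield a single cluster.
  Conversely, when one inter-group separation dominates all others, the
  selected scale can be coarser than the full group structure and close
  groups merge (undersplitting); lowering `split_jump` or raising
  `max_depth` trades this against oversplitting. Validation-triggered
  layering only refines clusters that fail the identity validation, so an
  undersplit cluster that still validates against its siblings is not
  revisited.
- Fβ uses pair counting (the natural companion of the Rand index); β
  defaults to 1.
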