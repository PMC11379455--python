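# Methods

## The problem

Mass cytometry (CyTOF) measures ~40 protein markers per cell across millions
of cells. The canonical main immune lineages (T-cell subsets, B cells, NK
cells, monocytes, dendritic cells) are defined by well-known marker
positivity patterns, yet most pipelines still recover them either by manual
gating (slow, operator-dependent) or by unsupervised clustering followed by
manual cluster annotation (resolution- and seed-dependent). cytobinary takes
the semi-supervised middle road: the analyst writes down the lineage
definitions once, as a cell-types x markers table over `{+, -, A}`, and the
classifier does the rest deterministically.

## The classifier

For each marker that carries at least one informative (`+` or `-`) entry in
the signature matrix, the arcsinh-scaled intensities are split into a
negative and a positive population by **exact one-dimensional two-means**.
The optimal 2-means partition of points on a line is contiguous in sorted
order, so the global within-cluster-sum-of-squares minimiser is found by
scanning the n-1 breakpoints of the sorted sample with prefix sums
(O(n log n), dominated by the sort). This replaces iterative Lloyd k-means:
there is no initialisation, no seed, and the result *is* what a brute-force
search would return — the unit tests exploit exactly that equivalence.
Ties in WSS resolve to the smallest breakpoint; breakpoints inside a block
of tied values are never chosen (the block boundary is always at least as
good, and only boundaries admit a separating threshold). The threshold is
the midpoint between the two clusters' adjacent extremes, so
`positive == value > threshold` holds exactly. A marker that is constant in
its fitting stratum is flagged *degenerate* and called all-negative with a
warning, rather than erroring: in practice this is a panel mistake the user
must see, not a crash.

Binarization is fitted **pooled** across all samples by default (the normal
situation after batch correction); a `per_sample` scope exists for data with
strong uncorrected batch structure.

A cell matches a signature row iff every `+` marker is positive and every
`-` marker negative; `A` never constrains. Cells matching no row are
`Unclassified` — a first-class category that appears in every downstream
table and denominator. Cells matching several rows (possible when the matrix
is not mutually exclusive; `separability_report` enumerates such row pairs
up front) resolve to the **most specific row** (fewest `A` entries), ties
broken by matrix row order. This tie-break is this package's own rule; the
per-cell `match_count` is kept so users can audit how often it fired.

The deliberate modelling assumption, inherited from the field, is that the
classification markers are *bimodally* distributed on the arcsinh scale.
Markers expressed on a continuum (activation gradients, exhaustion markers)
are not suitable signature markers; they belong in the `state` class where
they are compared across groups, not thresholded.

## Evaluation metrics

Per class against a reference labelling: precision `TP/pred_n`, recall
`TP/true_n`, F-measure `2PR/(P+R)` with the `0/0 := 0` convention; the macro
average is the unweighted mean over classes, the weighted average uses
reference counts — the two are kept clearly apart because they diverge
sharply in imbalanced panels. Partition similarity is the standard
Hubert–Arabie adjusted Rand index computed from the contingency table; a
per-class one-vs-rest ARI (ARI of the `{class, rest}` indicator partitions)
is provided for per-lineage benchmark tables. Method agreement on abundance
estimates uses Pearson correlation (r, r², two-sided t-test p) and
Bland–Altman bias with 95% limits of agreement `bias ± 1.96·sd` (sample
standard deviation, n−1). Values are rounded (half-up, 2 decimals) only in
the report layer, never inside computations.

## Differential analysis

Features are per-sample summaries: percent lineage abundance, or the median
transformed intensity of a state marker within a (sample, lineage) stratum.
Strata with fewer than `min_cells = 3` cells get a missing value rather than
a meaningless median. Because cytometry abundances are bounded, skewed and
small-n, testing is distribution-free and routed on the number of study
groups: exactly two groups get a two-sided Mann–Whitney U per feature
(exact enumeration for small tie-free samples, midrank normal approximation
with tie correction otherwise); three or more get Kruskal–Wallis with tie
correction, followed, for features passing the BH threshold, by Dunn's
z-tests on tie-corrected mean-rank differences (default) or pairwise
Wilcoxon. BH families are: all abundance features of one comparison
together; all (lineage x state marker) features of one comparison together;
and each feature's post hoc pairs as their own family. The KW family is
corrected first, post hoc families afterwards — the ordering is a package
choice and is stated here because other orderings are defensible.
Significance stars follow the usual bands (* <0.05, ** <0.01, *** <0.001,
**** <0.0001).

## Batch diagnostics

Batches are compared on technical replicates only, so observed differences
are non-biological by construction. For every marker, each batch's
replicate distribution is compared to the pooled replicate distribution of
the *other* batches by 1-D earth-mover's distance, estimated as the mean
absolute difference of 1,000 matched quantiles. Leave-one-out pooling (as
opposed to pooling all batches including the one under test) makes the
statistic directly interpretable: a location shift delta confined to one
batch is reported as ≈ delta for that batch rather than diluted by its own
contribution to the reference. The default flag threshold is 0.3 transformed
units — an arbitrary but conservative default, exposed as a parameter, since
no principled universal cutoff exists. The second diagnostic level is the
per-batch lineage proportion vector from classifying the replicate cells.
Correction itself (quantile-spline or RUV-style normalisation) is
intentionally out of scope; the report is designed as actionable input to
dedicated correction tools.

## Subclustering

The subclustering interface is pluggable because practitioners have strong
tool preferences here: `external_labels` adopts any label vector so foreign
clusterings flow into medians, merging and differential analysis. Two
built-ins keep the pipeline self-contained: `kmeans` (scikit-learn Lloyd's
with k-means++ seeding, 20 restarts, best WSS, seeded) and `som_meta`, a
10x10 self-organizing map (linear learning-rate 0.5→0.02 and radius decay
over 10 epochs, Gaussian neighbourhood, seeded sampling) whose *occupied*
node codebooks are merged into exactly k metaclusters by average-linkage
hierarchical clustering. Unoccupied nodes are excluded from the linkage
because they interpolate between populations and chain otherwise-separate
clusters; a metacluster that ends up empty of cells is repopulated with its
nearest cell so the requested k is always honoured. Both built-ins are
deterministic given their mandatory seed. They are *simple built-ins*, not
re-implementations of flowSOM or Phenograph, and no equivalence with those
tools is claimed.

## The synthetic generator

The generator emulates the distributional shape the classifier assumes:
per marker, on the transformed scale, a negative mode (point mass at exactly
0 with weight 0.3, else half-normal with scale 0.5) and a positive normal
mode (location 3.0, scale 0.5) — separation ≥ 2 transformed units, i.e.
clearly bimodal with zero inflation. A cell draws each signature marker from
its lineage's mode, flipped to the opposite mode with probability
`noise_flip`; agnostic (`A`) markers and state markers draw from the
mixture at the marker's mixing weight (0.3). Condition effects multiply
lineage proportions (renormalised per sample) or shift state-marker
locations; batch effects add per-(batch, marker) offsets. Sampling is
sample-major and fully determined by the spec seed; `write_fcs_set`
inverse-transforms to the ion-count scale and writes a complete runnable
fixture (FCS files + metadata/panel/matrix/truth CSVs).

The default study is 3 conditions x 6 samples (3 batches, one replicate
anchor per batch within the healthy condition), 5,000 cells per sample,
7 PBMC lineages at realistic proportions (CD4 T 36%, CD8 T 18%, monocytes
17%, B 11%, NK 11%, DC 4%, gamma-delta T 3%) over 8 phenotypic + 4 state
markers, with `noise_flip = 0.01` — a realistic per-(cell, marker)
misexpression rate; with 4–5 informative markers per signature it predicts
per-class recall around 0.95–0.96, and the rare gamma-delta T lineage
(whose signature nests inside the T-cell pattern, so flips in abundant
lineages leak into it) is the hardest class, mirroring where automated
methods struggle on real PBMC data.

What the generator does **not** model — ion-count physics, spillover,
doublets, debris, acquisition drift, continuum markers — bounds what
passing tests show: they validate the algorithmic contract (exact
binarization, rule matching, statistics) and behaviour under the stated
distributional assumptions, not robustness to real-world artefacts that
upstream pre-processing is expected to remove.

## Numerical and design choices

- arcsinh cofactor defaults to 5, the community standard for CyTOF ion
  counts; it is a parameter everywhere. The transform is applied exactly
  once (double transformation is a state error).
- FCS support is a purpose-built reader/writer for list-mode FCS 3.0/3.1
  (float32/float64/unsigned-integer data, either byte order); writing emits
  FCS 3.1 float32 little-endian. `$PnS` is preferred over `$PnN` for display
  names; the panel table overrides both at assembly.
- Markers with panel class `none` are dropped at assembly, never silently
  kept; metadata joins are strict and abort with a listing of unmatched
  samples.
- Problem sizes in the test-suite simulations (600–5,000 cells per sample,
  1,000 null / 100 power replicates at 500 cells per sample) were chosen so
  the whole suite runs in well under a minute while keeping Monte-Carlo
  error far below the asserted margins.

## Known limitations

- No probabilistic or soft assignment; a cell is positive or negative per
  marker, full stop.
- Lineages defined by continuum markers cannot be targeted by the signature
  matrix.
- The one-vs-rest per-class ARI is one reasonable per-class partition
  score among several; cross-package comparability of per-class ARI columns
  is not guaranteed.
- The built-in SOM is a compact reference implementation tuned for tens of
  markers and up to ~10^5 cells, not a performance-optimised flowSOM
  replacement.
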