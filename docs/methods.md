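# Methods

`sdclouds` organizes the sequence–function map of the six-nucleotide
Shine–Dalgarno (SD) core in *E. coli* into a coarse-grained design
space. This note records the model, the conventions the implementation
pins where the procedure was genuinely open, the synthetic study
conditions the test suite runs under, and known limitations.

## The landscape

The primary object is a complete map from all `4^6 = 4096` SD cores to
an effective translation rate (ETR), a dimensionless relative
expression strength in `[0, 1]`. In the intended application the map is
derived from a genome-integrated fixed-context expression library in
which only the SD core varies, so differences in the readout are
attributed to translation initiation. The upstream distribution of that
data embeds a *measured* and a *model-predicted* dictionary inside two
Python scripts; `convert_upstream_scripts` extracts `(sequence, value)`
pairs from such scripts by pattern matching and merges them, preferring
the measurement when both exist and recording per-entry provenance
(`measured` / `predicted` / `synthetic`) so the predicted fraction of a
landscape stays auditable. The canonical on-disk form is a headered TSV
(`core`, `etr`, `source`); values are written in shortest exact decimal
form so a file round-trip is lossless, and comparisons to published
4-decimal tables use 4-decimal rounding. No copy of the upstream data
ships with the package; users materialize it once with the converter.

## Wildcard lattice and CV-guided pruning

A *pattern* is a 6-character string over `{A, C, G, T, _}`; its level
is the number of fixed positions, and the number of distinct level-k
patterns is `C(6, k) · 4^k` (15 625 in total). Every pattern is
annotated with the mean and coefficient of variation (CV) of the ETRs
of the `4^(6−k)` cores it matches. Conventions:

* CV uses the sample (n−1) standard deviation divided by the mean; a
  single leaf has CV 0. A zero mean with nonzero spread would make CV
  undefined; it is set to `+inf` so such a parent is never preferred
  (unreachable for ETRs in `(0, 1]`, but kept for degenerate inputs).
* A level-j pattern has j candidate parents (unfix one fixed position).
  Pruning gives every pattern the candidate parent of **minimal CV**;
  ties are broken by lexicographic order of the parent pattern under
  the symbol order `_ < A < C < G < T`. On a constant landscape (all
  CVs tied) this makes every chain unfix the leftmost fixed position,
  so all level-1 patterns have the form `_____X` — a property the suite
  checks by enumeration.
* The retained node set is the union of the 4096 leaf-to-root chains;
  because parent choice is a per-node function, the result is an
  arborescence with each core appearing exactly once as a leaf.
* The original workflow described pruning as deleting duplicate node
  objects from a fully expanded tree (where a level-j pattern occurs
  j! times) ranked by "CV contribution", a statistic it does not define.
  The min-CV parent selection implemented here realizes the same
  "path of minimal variability" intent while being deterministic and
  testable; exact node-for-node agreement with the original tree is
  therefore not a contract, only the invariants and the leaf ETRs are.
* The depth-first export visits children in the same `_ < A < C < G <
  T` lexicographic order, which pins the row order of the path table
  (`level 0` … `level 6`, `ETR`, `df_index`) and hence the cloud label
  numbering downstream.

## Activity clouds

Each leaf is embedded in `{0,1}^230`: a 30-bit one-hot sequence block
(5 symbols × 6 positions; the wildcard slot is retained, constantly 0
for leaves, to keep the stated layout) concatenated with a 200-bit
thermometer encoding of ETR with `k = round(v, 2) × 200` leading ones.
The `round`-first form is pinned because it is the one consistent with
the worked example `v = 0.50 → k = 100`. Squared Euclidean distance
then decomposes exactly as `2·hamming + |Δk|`, making sequence and
expression differences commensurable.

Clustering is DBSCAN (Euclidean) with `min_samples = 1`, under which
no point is noise and the labels are exactly the connected components
of the ε-neighborhood graph — the suite checks this equivalence
against a union-find oracle. ε is swept from 5.9 in steps of 0.05
until at most 400 labels remain (the published cap; label count is
non-increasing along the sweep and asserted so). Rows are the 4096
fully specified leaves: the alternative reading that internal wildcard
patterns are clustered too is rejected because published cloud
memberships contain only full cores. Cloud labels are assigned by
first member occurrence in depth-first path-table order; per-cloud
statistics are the mean and sample standard deviation of member ETRs
(singleton σ is reported as missing, rendered `N/A` in CSV).

Note a geometric consequence of the encoding: when ETR values are
dense (many cores within ~0.1 of a neighbor at small Hamming
distance), the ε-graph at the published starting radius is already
highly connected and the sweep terminates immediately with few, large
clouds. Sparse, gapped landscapes fragment into many clouds instead.
The default synthetic landscape is dense, so the default pipeline run
yields a single cloud; analyses that need a many-cloud partition at
desk scale (correlation recovery, composition of strong clouds) use a
quantile-binned partition of the landscape, constructed directly and
labeled as synthetic, rather than a re-tuned sweep.

## Design queries and external validation

* Forward: `core_to_cloud` returns the unique cloud of a core with its
  ETR band. Inverse: `target_to_candidates` ranks clouds by
  `|μ_j − target|`, ties to the lower label.
* SD-core calling in a 5′-UTR: for each spacer length in 5–8 nt the
  candidate window is the 6-mer ending that many bases before the
  start codon; the window with maximal ETR wins. The *spacer* is
  defined as the bases strictly between the core's 3′ end and the
  start codon's first base, with 0-based UTR coordinates; ties break
  toward the smallest spacer. Both conventions are pinned here because
  the procedure is otherwise underdetermined; calling is translation
  invariant by construction.
* External records (sequence, readout, read count) are filtered at a
  read-count threshold (default 500), resolved to clouds via core
  calling, aggregated per cloud (mean, sample std, 95% CI half-width
  `1.96·σ/√n`, missing for n < 2), and the cloud-mean readout is
  correlated with the cloud-mean ETR (Pearson, two-sided p). The
  correlation is computed at cloud level, matching the aggregation the
  module exposes.

## Positional influence

A partial least squares regression of ETR on the 30 one-hot predictors
(4 components, 80/20 split with a fixed seed) yields per-feature
coefficients. Predictors are deliberately **unscaled**: one-hot columns
share a scale already, and with `scale=False` the coefficient chain is
exactly `B = x_rotations · y_loadingsᵀ`, so component *a* contributes
`x_rotations[:, a] · y_loadings[a]` per feature. The *raw* influence
matrix (5 symbols × 6 positions) sums these contributions signed (and
equals the overall coefficient); the *absolute* matrix sums their
magnitudes. The wildcard row is exactly zero when fitting on full
cores (constant columns). A constant response returns all-zero
matrices rather than an error — "no signal" is a meaningful answer for
a degenerate landscape. Held-out R² is reported but not contractual.
One-hot coefficients are centered within each position block, so a
planted additive effect is recovered relative to its position mean;
the suite asserts sign recovery for planted effects of magnitude
≥ 0.05 with small competitors, and argmax recovery.

Composition summaries count the nucleotide newly fixed at a given tree
level across all 4096 leaf paths (counts sum to 4096) and the
positional nucleotide distribution inside clouds with mean ETR above a
threshold (default 0.75).

## Mutational graph

Nodes are cores with ETR and cloud label; edges join Hamming-1 pairs
(≤ 18 neighbors; the complete set is 18-regular with 36 864 edges).
Per cloud-induced subgraph: components, giant-component size/fraction,
average degree, clustering, and mean shortest path on the giant
component (0 for a single node; the all-pairs average is quadratic in
the giant size, so the pipeline caps it at 1500 nodes by default and
reports NaN beyond — a problem-size choice, configurable). The cloud
meta-graph carries per-pair bridge counts and mean |ΔETR|. Directed
moves are counted once per ordered adjacent pair (the uniform random
single-base step model); the transition matrix row-normalizes them
(diagonal = P(stay)), beneficial fractions are the share of directed
moves with ΔETR > 0 (missing for pairs without bridges), and monotone
accessibility is BFS on the subgraph of ΔETR ≥ 0 (or > 0) edges with
lexicographic tie-breaks for a deterministic witness path. Matrix
exports are ordered by ascending mean cloud ETR by default, with a
label-order flag.

## Synthetic study conditions

The synthetic landscape is additive with seeded Gaussian noise:
`etr = clamp01(baseline + Σ effects + ε)`. The defaults emulate the
salient features of the measured SD landscape: guanine carries the
dominant positive weight, strongest at the central positions
(0.05/0.10/0.15/0.15/0.10/0.05 across positions 1–6), thymine is
mildly positive, cytosine mildly detrimental, baseline 0.12, noise SD
0.02 — giving a noise-free range of roughly 0.02 (C-rich) to 0.75
(GGGGGG), most mass in the weak-initiation regime, and >60% guanine at
level 1 of the pruned tree. Synthetic external measurements embed a
random core at a random 5–8 nt spacer in a 20-nt UTR, with readout
`max(0, a·ETR + b + noise)` (defaults a = 1, b = 0.05, noise SD 0.05)
and log-normal read counts (σ = 1) around a median of 1000, so a
realistic minority of rows falls below the 500-read filter.

What the generator does *not* emulate: measurement heteroscedasticity,
context effects of leader/spacer/coding sequence, secondary-structure
coupling, epistasis between positions, and the sparse, gapped ETR
distribution of real libraries. Passing tests therefore demonstrate
the correctness of the machinery (combinatorics, encodings, clustering
semantics, estimator contracts, parameter recovery), not biological
accuracy of any particular partition.

## Problem sizes and numerics

The suite and the acceptance script run at full landscape scale (4096
cores, 15 625 patterns, 36 864 edges) for everything except: the
DBSCAN-vs-components oracle (200 instances of 50 points — the oracle
is quadratic), the distance-identity oracle (1000 random pairs), and
synthetic external data sets of 300–2000 records. Floating-point
tolerances: CV comparisons in pruning use a 1e-15 slack; row
stochasticity is asserted to 1e-12; published 4-decimal values are
compared after 4-decimal rounding.

## Known limitations

* Exact reproduction of the original pruned tree's internal paths is
  out of scope (the published deletion order is underdetermined); the
  cloud partition may likewise differ in detail from the published one
  wherever it depended on that order, so downstream counts tied to the
  exact partition (e.g. the number of singleton clouds) are sensitive
  to the pinned conventions.
* The thermodynamic (ΔG-based) core identification and folding-energy
  stratification used in some comparisons are not implemented; only
  the max-ETR calling rule is.
* The upstream measured/predicted tables are consumed, never refit; no
  imputation model is included.
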