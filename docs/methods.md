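# Methods

This note documents the models and procedures `contactscape` implements,
the parameters that matter, what the synthetic data emulate (and what they
do not), and the numerical and design choices made where more than one
reasonable option existed.

## Read-pair filtering

Each paired-end read carries one or more candidate mapped locations per
end. Two acceptance strategies are provided.

**strict_unique** (default): a pair is accepted only when both ends map to
exactly one location. This is the most stringent noise-reduction policy and
the one used for all quantitative results in this package.

**four_case**: rescues limited ambiguity using two physical scales — the
DNA insert length (`insert_length`, default 2000 bp) and the read length:

1. both ends unique → accept;
2./3. one end unique at A, the other with two candidates B, C → valid iff
   B or C lies within the insert length of A (same chromosome). The nearby
   candidate is interpreted as the physically linked insert end, and the
   *other* candidate becomes the recorded contact partner. This assignment
   is a package design choice: the validity test alone does not determine
   which location to record, and recording the distant candidate is the
   only reading that makes the rescued pair informative;
4. both ends with two candidates (A,B / C,D) → valid iff |A−C| and |B−D|
   are both smaller than the read length (the two candidate sets form two
   near-identical mapped pairs); the first candidate of each end is then
   emitted — a deterministic, documented choice;
- any end with ≥ 3 candidate locations is always discarded.

Accepted same-chromosome contacts closer than `min_separation` (default
2000 bp, the insert length) are removed: that range is dominated by
self-ligation and unligated-insert artifacts. The boundary is inclusive
(separation exactly 2000 bp is kept). Duplicate identical contacts are
kept by default; a `dedup` switch exists but is off, since collapsing
duplicates is a separate protocol decision. Strand is parsed but unused.

## Contact matrices

Positions are 1-based mapped read starts; bin `k` of a chromosome covers
`[k·res, (k+1)·res)` in 0-based coordinates, so position `p` maps to bin
`(p−1) // res`; the last bin may be short. Intra-chromosomal matrices are
symmetric, with a contact whose ends share a bin incrementing the diagonal
once — hence the conservation identity `Σ_{i≤j} M[i,j] = #contacts`, and
exact aggregation of fine bins into coarse bins (upper-triangle summation
on diagonal blocks). A visualization cap (default 50) clips values for
heat-map rendering only, never for statistics.

## Normalization

**Low-coverage removal.** Bins whose raw-count row has Euclidean norm
below a threshold are zeroed and recorded before balancing. Defaults
follow the coverage regimes of the matrices: 10 for inter maps at 1 Mb and
intra maps at 10 Mb, 100 for intra maps at 1 Mb. Filtering operates on raw
counts, before any normalization. Intra matrices remove the matching
column of each removed row; inter matrices screen rows and columns against
their own norms independently, since the two axes are different
chromosomes.

**SCN.** Alternately divide each column and then each row by its Euclidean
norm until `max|M − Mᵀ|` falls below `scn_tolerance` (default 1e−6), up to
`scn_max_iter` (default 200) sweeps. The metric and stopping rule are
package choices — the procedure is specified only as "repeat until
symmetric" — and max-abs asymmetry is the strictest elementwise reading.
Rectangular inter maps have no symmetry to test, so iteration stops when
the iterate stops changing (same tolerance). Zero rows or columns are left
untouched and recorded as removed bins; since the loop ends after a row
sweep, every surviving row has Euclidean norm 1 exactly. SCN is scale
invariant (`SCN(cM) = SCN(M)`) and its output is a fixed point — both are
enforced as tests.

**Distance normalization** (intra only): every cell is divided by the mean
of non-removed cells at the same diagonal offset, so each populated offset
of the output averages exactly 1; offsets with zero mean stay zero. The
combined long-range map is distance normalization followed by SCN, and bin
removal happens first.

**Simple scalings** (`x/avg`, `(x−min)/max`, `(x−mean)/sd`) use
whole-matrix statistics, matching their role as quick global rescalings
for visual comparison; degenerate statistics (zero mean/max/sd) raise an
error naming the method.

## Matrix statistics

**Correlation maps.** `C[i,j]` is the Pearson correlation of full rows `i`
and `j`, including the diagonal columns (excluding them is a variant the
row-profile definition does not require) but excluding removed bins'
columns. Constant or removed rows get an undefined flag and a stored 0.
Values are clipped to [−1, 1] against floating-point overshoot.

**Difference and change maps.** `|C₁ − C₂|` on a shared grid; each cell is
additionally classified as `sign_change` (product negative), `unchanged`
(|difference| < 1e−9, an exact-equality surrogate), else `value_change`.

**Poisson significance.** Off-diagonal, non-removed counts of a raw intra
matrix are modelled as Poisson with `λ` equal to their mean (one rate per
matrix, not per distance — the background model deliberately ignores
distance decay so that short-range enrichment is visible). Each cell gets
`Pr(X > M[i,j])`, strictly greater. Diagonal cells are reported but never
enter the `λ` estimate. The implementation delegates the tail to the scipy
survival function; tests verify it against direct pmf summation to 1e−12.
No multiple-testing correction is applied; the map reports raw tail
probabilities.

**Inter-chromosomal enrichment.** With `N` total inter-chromosomal reads
and `N_ij` counts per chromosome pair, `f_i = Σ_{j≠i} N_ij / N` is the
fraction of inter reads involving chromosome `i` (so `Σ f_i = 2`),
`E_ij = f_i f_j N`, and the reported ratio is `N_ij / E_ij`. The read-share
definition of `f_i` is a package choice; its self-check is the constancy
property — when all pairwise counts are balanced every ratio equals
`k / (2(k−1))` for `k` chromosomes, and the hand-computable 3-chromosome
example (10/20/30 reads) gives ratio 0.5 for the first pair.

## Translocation detection and correction

A reciprocal translocation exchanges terminal segments of two chromosomes.
Contacts inside a derivative chromosome that span the fusion junction are
mapped to the *reference* genome as inter-chromosomal contacts whose
density peaks at the breakpoints and decays with junction distance,
producing two dense opposite corner blocks in the inter matrix.

**Coarse scan (1 Mb).** For every candidate split `(a, b)` the scan scores
blocks of up to 2 bins per side anchored at the split corner of the dense
quadrants against the mean of the two complementary (background) quadrants
shrunk one bin away from the split. Anchored blocks include the bins the
breakpoints fall in — that is where the signal peaks — while the shrunk
background excludes them, since a mid-bin breakpoint contaminates its bin.
Candidates are the two reciprocal corner-pair unions (the translocation
signature) and each single corner (one-sided blocks); the best score must
reach `enrichment_min` (default 5) for a call. Whole-quadrant means were
tried first and proved too diluted by the decaying signal: they hover near
the threshold at desk-scale read depth, while split-anchored blocks score
it at 2–3× the threshold with no false calls on 100 translocation-free
replicates.

**Refinement (0.1 Mb, then 0.01 Mb).** Each breakpoint is refined inside a
window of ±2 coarse bins. The marginal contact profile along one
chromosome, conditioned on whether the partner position lies on the
translocated or non-translocated side of the partner breakpoint, steps
sharply at the junction (down in one conditional, up in the other). The
refined breakpoint maximizes the joint two-segment Poisson likelihood of
the two conditional profiles. Contacts whose partner position lies within
one coarse bin of the partner estimate are dropped (mis-sided partners
would leak junction signal across the boundary), and each stage runs two
sweeps so each axis is refined against the other's improved estimate. A
mean-ratio rescan at the fine scale was tried first and mislocalized by
several fine bins, because the decaying junction profile makes the
mean-ratio maximum flat; the changepoint likelihood is sensitive to the
local jump at the boundary.

**Correction.** The breakpoints partition the inter matrix into regions
A (non-translocated × non-translocated), B (translocated × translocated),
C and D (mixed, the junction artifacts). A and B hold genuine
inter-chromosomal contacts and are halved; C and D are corrected cell-wise
as `max(0, value − background)` where the background for a C cell is its
row's mean over region A and for a D cell its column's mean over region A,
both computed on the original counts. Halved counts are kept fractional,
and the corrected matrix stays in reference coordinates.

## Interaction networks

Contact ends are matched to annotated features (1-based inclusive
containment); gene networks keep only `GENE` entries, excluding `PSEUDO`,
`RNA`, `CDS` and `UTR` records. An end overlapping several allowed
features increments all induced pairs — single-assignment would need an
arbitrary priority. Edges require contact count strictly greater than the
threshold (threshold 0 is the "at least one read" network); isolated
features never appear. Cross-sample comparability uses depth-dependent
thresholds: the smallest integer `t` with at most `target` edges above it,
then ties at `t` added back in deterministic order (weight descending,
then lexicographic pair id) until exactly `target` edges — resolving the
tie handling that integer thresholds alone cannot.

Graph statistics are implemented from their definitions (BFS-based, with
networkx only as the graph container; an independent brute-force oracle
checks every statistic in the tests): degree and shortest-path histograms
(unweighted paths, unordered reachable pairs), clustering coefficient
`2e_n/(k_n(k_n−1))` (0 for degree < 2), closeness centrality as the
reciprocal mean distance to reachable nodes (0 for isolated nodes), stress
as the number of shortest paths through a node counting *all* shortest
paths per pair (histogram binned [0], [1,9], [10,99], ...), and the
topological coefficient: the mean over partners (nodes sharing a neighbor
or directly linked) of shared-neighbor counts plus one for a direct link,
divided by the degree (0 for degree ≤ 1). The scale-free diagnostic is an
ordinary least-squares line through `(log₁₀ k, log₁₀ count)` over degrees
with positive count (≥ 3 distinct degrees required); a constant histogram
fits perfectly with slope 0, reported as R² = 1.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions all tests run under. Defaults:
two 5 Mb chromosomes, 200,000 read pairs, read length 100 bp.

- **Distance decay:** the contact rate between two loci at separation `d`
  is ∝ `d^−α` with α = 1; the separation marginal is therefore weighted by
  `d^−α (L − d)`, the second factor counting locus pairs at separation
  `d`. Sampling is inverse-CDF on a 1 kb grid with a uniform offset inside
  the step — exact, integer-based and seedable.
- **Compartments:** 0/1 labels per 500 kb bin in alternating blocks of
  geometric length (mean 2 bins); same-compartment contacts are weighted
  `(1 + plaid)` and cross-compartment `(1 − plaid)` with plaid = 0.6,
  via rejection sampling.
- **Inter background:** uniform, 2% of pairs. In a real genome roughly
  half the reads are inter-chromosomal but they are spread over hundreds
  of chromosome pairs; 2% approximates the share a single pair of
  chromosomes receives, which is the quantity that matters for a
  two-chromosome fixture.
- **Artifacts:** 10% of records receive 1–2 decoy candidate locations on
  one end (multi-mapping), 10% are drawn with separation in [50, 2000) bp
  (self-ligation-like); the categories are mutually exclusive, so the pair
  filter's tallies estimate the planted rates directly.
- **Translocation:** a tail-tail reciprocal exchange; pairs on the two
  partner chromosomes are sampled on the derivative chromosomes
  (decay running across the junction) and mapped back to reference
  coordinates. Translocation fixtures use an 8 Mb + 6 Mb chromosome pair
  with 40,000 read pairs — a desk-scale depth at which detection operates
  with a clear margin — and breakpoints at 10 kb multiples in the central
  region of each chromosome.
- **Annotations:** one gene per equal-width slot (guaranteed
  non-overlapping) with kinds drawn 60% `GENE` / 10% each `PSEUDO`, `RNA`,
  `CDS`, `UTR`; TFBS likewise in their own slots, 200–1000 bp.

All randomness derives from one seed through named, independently spawned
streams (compartments, features, pairs, decoys, shorts), so outputs are
bit-reproducible and adding a stream does not perturb the others.

Not emulated: restriction-fragment structure and ligation chemistry, GC
and mappability biases (SCN is exercised on coverage heterogeneity arising
from sampling noise and the plaid, not on explicit bias models),
sequencing errors (no FASTQ level), copy-number variation, and more than
one rearrangement per chromosome pair. Passing tests therefore demonstrate
the correctness of the algorithms under the stated generative model, not
robustness to every artifact of real libraries.

## Problem sizes and degenerate inputs

Test and acceptance workloads use desk-scale sizes chosen to keep the
model regimes intact: 200k pairs for the end-to-end fixture, 40k for
translocation replicates, 10×10–25-node graphs for oracle comparisons.
Degenerate inputs raise explicit errors: unknown chromosomes or
out-of-range positions at parse time (with line numbers for malformed
tables), an all-removed matrix at normalization, a zero background rate in
the significance model, empty region A in the translocation correction,
and unreachable edge-equalization targets. Non-convergent SCN warns and
returns the last iterate rather than failing.
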