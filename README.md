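# contactscape

Analysis of genome conformation from Hi-C chromosome-conformation-capture
data: from mapped paired-end reads to contact matrices, normalized maps,
compartment and significance statistics, translocation calls, and spatial
gene/TFBS interaction networks.

Hi-C ligates spatially proximal DNA fragments and sequences the junctions;
each read pair evidences one spatial **contact** between two genomic
locations. `contactscape` implements the downstream computational stack for
such data:

- **Pair filtering** — resolves candidate mapped locations per read end
  (strict unique mapping by default, or a four-case rescue strategy using
  the ~2 kb insert length), and removes same-chromosome pairs closer than
  2 kb (self-ligation artifacts).
- **Contact matrices** — `M[i, j]` counts contacts between fixed-size bins
  `i` and `j` (intra- or inter-chromosomal), at any resolution.
- **Normalization** — low-coverage bin removal (Euclidean-norm threshold),
  **SCN** balancing (alternately divide columns and rows by their Euclidean
  norms until `M` is symmetric), genomic-distance normalization (divide each
  cell by the mean at its diagonal offset), and simple whole-matrix
  scalings (`x/avg`, `(x-min)/max`, `(x-mean)/sd`).
- **Matrix statistics** — Pearson correlation maps
  `C[i, j] = corr(row_i, row_j)` that amplify the A/B-compartment plaid
  pattern; absolute difference maps and sign-change classification between
  samples; Poisson contact significance `Pr(X > M[i, j])` with the
  background rate `λ` estimated from the off-diagonal mean; per-chromosome
  inter-chromosomal enrichment `observed / expected` with
  `E_ij = f_i f_j N` (where `f_i` is chromosome *i*'s share of the `N`
  inter-chromosomal reads); cross-sample contact-vector correlations.
- **Translocation detection** — a reciprocal translocation shows up as two
  dense opposite corner blocks in the inter-chromosomal matrix (junction
  contacts of the derivative chromosomes mapped back to the reference);
  an exhaustive corner-block split scan finds the breakpoints at 1 Mb and
  refines them to 10 kb, and the inter matrix is corrected region by region
  (background regions halved, junction regions background-subtracted).
- **Interaction networks** — weighted graphs over genes and
  transcription-factor binding sites with contact-count edge weights,
  depth-equalized edge thresholds across samples, and the graph statistics
  used to diagnose scale-free modular structure: degree and shortest-path
  histograms, clustering coefficient `2e_n / (k_n(k_n-1))`, closeness
  centrality, stress (number of shortest paths through a node), topological
  coefficient, and the log-log power-law fit of the degree distribution.
- **Synthetic data** — a seeded generator producing genomes, annotations
  and mapped read-pair tables with distance-decay contacts
  (rate ∝ d<sup>−α</sup>), a two-compartment plaid, uniform inter
  background, multi-mapping and short-separation artifacts, and optional
  planted reciprocal translocations — so the whole pipeline is testable
  without any external data.

## Worked example

```python
import contactscape as cs
from contactscape.matrix import bin_contacts
from contactscape.normalization import distance_scn_normalize, filter_low_coverage_bins
import numpy as np

params = cs.SimulationParams(n_pairs=200_000, seed=1)   # two 5 Mb chromosomes
sg = cs.simulate_genome(params)
records = cs.simulate_pairs(sg, params)

contacts, stats = cs.filter_pair_stream(records, cs.FilterPolicy(), sg.genome)
print(stats)
# {'accepted': 160222, 'multi_mapped': 20002, 'short_separation': 19776}

raw = bin_contacts(contacts, sg.genome.grid("chr1", 500_000))
norm = distance_scn_normalize(filter_low_coverage_bins(raw, 10.0))
corr = cs.correlation_matrix(norm)
labels = sg.compartments["chr1"]
same = np.equal.outer(labels, labels)
off = ~np.eye(len(labels), dtype=bool)
print(round(corr.values[same & off].mean(), 3),
      round(corr.values[~same & off].mean(), 3))
# 0.7 -0.771
```

The filter tally recovers the planted 10% multi-mapped and 10%
short-separation artifact rates, and the correlation map of the normalized
matrix shows the compartment plaid: bins in the same compartment correlate
positively (+0.70 on average), bins in different compartments negatively
(−0.77).

The `examples/` directory has one short script per capability (filtering
and binning, normalization and compartments, translocation detection and
correction, interaction networks), each printing the numbers it computes
with a line on what they mean.

## Command line

The same stages are exposed as a thin CLI:

```bash
contactscape simulate --seed 1 --out-dir fixtures/
contactscape filter --pairs fixtures/pairs.tsv --genome fixtures/genome.tsv \
    --strategy strict_unique --min-sep 2000 --out contacts.tsv
contactscape matrix --contacts contacts.tsv --genome fixtures/genome.tsv \
    --resolution 1000000 --chrom chr1 --out M.tsv
contactscape normalize --matrix M.tsv --method dist-scn --out N.tsv
contactscape transloc detect --contacts contacts.tsv --genome fixtures/genome.tsv \
    --chrom-a chr1 --chrom-b chr2 --out transloc.tsv
contactscape run --config pipeline.yaml      # all stages, with a manifest
```

`contactscape run` executes the configured stages in dependency order and
writes a `manifest.json` with SHA-256 checksums of every artifact; reruns
with unchanged inputs are byte-identical.

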