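"""Statistics on contact matrices.

Covers the comparative and inferential layer of the analysis:

* Pearson correlation maps (``C[i, j]`` = correlation of rows ``i`` and ``j``
  of the contact matrix), which amplify the plaid open/closed-compartment
  pattern;
* absolute difference maps between two correlation matrices, and a
  three-way classification of each cell (sign change / value change /
  unchanged) between two samples;
* Poisson significance of contact counts, with the background rate estimated
  from the off-diagonal mean;
* observed/expected enrichment of inter-chromosomal contacts per chromosome
  pair;
* cross-sample Pearson similarity of contact-count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BinGrid, Genome
from .matrix import ContactMatrix
from .pair_filtering import contacts_frame


@dataclass
class CorrelationMatrix:
    """Row-row Pearson correlation map of a contact matrix.

    ``undefined`` flags rows with zero variance (or removed bins), whose
    correlations are stored as 0.
    """

    grid: BinGrid
    values: np.ndarray
    undefined: np.ndarray
    source_kind: str = "raw_counts"

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SignificanceMatrix:
    """Upper-tail Poisson probabilities for each cell of a raw contact matrix."""

    grid: BinGrid
    pvalues: np.ndarray
    lam: float  # background mean contact count (off-diagonal cells)


def correlation_matrix(matrix: ContactMatrix) -> CorrelationMatrix:
    """Pearson correlation between every pair of rows of a square matrix.

    Removed bins' columns are excluded from the row vectors; removed or
    constant rows yield undefined correlations, stored as 0 and flagged.
    """
    values = matrix.values
    if values.shape[0] != values.shape[1]:
        raise ValueError("correlation map requires a square matrix")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 columns to correlate rows")
    kept_cols = matrix.kept_cols()
    if kept_cols.sum() < 2:
        raise ValueError("fewer than 2 usable columns after bin removal")
    rows = values[:, kept_cols]
    defined = matrix.kept_rows() & (rows.std(axis=1) > 0)
    n = values.shape[0]
    corr = np.zeros((n, n))
    idx = np.nonzero(defined)[0]
    if idx.size >= 2:
        sub = np.corrcoef(rows[idx])
        corr[np.ix_(idx, idx)] = np.clip(sub, -1.0, 1.0)
    elif idx.size == 1:
        corr[idx[0], idx[0]] = 1.0
    undefined = ~defined
    corr[undefined, :] = 0.0
    corr[:, undefined] = 0.0
    return CorrelationMatrix(matrix.row_grid, corr, undefined, matrix.kind)


def difference_matrix(c1: CorrelationMatrix, c2: CorrelationMatrix) -> np.ndarray:
    """Elementwise |C1 - C2| between two correlation maps on the same grid."""
    if c1.shape != c2.shape or c1.grid != c2.grid:
        raise ValueError("correlation matrices have mismatched grids")
    return np.abs(c1.values - c2.values)


def classify_correlation_change(c1: CorrelationMatrix, c2: CorrelationMatrix,
                                tol: float = 1e-9) -> np.ndarray:
    """Per-cell change category between two samples' correlation maps.

    ``sign_change`` when the correlation flips sign, ``unchanged`` when the
    values agree within ``tol``, else ``value_change``.
    """
    if c1.shape != c2.shape:
        raise ValueError("correlation matrices have mismatched shapes")
    diff = np.abs(c1.values - c2.values)
    out = np.full(c1.shape, "value_change", dtype="<U12")
    out[(c1.values * c2.values < 0) & (diff >= tol)] = "sign_change"
    out[diff < tol] = "unchanged"
    return out


def poisson_tail_probability(count, lam: float):
    """``Pr(X > count)`` for ``X ~ Poisson(lam)`` (strictly greater)."""
    return sps.poisson.sf(count, lam)


def poisson_significance(matrix: ContactMatrix) -> SignificanceMatrix:
    """Probability of observing a higher count by chance, per cell.

    The background rate ``lambda`` is the mean of the off-diagonal,
    non-removed cells of the raw intra matrix; each cell's value is
    ``Pr(X > M[i, j])`` for ``X ~ Poisson(lambda)`` (strictly greater).
    Diagonal cells are reported but excluded from the ``lambda`` estimate.
    """
    values = matrix.values
    if values.shape[0] != values.shape[1]:
        raise ValueError("significance analysis requires a square intra matrix")
    kept = matrix.kept_rows()
    off = ~np.eye(values.shape[0], dtype=bool) & np.outer(kept, kept)
    if not off.any():
        raise ValueError("no off-diagonal cells to estimate the background rate")
    lam = float(values[off].mean())
    if lam == 0:
        raise ValueError("background rate is zero: no off-diagonal contacts")
    pvalues = poisson_tail_probability(values, lam)
    return SignificanceMatrix(matrix.row_grid, pvalues, lam)


@dataclass
class InterChromProfile:
    """Observed vs expected inter-chromosomal contacts for all chromosome pairs.

    ``fractions[i]`` is the share of inter-chromosomal reads involving
    chromosome ``i`` (the fractions sum to 2, each read touching two
    chromosomes); the expected count is ``E_ij = f_i * f_j * N`` and
    ``ratio = observed / expected`` (NaN on the diagonal).
    """

    chromosomes: tuple[str, ...]
    counts: np.ndarray
    fractions: np.ndarray
    total: float
    expected: np.ndarray
    ratio: np.ndarray

    def ratio_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratio, index=self.chromosomes,
                            columns=self.chromosomes)


def observed_expected_ratios(
        pair_counts: Mapping[tuple[str, str], float] | pd.DataFrame,
) -> InterChromProfile:
    """Observed/expected enrichment ratio per chromosome pair.

    ``pair_counts`` maps unordered chromosome pairs to inter-chromosomal
    contact counts (or is a symmetric DataFrame).  Ratios > 1 indicate
    enrichment of contacts between the two chromosomes, < 1 depletion.
    """
    if isinstance(pair_counts, pd.DataFrame):
        chroms = tuple(pair_counts.index)
        counts = pair_counts.to_numpy(dtype=float).copy()
        if list(pair_counts.columns) != list(chroms):
            raise ValueError("pair-count frame must have matching index and columns")
    else:
        chroms = tuple(dict.fromkeys(c for pair in pair_counts for c in pair))
        k = len(chroms)
        pos = {c: i for i, c in enumerate(chroms)}
        counts = np.zeros((k, k))
        for (ca, cb), n in pair_counts.items():
            if ca == cb:
                raise ValueError("pair counts must be inter-chromosomal (i != j)")
            counts[pos[ca], pos[cb]] += n
            counts[pos[cb], pos[ca]] += n
    np.fill_diagonal(counts, 0.0)
    if not np.allclose(counts, counts.T):
        raise ValueError("pair-count matrix must be symmetric")
    total = counts.sum() / 2.0
    if total == 0:
        raise ValueError("no inter-chromosomal contacts")
    fractions = counts.sum(axis=1) / total
    expected = np.outer(fractions, fractions) * total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, counts / expected, np.nan)
    np.fill_diagonal(ratio, np.nan)
    return InterChromProfile(chroms, counts, fractions, total, expected, ratio)


def cross_sample_correlation(vectors: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Sample-by-sample Pearson matrix over equal-length contact-count vectors.

    Constant vectors yield undefined correlations, reported as NaN.
    """
    names = list(vectors)
    arr = np.asarray([np.asarray(vectors[n], dtype=float) for n in names])
    if arr.ndim != 2:
        raise ValueError("vectors must all have the same length")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(arr)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# contact-count summaries feeding the statistics above

def inter_pair_counts(contacts, genome: Genome) -> dict[tuple[str, str], int]:
    """Number of inter-chromosomal contacts for every chromosome pair."""
    df = contacts_frame(contacts)
    inter = df[df["chrom_a"] != df["chrom_b"]]
    counts = {pair: 0 for pair in genome.pairs()}
    grouped = inter.groupby(["chrom_a", "chrom_b"]).size()
    for (ca, cb), n in grouped.items():
        key = (ca, cb) if genome.index(ca) < genome.index(cb) else (cb, ca)
        counts[key] = counts.get(key, 0) + int(n)
    return counts


def intra_totals(contacts, genome: Genome) -> pd.Series:
    """Total intra-chromosomal contacts per chromosome (one sample vector)."""
    df = contacts_frame(contacts)
    intra = df[df["chrom_a"] == df["chrom_b"]]
    totals = intra.groupby("chrom_a").size()
    return pd.Series([int(totals.get(c, 0)) for c in genome.chromosomes],
                     index=list(genome.chromosomes), dtype=int)
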