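"""Binned intra- and inter-chromosomal contact matrices.

The contact matrix ``M`` of one chromosome (or chromosome pair) at a given
resolution counts the accepted contacts whose two ends fall into each pair of
bins: ``M[i, j]`` is the number of contacts between region ``i`` and region
``j``.  Intra-chromosomal matrices are symmetric; a contact whose two ends
fall into the same bin increments the diagonal once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import BinGrid, grid_from_labels
from .pair_filtering import contacts_frame


@dataclass
class ContactMatrix:
    """A binned (and possibly normalized) contact matrix.

    ``removed_rows`` / ``removed_cols`` hold indices of bins zeroed out by
    low-coverage filtering; they are carried through every normalization.
    """

    row_grid: BinGrid
    col_grid: BinGrid
    values: np.ndarray
    kind: str = "raw_counts"
    removed_rows: frozenset[int] = frozenset()
    removed_cols: frozenset[int] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.row_grid.n_bins, self.col_grid.n_bins)
        if self.values.shape != expected:
            raise ValueError(f"matrix shape {self.values.shape} != grid shape {expected}")
        self.removed_rows = frozenset(self.removed_rows)
        self.removed_cols = frozenset(self.removed_cols)

    @property
    def is_intra(self) -> bool:
        return self.row_grid == self.col_grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def removed_bins(self) -> set[tuple[str, int]]:
        return ({("row", i) for i in self.removed_rows}
                | {("col", j) for j in self.removed_cols})

    def kept_rows(self) -> np.ndarray:
        mask = np.ones(self.shape[0], dtype=bool)
        mask[list(self.removed_rows)] = False
        return mask

    def kept_cols(self) -> np.ndarray:
        mask = np.ones(self.shape[1], dtype=bool)
        mask[list(self.removed_cols)] = False
        return mask

    def with_values(self, values: np.ndarray, kind: Optional[str] = None,
                    removed_rows=None, removed_cols=None) -> "ContactMatrix":
        return ContactMatrix(
            self.row_grid, self.col_grid, values,
            kind if kind is not None else self.kind,
            self.removed_rows if removed_rows is None else removed_rows,
            self.removed_cols if removed_cols is None else removed_cols)


def bin_contacts(contacts, row_grid: BinGrid,
                 col_grid: Optional[BinGrid] = None) -> ContactMatrix:
    """Bin contacts into the matrix of one chromosome (pair).

    Contacts not involving the requested chromosome(s) are ignored, so the
    full contact list of a sample can be passed directly.  For intra matrices
    each contact increments ``M[i, j]`` and ``M[j, i]`` (the diagonal once);
    the total intra count over ``i <= j`` equals the number of contacts.
    """
    df = contacts_frame(contacts)
    if col_grid is None or col_grid == row_grid:
        return _bin_intra(df, row_grid)
    return _bin_inter(df, row_grid, col_grid)


def _bin_intra(df: pd.DataFrame, grid: BinGrid) -> ContactMatrix:
    n = grid.n_bins
    sel = (df["chrom_a"] == grid.chromosome) & (df["chrom_b"] == grid.chromosome)
    sub = df.loc[sel]
    i = np.asarray(grid.bin_of(sub["pos_a"].to_numpy())) if len(sub) else np.empty(0, int)
    j = np.asarray(grid.bin_of(sub["pos_b"].to_numpy())) if len(sub) else np.empty(0, int)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    upper = np.bincount(lo * n + hi, minlength=n * n).reshape(n, n).astype(float)
    full = upper + upper.T - np.diag(np.diagonal(upper))
    return ContactMatrix(grid, grid, full, kind="raw_counts")


def _bin_inter(df: pd.DataFrame, row_grid: BinGrid, col_grid: BinGrid) -> ContactMatrix:
    cr, cc = row_grid.chromosome, col_grid.chromosome
    n, m = row_grid.n_bins, col_grid.n_bins
    values = np.zeros((n, m))
    for a_col, b_col, ca, cb in ((("chrom_a", "chrom_b") + (cr, cc)),
                                 (("chrom_b", "chrom_a") + (cr, cc))):
        sel = (df[a_col] == ca) & (df[b_col] == cb)
        if not sel.any():
            continue
        pa = "pos_a" if a_col == "chrom_a" else "pos_b"
        pb = "pos_b" if a_col == "chrom_a" else "pos_a"
        i = np.asarray(row_grid.bin_of(df.loc[sel, pa].to_numpy()))
        j = np.asarray(col_grid.bin_of(df.loc[sel, pb].to_numpy()))
        values += np.bincount(i * m + j, minlength=n * m).reshape(n, m)
    return ContactMatrix(row_grid, col_grid, values, kind="raw_counts")


def cap_for_visualization(matrix: ContactMatrix, cap: float = 50) -> ContactMatrix:
    """Clip values at ``cap`` for heat-map rendering (never for statistics)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return matrix.with_values(np.minimum(matrix.values, cap))


def region_contact_profile(matrices: Iterable[ContactMatrix],
                           chromosome: str) -> np.ndarray:
    """Per-bin totals of intra plus inter contacts for one chromosome.

    ``matrices`` are all (intra and inter) matrices of a sample at one
    resolution; entry ``i`` sums row ``i`` of the chromosome's intra matrix
    and its rows/columns in every inter matrix that involves it.
    """
    profile: Optional[np.ndarray] = None
    for m in matrices:
        if m.row_grid.chromosome == chromosome:
            contrib = m.values.sum(axis=1)
        elif m.col_grid.chromosome == chromosome:
            contrib = m.values.sum(axis=0)
        else:
            continue
        if profile is None:
            profile = np.zeros_like(contrib)
        if profile.shape != contrib.shape:
            raise ValueError("inconsistent resolution across matrices")
        profile = profile + contrib
    if profile is None:
        raise ValueError(f"no matrix involves chromosome {chromosome!r}")
    return profile


# ---------------------------------------------------------------------------
# plain-text I/O: labelled TSV and sparse triplets

def write_matrix_tsv(matrix: ContactMatrix, path) -> None:
    """Write a matrix with ``chrom:start-end`` row/column labels.

    Removed bins, if any, go to a ``<path>.removed`` sidecar listing
    ``axis<TAB>label`` lines.
    """
    df = pd.DataFrame(matrix.values,
                      index=matrix.row_grid.labels(),
                      columns=matrix.col_grid.labels())
    with open(path, "w") as fh:
        fh.write(f"# kind={matrix.kind}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")
    if matrix.removed_rows or matrix.removed_cols:
        with open(f"{path}.removed", "w") as fh:
            for i in sorted(matrix.removed_rows):
                fh.write(f"row\t{matrix.row_grid.label(i)}\n")
            for j in sorted(matrix.removed_cols):
                fh.write(f"col\t{matrix.col_grid.label(j)}\n")


def read_matrix_tsv(path) -> ContactMatrix:
    kind = "raw_counts"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# kind="):
            kind = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    row_grid = grid_from_labels(list(df.index))
    col_grid = grid_from_labels(list(df.columns))
    removed_rows: set[int] = set()
    removed_cols: set[int] = set()
    try:
        with open(f"{path}.removed") as fh:
            row_idx = {lab: i for i, lab in enumerate(row_grid.labels())}
            col_idx = {lab: j for j, lab in enumerate(col_grid.labels())}
            for line in fh:
                axis, label = line.rstrip("\n").split("\t")
                (removed_rows if axis == "row" else removed_cols).add(
                    (row_idx if axis == "row" else col_idx)[label])
    except FileNotFoundError:
        pass
    return ContactMatrix(row_grid, col_grid, df.to_numpy(dtype=float), kind,
                         frozenset(removed_rows), frozenset(removed_cols))


def write_triplets(matrix: ContactMatrix, path) -> None:
    """Sparse 3-column (bin_i, bin_j, value) writer for large grids."""
    ii, jj = np.nonzero(matrix.values)
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            v = matrix.values[i, j]
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def render_heatmap(matrix: ContactMatrix, path, cap: Optional[float] = None) -> None:
    """Optional heat-map PNG (requires matplotlib); ``cap`` clips for display only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values if cap is None else np.minimum(matrix.values, cap)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values, cmap="Reds", origin="upper", aspect="auto")
    ax.set_xlabel(matrix.col_grid.chromosome)
    ax.set_ylabel(matrix.row_grid.chromosome)
    fig.colorbar(im, ax=ax, label="contacts")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
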