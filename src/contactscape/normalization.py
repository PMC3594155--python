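"""Contact-matrix normalization.

Three procedures are provided, matching the analysis stack this package
implements:

* **Low-coverage bin removal** — bins whose row of raw counts has a small
  Euclidean norm carry too few reads to normalize meaningfully and are zeroed
  out before balancing.  Default thresholds: 10 for inter-chromosomal 1 Mb
  maps and intra maps at 10 Mb, 100 for intra maps at 1 Mb.
* **SCN (Sequential Component Normalization)** — alternately divide each
  column and each row by its Euclidean norm until the matrix is symmetric.
  This equalizes the total visibility of every region, removing coverage
  biases (fragment size, GC content, mappability) without modelling them
  explicitly.
* **Genomic-distance normalization** — divide every intra-chromosomal cell by
  the mean count at its diagonal offset, converting counts into enrichment
  over the distance-decay expectation and de-emphasizing the dominant
  short-range signal.  The combined map used for compartment analysis is
  distance normalization followed by SCN.

Simple whole-matrix scalings (``x/avg``, ``(x-min)/max``, ``(x-mean)/sd``)
used for quick matrix comparison are also included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ContactMatrix

SIMPLE_METHODS = ("x_over_avg", "minmax", "zscore")


@dataclass(frozen=True)
class NormalizationParams:
    euclid_threshold: float = 10.0
    scn_tolerance: float = 1e-6
    scn_max_iter: int = 200
    simple_method: str = "x_over_avg"

    def __post_init__(self):
        if self.euclid_threshold < 0:
            raise ValueError("euclid_threshold must be >= 0")
        if self.scn_tolerance <= 0:
            raise ValueError("scn_tolerance must be positive")
        if self.scn_max_iter < 1:
            raise ValueError("scn_max_iter must be >= 1")
        if self.simple_method not in SIMPLE_METHODS:
            raise ValueError(f"unknown simple method {self.simple_method!r}")


def filter_low_coverage_bins(matrix: ContactMatrix,
                             threshold: float = 10.0) -> ContactMatrix:
    """Zero out bins whose raw-count vector has Euclidean norm < threshold.

    Applied to raw counts before any normalization.  For intra matrices the
    matching column of each removed row is zeroed as well; for inter matrices
    rows and columns are screened independently against their own norms.
    """
    values = matrix.values.copy()
    row_norms = np.linalg.norm(values, axis=1)
    bad_rows = set(np.nonzero(row_norms < threshold)[0].tolist()) | set(matrix.removed_rows)
    if matrix.is_intra:
        bad_cols = set(bad_rows)
    else:
        col_norms = np.linalg.norm(values, axis=0)
        bad_cols = set(np.nonzero(col_norms < threshold)[0].tolist()) | set(matrix.removed_cols)
    if len(bad_rows) == values.shape[0] or len(bad_cols) == values.shape[1]:
        raise ValueError("all bins removed by low-coverage filter: nothing to normalize")
    values[sorted(bad_rows), :] = 0.0
    values[:, sorted(bad_cols)] = 0.0
    return matrix.with_values(values, removed_rows=frozenset(bad_rows),
                              removed_cols=frozenset(bad_cols))


def scn_normalize(matrix: ContactMatrix,
                  params: NormalizationParams | None = None) -> ContactMatrix:
    """Sequential Component Normalization.

    Repeats {divide each column by its Euclidean norm; divide each row by its
    Euclidean norm} until ``max|M - M^T| < scn_tolerance`` (square matrices)
    or the iterate stops changing (rectangular inter maps), up to
    ``scn_max_iter`` sweeps.  Zero rows/columns are left untouched and
    recorded as removed bins.  Non-convergence raises a warning and returns
    the last iterate.
    """
    params = params or NormalizationParams()
    values = matrix.values.astype(float).copy()
    if not np.any(values):
        raise ValueError("matrix has no non-zero entries")
    square = values.shape[0] == values.shape[1]
    converged = False
    for _ in range(params.scn_max_iter):
        previous = values.copy()
        col_norms = np.linalg.norm(values, axis=0)
        col_norms[col_norms == 0] = 1.0  # zero columns stay untouched
        values /= col_norms[np.newaxis, :]
        row_norms = np.linalg.norm(values, axis=1)
        row_norms[row_norms == 0] = 1.0
        values /= row_norms[:, np.newaxis]
        if square:
            gap = np.max(np.abs(values - values.T))
        else:
            gap = np.max(np.abs(values - previous))
        if gap < params.scn_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(f"SCN did not converge within {params.scn_max_iter} iterations "
                      f"(residual {gap:.3g})", RuntimeWarning, stacklevel=2)
    # rows that ended up all-zero cannot be normalized; record them as removed
    zero_rows = frozenset(np.nonzero(~values.any(axis=1))[0].tolist()) | matrix.removed_rows
    zero_cols = frozenset(np.nonzero(~values.any(axis=0))[0].tolist()) | matrix.removed_cols
    kind = "distance_scn" if matrix.kind == "distance" else "scn"
    return matrix.with_values(values, kind=kind,
                              removed_rows=zero_rows, removed_cols=zero_cols)


def distance_normalize(matrix: ContactMatrix) -> ContactMatrix:
    """Divide every intra cell by the mean count at its genomic distance.

    For each diagonal offset ``d``, cells at offset ``d`` are divided by the
    mean over non-removed cells at the same offset; offsets whose mean is zero
    are left at zero.  Preserves symmetry and non-negativity.
    """
    if not matrix.is_intra:
        raise ValueError("distance normalization applies to intra-chromosomal matrices")
    values = matrix.values.astype(float).copy()
    n = values.shape[0]
    kept = matrix.kept_rows()
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        keep = kept[i] & kept[j]
        if not keep.any():
            continue
        mean = values[i[keep], j[keep]].mean()
        if mean == 0:
            continue
        values[i, j] = values[i, j] / mean
        if d > 0:
            values[j, i] = values[j, i] / mean
    values[~kept, :] = 0.0
    values[:, ~kept] = 0.0
    return matrix.with_values(values, kind="distance")


def distance_scn_normalize(matrix: ContactMatrix,
                           params: NormalizationParams | None = None) -> ContactMatrix:
    """Distance normalization followed by SCN (the combined long-range map)."""
    return scn_normalize(distance_normalize(matrix), params)


def simple_normalize(matrix, method: str) -> np.ndarray:
    """Whole-matrix elementwise scaling: x/avg, (x-min)/max or (x-mean)/sd."""
    values = matrix.values if isinstance(matrix, ContactMatrix) else np.asarray(matrix, float)
    if values.size == 0:
        raise ValueError("empty matrix")
    if method == "x_over_avg":
        mean = values.mean()
        if mean == 0:
            raise ValueError("x_over_avg: matrix mean is zero")
        return values / mean
    if method == "minmax":
        vmax = values.max()
        if vmax == 0:
            raise ValueError("minmax: matrix maximum is zero")
        return (values - values.min()) / vmax
    if method == "zscore":
        sd = values.std()
        if sd == 0:
            raise ValueError("zscore: matrix standard deviation is zero")
        return (values - values.mean()) / sd
    raise ValueError(f"unknown simple method {method!r}")
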