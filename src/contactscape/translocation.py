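"""Detection and correction of reciprocal chromosomal translocations.

A reciprocal translocation exchanges the terminal segments of two
chromosomes.  Contacts within a derivative chromosome that span the fusion
junction are mapped to the *reference* genome as inter-chromosomal contacts,
producing two unusually dense opposite corner blocks in the inter-chromosomal
contact matrix of the two partner chromosomes.  This module

* detects that signature by an exhaustive corner-block split search on the
  coarse (1 Mb) matrix, scoring each candidate breakpoint pair by the ratio
  of the mean count in split-anchored corner blocks (where the junction
  signal peaks) to the mean over clean background quadrants;
* refines each breakpoint through successively finer resolutions (0.1 Mb,
  then 0.01 Mb) inside a window of +-2 coarse bins, by fitting a two-segment
  Poisson step to the marginal contact profile conditioned on the partner
  chromosome's translocated / non-translocated side (the profile drops or
  jumps sharply at the true junction);
* partitions the inter matrix into the four regions induced by the
  breakpoints and reconstructs the corrected inter-chromosomal matrix of the
  derivative chromosomes: junction-artifact regions are background-subtracted
  and genuinely inter-chromosomal regions halved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import BinGrid, Genome
from .matrix import ContactMatrix, bin_contacts
from .pair_filtering import contacts_frame

Side = str  # 'tail' (distal/telomeric segment) or 'head' (proximal segment)


@dataclass(frozen=True)
class TranslocationModel:
    """A reciprocal-translocation call.

    ``breakpoint_a``/``breakpoint_b`` are boundary coordinates in bp (aligned
    to the detection resolution): positions strictly greater than the
    breakpoint lie in the chromosome's *tail* segment.  ``orientation`` names
    the translocated (exchanged) segment of each chromosome.
    """

    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int
    orientation: tuple[Side, Side] = ("tail", "tail")
    score: float = float("nan")
    resolution: int = 10_000

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.chrom_a}\t{self.breakpoint_a}\t"
                     f"{self.chrom_b}\t{self.breakpoint_b}\t"
                     f"{self.orientation[0]}\t{self.orientation[1]}\t"
                     f"{self.score:.6g}\t{self.resolution}\n")

    @classmethod
    def from_tsv(cls, path) -> "TranslocationModel":
        with open(path) as fh:
            tok = fh.readline().rstrip("\n").split("\t")
        return cls(tok[0], int(tok[1]), tok[2], int(tok[3]),
                   (tok[4], tok[5]), float(tok[6]), int(tok[7]))


@dataclass
class RegionPartition:
    """Four-region partition of an inter matrix induced by a breakpoint pair.

    A: non-translocated x non-translocated (true inter background);
    B: translocated x translocated (true inter background after exchange);
    C: non-translocated rows x translocated columns (junction artifact);
    D: translocated rows x non-translocated columns (junction artifact).
    """

    trans_rows: np.ndarray
    trans_cols: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray


def corner_block_scan(matrix: ContactMatrix, window: int = 2):
    """Exhaustive corner-block split search on an inter matrix.

    A translocation junction produces dense blocks whose contact density
    peaks at the breakpoints and decays away from them, so each candidate
    split ``(a, b)`` is scored with blocks of up to ``window`` bins per side
    anchored at the split corner of the dense quadrants (boundary bins
    included -- that is where the signal is strongest).  The background mean
    is estimated from the two complementary quadrants shrunk one bin away
    from the split, which keeps bins straddling a mid-bin breakpoint out of
    the background.  ``score = mean(block) / mean(background)``.

    Candidate signatures are the two reciprocal corner-pair unions (a
    reciprocal exchange lights up two opposite corners) and each single
    corner.  Returns ``(score, a, b, signature)`` for the best split, where
    ``signature`` is ``'anti'`` (dense corners rows<a x cols>=b and
    rows>=a x cols<b, the pattern of a tail-tail exchange) or ``'main'``
    (the other diagonal).
    """
    values = matrix.values
    n, m = values.shape
    if n < 4 or m < 4:
        raise ValueError(f"matrix too small for breakpoint scan ({n} x {m} bins)")
    P = np.zeros((n + 1, m + 1))
    P[1:, 1:] = values.cumsum(axis=0).cumsum(axis=1)

    def rect(r0, r1, c0, c1):
        """Sums over rows r0..r1 x cols c0..c1 (inclusive), vectorized."""
        good = (r1 >= r0) & (c1 >= c0)
        r0c, r1c = np.minimum(r0, n - 1), np.minimum(r1, n - 1)
        c0c, c1c = np.minimum(c0, m - 1), np.minimum(c1, m - 1)
        out = P[r1c + 1, c1c + 1] - P[r0c, c1c + 1] - P[r1c + 1, c0c] + P[r0c, c0c]
        return np.where(good, out, 0.0)

    def cells(r0, r1, c0, c1):
        return (np.maximum(0, r1 - r0 + 1) * np.maximum(0, c1 - c0 + 1)).astype(float)

    a = np.arange(1, n)[:, None]
    b = np.arange(1, m)[None, :]
    # split-anchored windows on each side of the candidate breakpoints
    hr0, hr1 = np.maximum(0, a - window), a - 1          # head-side rows
    tr0, tr1 = a + 0, np.minimum(n - 1, a + window - 1)  # tail-side rows
    hc0, hc1 = np.maximum(0, b - window), b - 1
    tc0, tc1 = b + 0, np.minimum(m - 1, b + window - 1)
    A_blk, nA = rect(hr0, hr1, hc0, hc1), cells(hr0, hr1, hc0, hc1)
    B_blk, nB = rect(tr0, tr1, tc0, tc1), cells(tr0, tr1, tc0, tc1)
    C_blk, nC = rect(hr0, hr1, tc0, tc1), cells(hr0, hr1, tc0, tc1)
    D_blk, nD = rect(tr0, tr1, hc0, hc1), cells(tr0, tr1, hc0, hc1)
    # background quadrants, shrunk one bin away from the split
    zeros = np.zeros_like(a + b)
    bgA = rect(zeros, a - 2, zeros, b - 2)
    bgB = rect(a + 1, zeros + n - 1, b + 1, zeros + m - 1)
    bgC = rect(zeros, a - 2, b + 1, zeros + m - 1)
    bgD = rect(a + 1, zeros + n - 1, zeros, b - 2)
    n_bgA = cells(zeros, a - 2, zeros, b - 2)
    n_bgB = cells(a + 1, zeros + n - 1, b + 1, zeros + m - 1)
    n_bgC = cells(zeros, a - 2, b + 1, zeros + m - 1)
    n_bgD = cells(a + 1, zeros + n - 1, zeros, b - 2)
    anti_bg, n_anti_bg = bgA + bgB, n_bgA + n_bgB    # background for dense C/D
    main_bg, n_main_bg = bgC + bgD, n_bgC + n_bgD    # background for dense A/B
    candidates = [
        ("anti", C_blk + D_blk, nC + nD, anti_bg, n_anti_bg),
        ("main", A_blk + B_blk, nA + nB, main_bg, n_main_bg),
        ("anti", C_blk, nC, anti_bg, n_anti_bg),
        ("anti", D_blk, nD, anti_bg, n_anti_bg),
        ("main", A_blk, nA, main_bg, n_main_bg),
        ("main", B_blk, nB, main_bg, n_main_bg),
    ]
    best = (-np.inf, 1, 1, "anti")
    for signature, blk, n_blk, bg, n_bg in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (blk / n_blk) / (bg / n_bg)
        score = np.where((bg > 0) & (n_bg >= 4) & (n_blk > 0), score, np.nan)
        if np.all(np.isnan(score)):
            continue
        flat = np.nanargmax(score)
        ia, ib = np.unravel_index(flat, score.shape)
        s = score[ia, ib]
        if s > best[0]:
            best = (float(s), int(ia) + 1, int(ib) + 1, signature)
    return best


def _pair_positions(contacts, chrom_a: str, chrom_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions (x on chrom_a, y on chrom_b) of the pair's inter contacts."""
    df = contacts_frame(contacts)
    fwd = df[(df["chrom_a"] == chrom_a) & (df["chrom_b"] == chrom_b)]
    rev = df[(df["chrom_a"] == chrom_b) & (df["chrom_b"] == chrom_a)]
    x = np.concatenate([fwd["pos_a"].to_numpy(int), rev["pos_b"].to_numpy(int)])
    y = np.concatenate([fwd["pos_b"].to_numpy(int), rev["pos_a"].to_numpy(int)])
    return x, y


def _step_loglik(profile: np.ndarray) -> np.ndarray:
    """Two-segment Poisson log-likelihood for every split of a 1-D profile."""
    n = profile.size
    cum = np.concatenate([[0.0], np.cumsum(profile)])
    splits = np.arange(1, n)
    s_left, s_right = cum[splits], cum[n] - cum[splits]
    n_left, n_right = splits.astype(float), (n - splits).astype(float)

    def seg(s, k):
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = s * np.log(s / k) - s
        return np.where(s > 0, ll, 0.0)

    return seg(s_left, n_left) + seg(s_right, n_right)


def _refine_axis(u: np.ndarray, v: np.ndarray, bp_u: int, bp_v: int,
                 length_u: int, res_coarse: int, res_fine: int,
                 trans_v: Side, window: int) -> int:
    """Refine one breakpoint at a finer resolution.

    Bins positions ``u`` (the axis under refinement) inside a window of
    +-``window`` coarse bins around the current estimate, split into the
    contacts whose partner position ``v`` lies on the translocated vs the
    non-translocated side of the partner breakpoint.  Both conditional
    profiles step at the true junction (in opposite directions); the shared
    changepoint maximizing the joint two-segment Poisson likelihood is the
    refined breakpoint.  Contacts whose partner position lies within one
    coarse bin of the partner breakpoint are dropped: the partner estimate
    is only accurate to that resolution, and mis-sided partners would leak
    junction signal across the boundary.
    """
    lo = max(0, bp_u - window * res_coarse)
    hi = min(length_u, bp_u + window * res_coarse)
    lo = (lo // res_fine) * res_fine
    hi = -(-hi // res_fine) * res_fine
    hi = min(hi, (length_u // res_fine) * res_fine)  # keep boundary inside chromosome
    n_bins = (hi - lo) // res_fine
    if n_bins < 2:
        return bp_u
    confident = np.abs(v - bp_v) > res_coarse
    in_window = (u > lo) & (u <= hi) & confident
    if not in_window.any():
        return bp_u
    if trans_v == "tail":
        v_trans = v > bp_v
    else:
        v_trans = v <= bp_v
    bins = (u[in_window] - 1 - lo) // res_fine
    trans_side = v_trans[in_window]
    h_trans = np.bincount(bins[trans_side], minlength=n_bins).astype(float)
    h_non = np.bincount(bins[~trans_side], minlength=n_bins).astype(float)
    loglik = _step_loglik(h_trans) + _step_loglik(h_non)
    split = int(np.argmax(loglik)) + 1
    return int(lo + split * res_fine)


def detect_translocation(contacts, genome: Genome, chrom_a: str, chrom_b: str,
                         resolutions: Sequence[int] = (1_000_000, 100_000, 10_000),
                         enrichment_min: float = 5.0,
                         window: int = 2) -> Optional[TranslocationModel]:
    """Detect a reciprocal translocation between two chromosomes.

    Scans the coarse inter-chromosomal matrix for the opposite-corner-block
    signature; if the best split's enrichment score reaches
    ``enrichment_min``, the two breakpoints are refined through the finer
    resolutions and a :class:`TranslocationModel` is returned, else ``None``.
    """
    if genome.index(chrom_a) > genome.index(chrom_b):
        chrom_a, chrom_b = chrom_b, chrom_a
    res0 = resolutions[0]
    grid_a = genome.grid(chrom_a, res0)
    grid_b = genome.grid(chrom_b, res0)
    coarse = bin_contacts(contacts, grid_a, grid_b)
    score, a, b, signature = corner_block_scan(coarse)
    if not np.isfinite(score) or score < enrichment_min:
        return None
    bp_a, bp_b = a * res0, b * res0
    trans_a, trans_b = ("tail", "tail") if signature == "anti" else ("tail", "head")
    x, y = _pair_positions(contacts, chrom_a, chrom_b)
    res_coarse = res0
    for res_fine in resolutions[1:]:
        # two sweeps per stage: the second refines each axis against the
        # other's already-improved estimate
        for _ in range(2):
            bp_a = _refine_axis(x, y, bp_a, bp_b, genome.length(chrom_a),
                                res_coarse, res_fine, trans_b, window)
            bp_b = _refine_axis(y, x, bp_b, bp_a, genome.length(chrom_b),
                                res_coarse, res_fine, trans_a, window)
        res_coarse = res_fine
    return TranslocationModel(chrom_a, bp_a, chrom_b, bp_b,
                              (trans_a, trans_b), score, resolutions[-1])


def partition_regions(model: TranslocationModel, grid_a: BinGrid,
                      grid_b: BinGrid) -> RegionPartition:
    """Assign every cell of the inter matrix to one of the regions A-D."""

    def trans_mask(grid: BinGrid, breakpoint: int, side: Side) -> np.ndarray:
        k = int(round(breakpoint / grid.resolution))
        if not 0 <= k <= grid.n_bins:
            raise ValueError(f"breakpoint {breakpoint} outside {grid.chromosome}")
        idx = np.arange(grid.n_bins)
        return idx >= k if side == "tail" else idx < k

    tr = trans_mask(grid_a, model.breakpoint_a, model.orientation[0])
    tc = trans_mask(grid_b, model.breakpoint_b, model.orientation[1])
    A = np.outer(~tr, ~tc)
    B = np.outer(tr, tc)
    C = np.outer(~tr, tc)
    D = np.outer(tr, ~tc)
    return RegionPartition(tr, tc, A, B, C, D)


def reconstruct_corrected_matrix(matrix: ContactMatrix,
                                 partition: RegionPartition) -> ContactMatrix:
    """Corrected inter matrix of the derivative chromosomes.

    Regions A and B (true inter-chromosomal contacts, each counted from two
    homologues) are halved; the junction-artifact regions are
    background-subtracted using region A of the *original* counts:
    ``C[i, j] -> max(0, C[i, j] - mean of row i in region A)`` and
    ``D[i, j] -> max(0, D[i, j] - mean of column j in region A)``.
    The reference-genome coordinate frame is kept.
    """
    values = matrix.values
    out = values.astype(float).copy()
    tr, tc = partition.trans_rows, partition.trans_cols
    ntr, ntc = ~tr, ~tc
    if not partition.A.any() and (partition.C.any() or partition.D.any()):
        raise ValueError("region A is empty: no background available for subtraction")
    out[partition.A] = values[partition.A] / 2.0
    out[partition.B] = values[partition.B] / 2.0
    if partition.C.any():
        row_bg = values[:, ntc].mean(axis=1)
        corrected = values[np.ix_(ntr, tc)] - row_bg[ntr][:, None]
        out[np.ix_(ntr, tc)] = np.maximum(0.0, corrected)
    if partition.D.any():
        col_bg = values[ntr, :].mean(axis=0)
        corrected = values[np.ix_(tr, ntc)] - col_bg[ntc][None, :]
        out[np.ix_(tr, ntc)] = np.maximum(0.0, corrected)
    return matrix.with_values(out, kind="corrected")
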