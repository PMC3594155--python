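"""Synthetic Hi-C data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the features of mapped Hi-C read-pair
data that every downstream stage relies on:

* intra-chromosomal contacts with power-law distance decay (rate ~ d^-alpha);
* a two-compartment plaid structure: contacts between bins in the same
  compartment are up-weighted by ``(1 + plaid)`` and cross-compartment
  contacts down-weighted by ``(1 - plaid)``, with compartments assigned in
  alternating blocks of geometric length;
* a uniform inter-chromosomal background.  The default inter share per
  chromosome pair (2%) reflects that in a real genome the inter-chromosomal
  read mass is spread over hundreds of chromosome pairs, so any single pair
  receives only a small fraction of it;
* mapping artifacts: a fraction of records carry 2-3 candidate locations on
  one end (multi-mapping decoys) and a fraction are short-separation pairs
  (< 2 kb apart, self-ligation-like) that the pair filter must remove;
* optionally, a planted reciprocal translocation: pairs involving the two
  partner chromosomes are drawn on the *derivative* chromosomes (distance
  decay running across the fusion junction) and then mapped back to
  reference coordinates, which creates the dense opposite-corner blocks in
  the inter-chromosomal matrix.

Annotations (genes with a mix of entry kinds, TFBS intervals) are generated
alongside, so feature-network construction is exercised end to end.  All
randomness flows from a single seed through named, independently spawned
streams, so outputs are bit-reproducible and adding a new stream does not
shift existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .genome import Genome
from .networks import FeatureInterval, write_features
from .pair_filtering import CandidateLocation, ReadPairRecord, write_pair_table

GENE_KIND_WEIGHTS = {"GENE": 0.6, "PSEUDO": 0.1, "RNA": 0.1, "CDS": 0.1, "UTR": 0.1}


@dataclass(frozen=True)
class TranslocationSpec:
    """A reciprocal tail-tail exchange between two chromosomes.

    The derivative chromosomes are ``head(A) + tail(B)`` and
    ``head(B) + tail(A)``, split at the two breakpoints (bp).
    """

    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int


@dataclass
class SimulationParams:
    """Study conditions for the synthetic dataset.

    The defaults define the standard desk-scale fixture: two 5 Mb
    chromosomes, 200,000 read pairs, distance-decay exponent 1, plaid
    strength 0.6 over 500 kb compartment bins, 10% multi-mapped and 10%
    short-separation artifact records.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_pairs: int = 200_000
    alpha: float = 1.0
    inter_fraction: float = 0.02
    plaid: float = 0.6
    compartment_bin: int = 500_000
    block_mean_bins: float = 2.0
    multi_map_fraction: float = 0.1
    short_pair_fraction: float = 0.1
    min_separation: int = 2000
    read_length: int = 100
    n_genes: int = 60            # per chromosome
    gene_length_range: tuple[int, int] = (5_000, 40_000)
    n_tfbs: int = 150            # per chromosome
    tfbs_length_range: tuple[int, int] = (200, 1_000)
    translocation: Optional[TranslocationSpec] = None
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("inter_fraction", "plaid", "multi_map_fraction",
                     "short_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.multi_map_fraction + self.short_pair_fraction > 1:
            raise ValueError("artifact fractions exceed 1")
        if self.translocation is not None and not isinstance(
                self.translocation, TranslocationSpec):
            self.translocation = TranslocationSpec(**dict(self.translocation))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("compartments", "features", "pairs", "decoys", "shorts")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


@dataclass
class SyntheticGenome:
    genome: Genome
    features: list[FeatureInterval]
    compartments: dict[str, np.ndarray]  # per-chromosome 0/1 labels per bin


def _compartment_labels(n_bins: int, block_mean: float,
                        rng: np.random.Generator) -> np.ndarray:
    labels = np.empty(n_bins, dtype=np.int8)
    current = int(rng.integers(0, 2))
    i = 0
    while i < n_bins:
        run = int(rng.geometric(1.0 / block_mean))
        labels[i:i + run] = current
        current = 1 - current
        i += run
    return labels


def simulate_genome(params: SimulationParams) -> SyntheticGenome:
    """Chromosome table, feature annotations, and compartment labels.

    Genes are placed one per equal-width slot (guaranteeing non-overlap)
    with kinds drawn from the annotation-entry mix, so kind filtering is
    exercised downstream; TFBS are placed the same way in their own slot
    system.  Deterministic given the seed.
    """
    rng = _streams(params.seed)["features"]
    crng = _streams(params.seed)["compartments"]
    genome = Genome(params.chrom_lengths)
    features: list[FeatureInterval] = []
    compartments: dict[str, np.ndarray] = {}
    kinds = list(GENE_KIND_WEIGHTS)
    kind_p = np.array([GENE_KIND_WEIGHTS[k] for k in kinds])
    for chrom in genome:
        length = genome.length(chrom)
        n_bins = -(-length // params.compartment_bin)
        compartments[chrom] = _compartment_labels(n_bins, params.block_mean_bins, crng)
        for prefix, n_feat, (lo, hi), tfbs in (
                ("g", params.n_genes, params.gene_length_range, False),
                ("t", params.n_tfbs, params.tfbs_length_range, True)):
            if n_feat == 0:
                continue
            slot = length // n_feat
            if slot <= hi:
                raise ValueError(
                    f"{chrom}: {n_feat} features of up to {hi} bp do not fit "
                    f"in {length} bp without overlap")
            sizes = rng.integers(lo, hi + 1, size=n_feat)
            offsets = rng.integers(0, slot - sizes)
            for i in range(n_feat):
                start = i * slot + int(offsets[i]) + 1
                kind = "TFBS" if tfbs else kinds[
                    rng.choice(len(kinds), p=kind_p)]
                features.append(FeatureInterval(
                    f"{chrom}_{prefix}{i:03d}", chrom, start,
                    start + int(sizes[i]) - 1, kind))
    return SyntheticGenome(genome, features, compartments)


# ---------------------------------------------------------------------------
# read-pair sampling

class _EffectiveChrom:
    """A chromosome as sampled (reference, or derivative of a translocation)."""

    def __init__(self, name: str, length: int, segments):
        # segments: list of (eff_start_0based, ref_chrom, ref_start_0based, seg_len)
        self.name = name
        self.length = length
        self.segments = segments

    def to_reference(self, pos: np.ndarray):
        """Map 1-based effective positions to (ref chrom array, 1-based pos)."""
        chroms = np.empty(pos.shape, dtype=object)
        ref = np.empty_like(pos)
        for eff_start, ref_chrom, ref_start, seg_len in self.segments:
            inside = (pos > eff_start) & (pos <= eff_start + seg_len)
            chroms[inside] = ref_chrom
            ref[inside] = pos[inside] - eff_start + ref_start
        return chroms, ref


def _effective_chroms(genome: Genome,
                      spec: Optional[TranslocationSpec]) -> list[_EffectiveChrom]:
    effective = []
    for chrom in genome:
        length = genome.length(chrom)
        if spec is None or chrom not in (spec.chrom_a, spec.chrom_b):
            effective.append(_EffectiveChrom(chrom, length, [(0, chrom, 0, length)]))
            continue
        la, lb = genome.length(spec.chrom_a), genome.length(spec.chrom_b)
        bpa, bpb = spec.breakpoint_a, spec.breakpoint_b
        if not 0 < bpa < la or not 0 < bpb < lb:
            raise ValueError("translocation breakpoint outside chromosome")
        if chrom == spec.chrom_a:
            # der(A) = head of A + tail of B
            segments = [(0, spec.chrom_a, 0, bpa),
                        (bpa, spec.chrom_b, bpb, lb - bpb)]
            effective.append(_EffectiveChrom(chrom, bpa + lb - bpb, segments))
        else:
            segments = [(0, spec.chrom_b, 0, bpb),
                        (bpb, spec.chrom_a, bpa, la - bpa)]
            effective.append(_EffectiveChrom(chrom, bpb + la - bpa, segments))
    return effective


def _label_of(compartments, chroms: np.ndarray, pos: np.ndarray,
              bin_size: int) -> np.ndarray:
    labels = np.empty(pos.shape, dtype=np.int8)
    for chrom in np.unique(chroms.astype(str)):
        mask = chroms == chrom
        labels[mask] = compartments[chrom][(pos[mask] - 1) // bin_size]
    return labels


class _SeparationSampler:
    """Inverse-CDF sampling of intra separations on a 1 kb power-law grid.

    The contact rate is ``d^-alpha`` per pair of loci; the number of
    position pairs at separation ``d`` is proportional to ``L - d``, so the
    separation marginal is weighted by both factors.
    """

    def __init__(self, length: int, min_sep: int, alpha: float):
        n_steps = max(1, (length - 1 - min_sep) // 1000)
        d = min_sep + 1000 * np.arange(n_steps, dtype=float)
        w = d ** (-alpha) * (length - d)
        self.grid = d.astype(np.int64)
        self.cdf = np.cumsum(w) / w.sum()
        self.length = length

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        k = np.searchsorted(self.cdf, rng.random(size), side="right")
        k = np.minimum(k, len(self.grid) - 1)
        d = self.grid[k] + rng.integers(0, 1000, size=size)
        return np.minimum(d, self.length - 1)


def simulate_pairs(sg: SyntheticGenome,
                   params: SimulationParams) -> list[ReadPairRecord]:
    """Sample a mapped read-pair table from the synthetic genome.

    Category (normal / multi-mapped / short-separation) and intra vs inter
    status are drawn per record; intra pairs get a power-law separation
    modulated by the compartment plaid (rejection sampling), inter pairs are
    uniform background.  With a translocation spec, pairs on the two partner
    chromosomes are drawn on the derivative chromosomes and mapped back.
    """
    streams = _streams(params.seed)
    rng = streams["pairs"]
    n = params.n_pairs
    genome = sg.genome
    effective = _effective_chroms(genome, params.translocation)
    eff_lengths = np.array([e.length for e in effective], dtype=float)
    eff_p = eff_lengths / eff_lengths.sum()

    u = rng.random(n)
    mm, sp = params.multi_map_fraction, params.short_pair_fraction
    is_multi = u < mm
    is_short = (u >= mm) & (u < mm + sp)
    can_inter = len(effective) >= 2
    is_inter = (rng.random(n) < params.inter_fraction) & ~is_short & can_inter

    chrom_idx_1 = np.empty(n, dtype=object)
    chrom_idx_2 = np.empty(n, dtype=object)
    pos1 = np.zeros(n, dtype=np.int64)
    pos2 = np.zeros(n, dtype=np.int64)

    # --- intra pairs with distance decay and plaid modulation
    intra_idx = np.nonzero(~is_inter & ~is_short)[0]
    eff_choice = rng.choice(len(effective), size=intra_idx.size, p=eff_p)
    samplers = [_SeparationSampler(e.length, params.min_separation, params.alpha)
                for e in effective]
    for ci, eff in enumerate(effective):
        targets = intra_idx[eff_choice == ci]
        if targets.size == 0:
            continue
        need = targets.size
        got_c1, got_p1, got_c2, got_p2 = [], [], [], []
        collected = 0
        while collected < need:
            batch = max(32, int((need - collected) / 0.45) + 8)
            d = samplers[ci].sample(rng, batch)
            start = rng.integers(1, eff.length - d + 1)
            c1, p1 = eff.to_reference(start)
            c2, p2 = eff.to_reference(start + d)
            lab1 = _label_of(sg.compartments, c1, p1, params.compartment_bin)
            lab2 = _label_of(sg.compartments, c2, p2, params.compartment_bin)
            w = np.where(lab1 == lab2, 1.0 + params.plaid, 1.0 - params.plaid)
            accept = rng.random(batch) * (1.0 + params.plaid) < w
            got_c1.append(c1[accept]); got_p1.append(p1[accept])
            got_c2.append(c2[accept]); got_p2.append(p2[accept])
            collected += int(accept.sum())
        c1 = np.concatenate(got_c1)[:need]; p1 = np.concatenate(got_p1)[:need]
        c2 = np.concatenate(got_c2)[:need]; p2 = np.concatenate(got_p2)[:need]
        chrom_idx_1[targets] = c1; pos1[targets] = p1
        chrom_idx_2[targets] = c2; pos2[targets] = p2

    # --- uniform inter-chromosomal background
    inter_idx = np.nonzero(is_inter)[0]
    if inter_idx.size:
        ca = rng.choice(len(effective), size=inter_idx.size, p=eff_p)
        cb = np.empty_like(ca)
        pending = np.ones(inter_idx.size, dtype=bool)
        while pending.any():
            draw = rng.choice(len(effective), size=int(pending.sum()), p=eff_p)
            sel = np.nonzero(pending)[0]
            cb[sel] = draw
            pending[sel] = cb[sel] == ca[sel]
        for side, choice, (cc, pp) in (("a", ca, (chrom_idx_1, pos1)),
                                       ("b", cb, (chrom_idx_2, pos2))):
            for ci, eff in enumerate(effective):
                targets = inter_idx[choice == ci]
                if targets.size == 0:
                    continue
                raw = rng.integers(1, eff.length + 1, size=targets.size)
                chroms, refs = eff.to_reference(raw)
                cc[targets] = chroms
                pp[targets] = refs

    # --- short-separation artifact pairs (self-ligation-like)
    short_rng = streams["shorts"]
    short_idx = np.nonzero(is_short)[0]
    if short_idx.size:
        choice = short_rng.choice(len(effective), size=short_idx.size, p=eff_p)
        d = short_rng.integers(50, params.min_separation, size=short_idx.size)
        for ci, eff in enumerate(effective):
            targets = short_idx[choice == ci]
            if targets.size == 0:
                continue
            dd = d[choice == ci]
            start = short_rng.integers(1, eff.length - dd + 1)
            c1, p1 = eff.to_reference(start)
            c2, p2 = eff.to_reference(start + dd)
            chrom_idx_1[targets] = c1; pos1[targets] = p1
            chrom_idx_2[targets] = c2; pos2[targets] = p2

    # --- assemble records, planting multi-mapping decoys
    decoy_rng = streams["decoys"]
    chrom_names = genome.chromosomes
    records: list[ReadPairRecord] = []
    for i in range(n):
        loc1 = CandidateLocation(str(chrom_idx_1[i]), int(pos1[i]), "+")
        loc2 = CandidateLocation(str(chrom_idx_2[i]), int(pos2[i]), "-")
        end1: tuple = (loc1,)
        end2: tuple = (loc2,)
        if is_multi[i]:
            n_decoys = int(decoy_rng.integers(1, 3))
            decoys = []
            for _ in range(n_decoys):
                dc = chrom_names[int(decoy_rng.integers(0, len(chrom_names)))]
                dp = int(decoy_rng.integers(1, genome.length(dc) + 1))
                decoys.append(CandidateLocation(dc, dp, "+"))
            if decoy_rng.integers(0, 2):
                end1 = (loc1, *decoys)
            else:
                end2 = (loc2, *decoys)
        records.append(ReadPairRecord(f"r{i:07d}", end1, end2,
                                      read_length=params.read_length))
    return records


def plant_translocation(sg: SyntheticGenome,
                        params: SimulationParams) -> list[ReadPairRecord]:
    """Read pairs carrying a planted reciprocal-translocation signature."""
    if params.translocation is None:
        raise ValueError("params.translocation is not set")
    return simulate_pairs(sg, params)


# ---------------------------------------------------------------------------
# dataset assembly and truth files

@dataclass
class SyntheticDataset:
    genome: Genome
    features: list[FeatureInterval]
    compartments: dict[str, np.ndarray]
    records: list[ReadPairRecord]
    params: SimulationParams


def simulate_dataset(params: SimulationParams,
                     out_dir: Optional[Path] = None) -> SyntheticDataset:
    """Generate genome, annotations and read pairs; optionally write them.

    Writes ``genome.tsv``, ``features.tsv``, ``pairs.tsv`` and a
    ``truth.json`` recording the planted parameters for recovery tests.
    """
    sg = simulate_genome(params)
    records = simulate_pairs(sg, params)
    ds = SyntheticDataset(sg.genome, sg.features, sg.compartments, records, params)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ds.genome.to_tsv(out_dir / "genome.tsv")
        write_features(ds.features, out_dir / "features.tsv")
        write_pair_table(ds.records, out_dir / "pairs.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth_dict(ds), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return ds


def truth_dict(ds: SyntheticDataset) -> dict:
    params = dataclasses.asdict(ds.params)
    params["chrom_lengths"] = dict(ds.params.chrom_lengths)
    if ds.params.translocation is not None:
        params["translocation"] = dataclasses.asdict(ds.params.translocation)
    return {
        "params": params,
        "compartments": {c: labels.tolist() for c, labels in ds.compartments.items()},
    }
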