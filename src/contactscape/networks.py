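"""Spatial interaction networks of genes and transcription-factor binding sites.

Contacts whose two ends fall inside annotated features induce a weighted
undirected graph: nodes are features (genes, TFBS), an edge connects two
features when the number of contacts linking them exceeds a threshold, and
the edge weight is that contact count.  Gene networks keep only ``GENE``
annotation entries (``PSEUDO``, ``RNA``, ``CDS``, ``UTR`` records are
excluded); isolated features never appear as nodes.

The graph statistics used to characterise these networks (degree and
shortest-path histograms, clustering coefficient, closeness centrality,
stress, topological coefficient, and the log-log power-law fit that
diagnoses scale-free structure) are implemented here directly from their
definitions; they operate on any ``networkx`` graph.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .pair_filtering import contacts_frame

GENE_KINDS_EXCLUDED = ("PSEUDO", "RNA", "CDS", "UTR")


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic feature: 1-based inclusive interval with a kind tag."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str = "GENE"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start > end")


def read_features(path) -> list[FeatureInterval]:
    """Read a 5-column (id, chrom, start, end, kind) TSV annotation table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["id", "chrom", "start", "end", "kind"],
                     dtype={"id": str, "chrom": str, "kind": str})
    return [FeatureInterval(r.id, r.chrom, int(r.start), int(r.end), r.kind)
            for r in df.itertuples(index=False)]


def write_features(features: Iterable[FeatureInterval], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.kind}\n")


def map_contacts_to_features(contacts, features: Sequence[FeatureInterval],
                             node_kinds: Iterable[str] = ("GENE",),
                             ) -> dict[tuple[str, str], int]:
    """Count contacts linking every unordered pair of features.

    Each contact end is matched to *every* feature of an allowed kind whose
    interval contains its position; all cross pairs of distinct features (one
    per end) are incremented.  Ends inside no feature contribute nothing and
    self pairs are dropped.
    """
    kinds = set(node_kinds)
    allowed = [f for f in features if f.kind in kinds]
    trees: dict[str, IntervalTree] = {}
    for f in allowed:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end + 1, f)
    df = contacts_frame(contacts)
    counts: dict[tuple[str, str], int] = {}
    for ca, pa, cb, pb in zip(df["chrom_a"], df["pos_a"], df["chrom_b"], df["pos_b"]):
        hits_a = trees[ca][pa] if ca in trees else ()
        if not hits_a:
            continue
        hits_b = trees[cb][pb] if cb in trees else ()
        for ia in hits_a:
            for ib in hits_b:
                fa, fb = ia.data, ib.data
                if fa.id == fb.id:
                    continue
                key = (fa.id, fb.id) if fa.id < fb.id else (fb.id, fa.id)
                counts[key] = counts.get(key, 0) + 1
    return counts


def feature_kinds(features: Iterable[FeatureInterval]) -> dict[str, str]:
    """id -> kind mapping, for annotating network nodes."""
    return {f.id: f.kind for f in features}


def build_network(counts: Mapping[tuple[str, str], int], threshold: int = 0,
                  kinds: Optional[Mapping[str, str]] = None,
                  metadata: Optional[dict] = None) -> nx.Graph:
    """Weighted undirected graph of feature pairs with count > threshold.

    The threshold is strict; ``threshold=0`` is the "at least one contact"
    network.  Nodes with no surviving edge are omitted.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph(threshold=threshold, **(metadata or {}))
    for (a, b), n in counts.items():
        if n > threshold:
            g.add_edge(a, b, weight=int(n))
    if kinds:
        for node in g.nodes:
            g.nodes[node]["kind"] = kinds.get(node, "GENE")
    return g


def equalize_edges(counts_by_sample: Mapping[str, Mapping[tuple[str, str], int]],
                   target_edges: int) -> dict[str, tuple[int, nx.Graph]]:
    """Per-sample thresholds making every sample's network have equal edges.

    For each sample the smallest integer threshold ``t`` with
    ``|{count > t}| <= target`` is taken; if the strict network falls short
    of the target, pairs with ``count == t`` are added back in deterministic
    order (weight descending, then lexicographic pair id) until exactly
    ``target_edges`` edges remain.
    """
    out: dict[str, tuple[int, nx.Graph]] = {}
    for sample, counts in counts_by_sample.items():
        pairs = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if target_edges > len(pairs):
            raise ValueError(
                f"sample {sample!r}: target {target_edges} exceeds "
                f"{len(pairs)} available pairs")
        if target_edges == len(pairs):
            t = 0
            chosen = pairs
        else:
            t = pairs[target_edges][1]
            chosen = [kv for kv in pairs if kv[1] > t]
            ties = [kv for kv in pairs if kv[1] == t]
            chosen += ties[: target_edges - len(chosen)]
        g = nx.Graph(threshold=t, sample=sample)
        for (a, b), n in chosen:
            g.add_edge(a, b, weight=int(n))
        out[sample] = (t, g)
    return out


# ---------------------------------------------------------------------------
# graph statistics (implemented from their definitions)

def _adjacency(g: nx.Graph) -> tuple[list, dict, list[set]]:
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    neigh = [set(index[m] for m in g.neighbors(n)) for n in nodes]
    return nodes, index, neigh


def _bfs(neigh: list[set], s: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unweighted)."""
    n = len(neigh)
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=float)
    dist[s], sigma[s] = 0, 1.0
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in neigh[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _all_pairs(g: nx.Graph):
    nodes, _, neigh = _adjacency(g)
    n = len(nodes)
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s], sigma[s] = _bfs(neigh, s)
    return nodes, neigh, dist, sigma


def degree_histogram(g: nx.Graph) -> dict[int, int]:
    """Node count per degree; counts sum to the number of nodes."""
    hist: dict[int, int] = {}
    for _, d in g.degree:
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def shortest_path_histogram(g: nx.Graph) -> dict[int, int]:
    """Number of unordered reachable node pairs per shortest-path length."""
    _, _, dist, _ = _all_pairs(g)
    iu = np.triu_indices(dist.shape[0], k=1)
    lengths = dist[iu]
    lengths = lengths[lengths > 0]
    unique, counts = np.unique(lengths, return_counts=True)
    return {int(k): int(c) for k, c in zip(unique, counts)}


def clustering_coefficient(g: nx.Graph, node) -> float:
    """2 e_n / (k_n (k_n - 1)): the edge density among a node's neighbors."""
    neighbors = list(g.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(1 for i in range(k) for j in range(i + 1, k)
            if g.has_edge(neighbors[i], neighbors[j]))
    return 2.0 * e / (k * (k - 1))


def closeness_centrality(g: nx.Graph, node) -> float:
    """Reciprocal of the mean shortest-path length to reachable nodes (0 if isolated)."""
    nodes, index, neigh = _adjacency(g)
    dist, _ = _bfs(neigh, index[node])
    reachable = dist > 0
    if not reachable.any():
        return 0.0
    return float(reachable.sum() / dist[reachable].sum())


def stress_values(g: nx.Graph) -> dict:
    """Stress of every node: the number of shortest paths passing through it.

    All shortest paths between each unordered pair (s, t), s != n != t, are
    counted, not one representative per pair.
    """
    nodes, _, dist, sigma = _all_pairs(g)
    n = len(nodes)
    stress = {}
    iu = np.triu_indices(n, k=1)
    d_st = dist[iu]
    for vi, v in enumerate(nodes):
        through = (dist[iu[0], vi] + dist[vi, iu[1]] == d_st)
        valid = (iu[0] != vi) & (iu[1] != vi) & (d_st >= 0) \
            & (dist[iu[0], vi] > 0) & (dist[vi, iu[1]] > 0)
        paths = sigma[iu[0], vi] * sigma[vi, iu[1]]
        stress[v] = int(paths[through & valid].sum())
    return stress


def stress_distribution(g: nx.Graph) -> tuple[dict, dict[int, int]]:
    """Per-node stress plus a histogram binned by powers of ten.

    Histogram keys are bin lower bounds: 0, 1, 10, 100, ... covering
    [0], [1, 9], [10, 99], ...
    """
    stress = stress_values(g)
    hist: dict[int, int] = {}
    for v in stress.values():
        lower = 0 if v == 0 else 10 ** int(math.floor(math.log10(v)))
        hist[lower] = hist.get(lower, 0) + 1
    return stress, dict(sorted(hist.items()))


def topological_coefficient(g: nx.Graph, node) -> float:
    """Mean shared-neighbor count over a node's partners, divided by its degree.

    A partner is any node sharing at least one neighbor with ``node`` or
    directly linked to it; the shared-neighbor count J gains 1 for a direct
    link.  Nodes with fewer than two neighbors score 0.
    """
    nn = set(g.neighbors(node))
    k = len(nn)
    if k <= 1:
        return 0.0
    partners = set()
    for u in nn:
        partners.update(g.neighbors(u))
        partners.add(u)
    partners.discard(node)
    js = []
    for m in partners:
        j = len(nn & set(g.neighbors(m)))
        if g.has_edge(node, m):
            j += 1
        if j > 0:
            js.append(j)
    if not js:
        return 0.0
    return float(np.mean(js)) / k


def scale_free_fit(hist: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares line through (log10 degree, log10 count).

    Returns (slope, R^2); a slope near -2 with high R^2 is the scale-free
    signature.  Requires at least three distinct degrees with positive count.
    """
    points = [(k, c) for k, c in hist.items() if k > 0 and c > 0]
    if len(points) < 3:
        raise ValueError("need at least 3 distinct positive degrees to fit")
    x = np.log10([k for k, _ in points])
    y = np.log10([c for _, c in points])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return float(slope), r2


def node_metrics_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node table of all graph statistics (sorted by node id)."""
    stress = stress_values(g)
    rows = []
    for n in sorted(g.nodes):
        rows.append({
            "id": n,
            "kind": g.nodes[n].get("kind", ""),
            "degree": g.degree[n],
            "clustering": clustering_coefficient(g, n),
            "closeness": closeness_centrality(g, n),
            "stress": stress[n],
            "topological_coefficient": topological_coefficient(g, n),
        })
    return pd.DataFrame(rows)


def write_edge_list(g: nx.Graph, path) -> None:
    """Weighted edge-list TSV: idA, idB, weight, kindA, kindB."""
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            ka = g.nodes[a].get("kind", "")
            kb = g.nodes[b].get("kind", "")
            fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\t{ka}\t{kb}\n")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            a, b, w, ka, kb = line.rstrip("\n").split("\t")
            g.add_edge(a, b, weight=int(w))
            if ka:
                g.nodes[a]["kind"] = ka
            if kb:
                g.nodes[b]["kind"] = kb
    return g
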