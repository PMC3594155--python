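"""Independent brute-force oracles for graph statistics.

Deliberately naive: exhaustive enumeration via networkx primitives, kept
separate from the implementations they check.
"""

from itertools import combinations

import networkx as nx
import numpy as np


def degree_hist_oracle(g):
    adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    degrees = adj.sum(axis=1).astype(int)
    hist = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    return hist


def path_hist_oracle(g):
    hist = {}
    for s, t in combinations(sorted(g.nodes), 2):
        try:
            d = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        hist[d] = hist.get(d, 0) + 1
    return hist


def clustering_oracle(g, n):
    neighbors = list(g.neighbors(n))
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(1 for u, v in combinations(neighbors, 2) if g.has_edge(u, v))
    return 2.0 * e / (k * (k - 1))


def closeness_oracle(g, n):
    lengths = nx.single_source_shortest_path_length(g, n)
    others = [d for m, d in lengths.items() if m != n]
    if not others:
        return 0.0
    return len(others) / sum(others)


def stress_oracle(g, n):
    total = 0
    for s, t in combinations(sorted(g.nodes), 2):
        if n in (s, t):
            continue
        try:
            paths = nx.all_shortest_paths(g, s, t)
            total += sum(1 for p in paths if n in p[1:-1])
        except nx.NetworkXNoPath:
            continue
    return total


def topological_oracle(g, n):
    nn = set(g.neighbors(n))
    if len(nn) <= 1:
        return 0.0
    js = []
    for m in g.nodes:
        if m == n:
            continue
        shared = len(nn & set(g.neighbors(m)))
        direct = g.has_edge(n, m)
        if shared == 0 and not direct:
            continue
        js.append(shared + (1 if direct else 0))
    js = [j for j in js if j > 0]
    if not js:
        return 0.0
    return float(np.mean(js)) / len(nn)
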