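"""Independent slow oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive scans, O(n^2)/O(n^3)
algorithms, numerical quadrature) and shares no code with the package's own
code paths beyond the data containers.
"""

import math

import networkx as nx
import numpy as np
from scipy.integrate import quad


def to_networkx(skeleton):
    g = nx.Graph()
    for n in skeleton.nodes:
        g.add_node(n.id, pos=n.position)
    for parent, child in skeleton.edges():
        w = float(
            np.linalg.norm(skeleton.node(parent).position - skeleton.node(child).position)
        )
        g.add_edge(parent, child, weight=w)
    return g


def _terminal_paths(g, root):
    """(leaf, path nodes distal of the critical point, length) per terminal."""
    critical = {root} | {n for n in g if g.degree(n) >= 3}
    out = []
    for leaf in g:
        if g.degree(leaf) != 1 or leaf == root:
            continue
        path = [leaf]
        length = 0.0
        cur, prev = leaf, None
        while cur not in critical or cur == leaf:
            nbrs = [x for x in g.neighbors(cur) if x != prev]
            if not nbrs:
                break
            nxt = nbrs[0]
            length += g.edges[cur, nxt]["weight"]
            prev, cur = cur, nxt
            if cur in critical:
                break
            path.append(cur)
        out.append((leaf, path, length))
    return out


def brute_force_prune(skeleton, threshold):
    """Repeated single-branch removal to a fixpoint (sweep frozen per round).

    Returns the surviving node id set.  Within each round the short terminal
    branches are identified once, then removed one at a time; trees with no
    branch point are left untouched.
    """
    g = to_networkx(skeleton)
    root = skeleton.root_id
    while True:
        if not any(g.degree(n) >= 3 or (n == root and g.degree(n) >= 2) for n in g):
            return set(g.nodes)
        short = [
            path for _, path, length in _terminal_paths(g, root) if length < threshold
        ]
        if not short:
            return set(g.nodes)
        for path in short:
            g.remove_nodes_from(path)
    return set(g.nodes)


def brute_force_single_linkage(points, link_radius):
    """O(n^3) agglomerative single-linkage clustering at a cut distance."""
    clusters = [{i} for i in range(len(points))]
    merged = True
    while merged:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d <= link_radius:
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    return clusters


class UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(pairs):
    uf = UnionFind()
    for a, b in pairs:
        uf.union(a, b)
    comps = {}
    for x in uf.parent:
        comps.setdefault(uf.find(x), set()).add(x)
    return sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), min(c)))


def run_scan_windows(counts, min_samples, min_span):
    """Exhaustive scan for maximal non-zero runs and their detectability."""
    out = []
    n = len(counts)
    i = 0
    while i < n:
        if counts[i] > 0:
            j = i
            while j + 1 < n and counts[j + 1] > 0:
                j += 1
            total = sum(counts[i : j + 1])
            out.append((i, j, total, total >= min_samples and (j - i + 1) >= min_span))
            i = j + 1
        i += 1
    return out


def t_sf_quadrature(t, df):
    """Upper-tail t probability by numerical quadrature of the density."""

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(pdf, t, np.inf, limit=200)
    return val


def permutation_two_sample_p(a, b, n_perm, rng):
    """Permutation p-value for mean(b) > mean(a) by label shuffling."""
    pooled = np.concatenate([a, b])
    observed = np.mean(b) - np.mean(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if np.mean(perm[len(a):]) - np.mean(perm[: len(a)]) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
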