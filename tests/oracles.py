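"""Independent brute-force oracles used by the property and acceptance tests.

Deliberately written with plain loops and naive enumeration, sharing no
code path with the implementations they check.
"""
import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Unrooted binary trees by exhaustive edge insertion
# ---------------------------------------------------------------------------

def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists."""
    base = [(n, 0), (n, 1), (n, 2)]  # star on three leaves
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_node in trees:
            for k, (u, v) in enumerate(edges):
                w = next_node
                new = edges[:k] + edges[k + 1:] + [(u, w), (w, v), (w, leaf)]
                nxt.append((new, next_node + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def path_edges(edges, a, b):
    adj = _adjacency(edges)
    prev = {a: None}
    queue = [a]
    while queue:
        x = queue.pop(0)
        if x == b:
            break
        for y in adj[x]:
            if y not in prev:
                prev[y] = x
                queue.append(y)
    path = []
    x = b
    while prev[x] is not None:
        path.append(frozenset((x, prev[x])))
        x = prev[x]
    return path


def tree_splits(edges, n):
    """Non-trivial leaf bipartitions, canonical side excludes leaf 0."""
    adj = _adjacency(edges)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def minimum_evolution_tree(D):
    """Exhaustive minimum-evolution: OLS branch lengths on every topology,
    smallest total length wins.  Returns the winning topology's splits."""
    n = D.shape[0]
    best = (np.inf, None)
    for edges in enumerate_topologies(n):
        edge_ids = {frozenset(e): i for i, e in enumerate(edges)}
        pairs = list(itertools.combinations(range(n), 2))
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (a, b) in enumerate(pairs):
            for e in path_edges(edges, a, b):
                A[r, edge_ids[e]] = 1
            y[r] = D[a, b]
        lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
        total = lengths.sum()
        if total < best[0] - 1e-12:
            best = (total, tree_splits(edges, n))
    return best[1]


def random_additive_matrix(n, rng):
    """Distances realized on a random binary topology with random positive
    branch lengths (hence exactly additive)."""
    edges = enumerate_topologies(n)[rng.integers(
        len(enumerate_topologies(n)))]
    lengths = {frozenset(e): rng.uniform(0.1, 1.0) for e in edges}
    D = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        D[a, b] = D[b, a] = sum(lengths[e] for e in path_edges(edges, a, b))
    return D, tree_splits(edges, n)


# ---------------------------------------------------------------------------
# Threshold-optimization by direct per-query evaluation
# ---------------------------------------------------------------------------

def threshold_errors(D, species, grid):
    """(false positives + false negatives) per threshold, naive loops."""
    n = len(species)
    errors = []
    for t in grid:
        fp = fn = 0
        for q in range(n):
            neighbours = [j for j in range(n)
                          if j != q and D[q, j] <= t + 1e-12]
            conspecifics = [j for j in range(n)
                            if j != q and species[j] == species[q]]
            if conspecifics:
                if not neighbours:
                    fn += 1
                elif any(species[j] != species[q] for j in neighbours):
                    fp += 1
            else:
                if neighbours:
                    fp += 1
        errors.append(fp + fn)
    return np.asarray(errors)


# ---------------------------------------------------------------------------
# PERMANOVA by definition
# ---------------------------------------------------------------------------

def permanova_f(D, labels):
    """Pseudo-F from the definition, naive double loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += D[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for i in idx:
            for j in idx:
                if i < j:
                    acc += D[i, j] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exact_p(D, labels):
    """Exact permutation p over all label orderings (identity included)."""
    f_obs = permanova_f(D, labels)
    labels = list(labels)
    hits = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if permanova_f(D, list(perm)) >= f_obs - 1e-12:
            hits += 1
    return hits / total
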