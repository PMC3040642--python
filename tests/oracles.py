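"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (character loops, math.log,
exhaustive enumeration) and shares no code with the package internals.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
ACGT = {"A", "C", "G", "T"}


def k2p_oracle(a: str, b: str, min_overlap: int = 300) -> float:
    """Textbook K2P distance via an explicit per-character loop."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in ACGT or y not in ACGT:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n < min_overlap:
        return math.nan
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return math.nan
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def p_distance_oracle(a: str, b: str) -> float:
    """Raw proportion of differing sites among jointly unambiguous sites."""
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ACGT and y in ACGT:
            n += 1
            diff += x != y
    return diff / n if n else math.nan


def nn_bruteforce(m) -> dict[str, tuple[str, float]]:
    """Nearest neighbour per species by a double loop over specimen pairs."""
    best: dict[str, tuple[float, str]] = {}
    n = len(m.ids)
    for i in range(n):
        for j in range(n):
            if i == j or m.species[i] == m.species[j]:
                continue
            v = m.d[i, j]
            if math.isnan(v):
                continue
            sp, other = m.species[i], m.species[j]
            cur = best.get(sp)
            if cur is None or v < cur[0] or (v == cur[0] and other < cur[1]):
                best[sp] = (v, other)
    return {sp: (other, v) for sp, (v, other) in best.items()}


def mpd_bruteforce(m) -> dict[str, float]:
    """Max conspecific distance per species (>=2 specimens) by double loop."""
    out: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sp in m.species:
        counts[sp] = counts.get(sp, 0) + 1
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if m.species[i] != m.species[j]:
                continue
            v = m.d[i, j]
            if math.isnan(v):
                continue
            sp = m.species[i]
            out[sp] = max(out.get(sp, -1.0), v)
    return {sp: v for sp, v in out.items() if counts[sp] >= 2}


# ---------------------------------------------------------------------------
# trees: random additive matrices and exhaustive least-squares topology search


def random_tree_edges(
    n_leaves: int, rng: np.random.Generator, lo: float = 0.05, hi: float = 0.3
) -> dict[frozenset, float]:
    """Random unrooted binary tree as an edge->length map.

    Leaves are 0..n-1, internal nodes negative.  Built by attaching each
    new leaf to a uniformly chosen existing edge.
    """
    edges = {
        frozenset((0, -1)): rng.uniform(lo, hi),
        frozenset((1, -1)): rng.uniform(lo, hi),
        frozenset((2, -1)): rng.uniform(lo, hi),
    }
    next_internal = -2
    for leaf in range(3, n_leaves):
        target = list(edges)[rng.integers(len(edges))]
        length = edges.pop(target)
        u, v = tuple(target)
        mid = next_internal
        next_internal -= 1
        split = rng.uniform(0.25, 0.75)
        edges[frozenset((u, mid))] = length * split
        edges[frozenset((mid, v))] = length * (1 - split)
        edges[frozenset((leaf, mid))] = rng.uniform(lo, hi)
    return edges


def path_distances(edges: dict[frozenset, float], n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf path lengths of an edge map (graph BFS per leaf)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    out = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for dst in range(n_leaves):
            out[src, dst] = dist[dst]
    return out


def all_topologies(n_leaves: int):
    """Yield every unrooted binary topology as an edge set (lengths 1.0)."""
    base = {frozenset((0, -1)), frozenset((1, -1)), frozenset((2, -1))}
    tops = [base]
    next_internal = -2
    for leaf in range(3, n_leaves):
        new = []
        for top in tops:
            for target in top:
                u, v = tuple(target)
                mid = next_internal
                t2 = set(top)
                t2.remove(target)
                t2 |= {frozenset((u, mid)), frozenset((mid, v)), frozenset((leaf, mid))}
                new.append(t2)
        tops = new
        next_internal -= 1
    yield from tops


def splits_of_edges(edges, n_leaves: int) -> set[frozenset]:
    """Non-trivial leaf bipartitions (as the smaller/canonical side)."""
    adj: dict[int, set[int]] = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for e in edges:
        u, v = tuple(e)
        # leaves reachable from u without crossing e
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb == v and node == u:
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(x for x in seen if 0 <= x < n_leaves)
        if 1 < len(side) < n_leaves - 1:
            comp = frozenset(range(n_leaves)) - side
            out.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
    return out


def least_squares_tree_search(dm: np.ndarray) -> tuple[set[frozenset], float]:
    """Exhaustively fit every topology by OLS; return best splits + residual.

    For an additive matrix exactly one topology attains (near-)zero
    residual, so this is an independent oracle for tree reconstruction.
    """
    n = dm.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    y = np.array([dm[i, j] for i, j in pairs])
    best = (None, math.inf)
    for top in all_topologies(n):
        edge_list = sorted(top, key=lambda e: sorted(tuple(e)))
        # indicator matrix: does edge e lie on the path i-j?
        A = np.zeros((len(pairs), len(edge_list)))
        for col, e in enumerate(edge_list):
            with_e = {ee: 1.0 for ee in top}
            without = dict(with_e)
            without[e] = 0.0
            d_with = path_distances(with_e, n)
            d_without = path_distances(without, n)
            for row, (i, j) in enumerate(pairs):
                A[row, col] = d_with[i, j] - d_without[i, j]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ coef - y) ** 2).sum())
        if resid < best[1]:
            best = (splits_of_edges(top, n), resid)
    return best
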