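"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, tiny linear systems — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np


# --- betweenness by exhaustive simple-path enumeration --------------------

def _all_simple_paths(adj: dict, s, t) -> list[list]:
    paths = []

    def walk(node, seen, acc):
        if node == t:
            paths.append(acc[:])
            return
        for nxt in adj[node]:
            if nxt not in seen:
                walk(nxt, seen | {nxt}, acc + [nxt])

    walk(s, {s}, [s])
    return paths


def brute_force_betweenness(edges: list[tuple], nodes: list) -> dict:
    """Unnormalized betweenness: for every unordered pair, enumerate ALL
    simple paths, keep the shortest ones, split one unit evenly."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


# --- Fisher exact p by hypergeometric summation ---------------------------

def fisher_oracle(table, alternative: str = "two-sided") -> float:
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(x: int) -> Fraction:
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    if alternative == "greater":
        return float(sum(pmf(x) for x in range(a, hi + 1)))
    if alternative == "less":
        return float(sum(pmf(x) for x in range(lo, a + 1)))
    obs = pmf(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= obs))


# --- Wilcoxon rank-sum p by full permutation enumeration ------------------

def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_oracle(x, y) -> float:
    """Two-sided exact p: fraction of group assignments whose rank sum
    deviates from its mean at least as much as the observed one."""
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    n1 = len(x)
    mean_w = n1 * (len(pooled) + 1) / 2.0
    w_obs = sum(ranks[:n1])
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            hits += 1
    return hits / total


# --- two-label asynchronous LPA absorption probabilities ------------------

def lpa_absorption(adj: dict, initial: dict) -> dict[tuple, float]:
    """Exact distribution over final label states of asynchronous two-label
    propagation with per-sweep uniform update orders and uniform tie-breaks.

    States are tuples of 0/1 labels over ``sorted(adj)``; a sweep processes
    every node once in a random order (each node adopting the strict
    neighbor majority, branching 50/50 on ties); the process absorbs at the
    end of the first sweep after which every connected node's label is a
    majority label of its neighborhood.  Solved exactly as a finite Markov
    chain over sweep outcomes.
    """
    nodes = sorted(adj)
    idx = {n: i for i, n in enumerate(nodes)}
    nbrs = [tuple(idx[v] for v in adj[n]) for n in nodes]
    n = len(nodes)

    def stable(state: tuple) -> bool:
        for i in range(n):
            if not nbrs[i]:
                continue
            ones = sum(state[j] for j in nbrs[i])
            zeros = len(nbrs[i]) - ones
            if (state[i] == 1 and ones < zeros) or (state[i] == 0 and zeros < ones):
                return False
        return True

    def sweep(state: tuple) -> dict[tuple, Fraction]:
        out: dict[tuple, Fraction] = {}
        per_perm = Fraction(1, factorial(n))
        for perm in itertools.permutations(range(n)):
            frontier = [(list(state), Fraction(1))]
            for v in perm:
                if not nbrs[v]:
                    continue
                nxt = []
                for st, pr in frontier:
                    ones = sum(st[j] for j in nbrs[v])
                    zeros = len(nbrs[v]) - ones
                    if ones > zeros:
                        st2 = st[:]; st2[v] = 1
                        nxt.append((st2, pr))
                    elif zeros > ones:
                        st2 = st[:]; st2[v] = 0
                        nxt.append((st2, pr))
                    else:
                        for lab in (0, 1):
                            st2 = st[:]; st2[v] = lab
                            nxt.append((st2, pr / 2))
                frontier = nxt
            for st, pr in frontier:
                key = tuple(st)
                out[key] = out.get(key, Fraction(0)) + pr * per_perm
        return out

    start = tuple(initial[n_] for n_ in nodes)
    # discover reachable states and one-sweep transitions
    transitions: dict[tuple, dict[tuple, Fraction]] = {}
    todo = [start]
    while todo:
        s = todo.pop()
        if s in transitions:
            continue
        transitions[s] = sweep(s)
        for t in transitions[s]:
            if not stable(t) and t not in transitions:
                todo.append(t)

    transient = [s for s in transitions if not stable(s) or s == start]
    # the start state always undergoes at least one sweep, mirroring the
    # implementation, even if it is already stable
    absorbing = sorted({t for out in transitions.values() for t in out if stable(t)})
    t_index = {s: i for i, s in enumerate(transient)}
    a_index = {s: i for i, s in enumerate(absorbing)}
    T = np.zeros((len(transient), len(transient)))
    R = np.zeros((len(transient), len(absorbing)))
    for s in transient:
        for t, pr in transitions[s].items():
            p = float(pr)
            if stable(t):
                R[t_index[s], a_index[t]] += p
            else:
                T[t_index[s], t_index[t]] += p
    B = np.linalg.solve(np.eye(len(transient)) - T, R)
    row = B[t_index[start]]
    return {state: float(row[a_index[state]]) for state in absorbing}


# --- connected components by union-find -----------------------------------

def union_find_components(nodes, edges) -> list[set]:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))
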