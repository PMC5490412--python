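"""Independent brute-force oracles used only by the test suite.

These are deliberately written against the textbook definitions rather than
the package's implementation paths: current-flow betweenness from grounded
Laplacian solves, hypergeometric tails by draw enumeration, Benjamini-
Hochberg by the step-up recipe, Welch's test from the raw formula, and
Boolean dynamics by exhaustive state-space walks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def current_flow_betweenness_oracle(graph) -> dict:
    """Newman's random-walk betweenness via grounded Laplacian solves.

    For each source-target pair a unit current is injected and extracted;
    each intermediate node's throughput is half the sum of absolute currents
    on its incident edges. Normalized by the number of source-target pairs
    not involving the node, (n-1)(n-2)/2. Avoids the generic pseudoinverse:
    potentials come from solving the reduced (grounded) system directly.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    lap = np.zeros((n, n))
    edges = []
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        i, j = index[u], index[v]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
        edges.append((i, j, w))
    reduced = lap[:-1, :-1]
    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            rhs = np.zeros(n)
            rhs[s], rhs[t] = 1.0, -1.0
            potential = np.zeros(n)
            potential[:-1] = np.linalg.solve(reduced, rhs[:-1])
            throughput = np.zeros(n)
            for i, j, w in edges:
                current = w * abs(potential[i] - potential[j])
                throughput[i] += current / 2.0
                throughput[j] += current / 2.0
            throughput[s] = throughput[t] = 0.0
            betweenness += throughput
    norm = (n - 1) * (n - 2) / 2.0
    return dict(zip(nodes, betweenness / norm))


def hypergeometric_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing the exact pmf over the upper tail."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / total


def benjamini_hochberg_oracle(pvalues):
    """Step-up BH adjustment: q_(i) = min over j>=i of p_(j) * m / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def welch_oracle(a, b):
    """Welch's t, Welch-Satterthwaite df and two-sided p from the raw formula."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def boolean_trajectory_oracle(update, n_nodes: int, start):
    """Walk the synchronous dynamics from ``start`` until a state repeats.

    ``update`` maps a 0/1 tuple to the next 0/1 tuple. Returns (transient,
    cycle) as lists of state tuples, found by exhaustive walking — feasible
    because the state space has only 2**n_nodes states.
    """
    seen = {}
    path = []
    state = tuple(start)
    while state not in seen:
        seen[state] = len(path)
        path.append(state)
        state = tuple(update(state))
    first = seen[state]
    return path[:first], path[first:]


def all_boolean_states(n: int):
    """All 2**n corner states as 0/1 tuples."""
    return list(itertools.product((0, 1), repeat=n))
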