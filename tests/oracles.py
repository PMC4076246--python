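"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — brute
force, enumeration, or closed form — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# brute-force d-separation: enumerate every undirected simple path and
# apply the chain/fork/collider blocking rules triple by triple

def _descendants(edges: set, node) -> set:
    out = set()
    frontier = [node]
    children = {}
    for u, v in edges:
        children.setdefault(u, []).append(v)
    while frontier:
        cur = frontier.pop()
        for child in children.get(cur, []):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


def _undirected_paths(nodes: set, edges: set, x, y):
    neighbors = {n: set() for n in nodes}
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)

    def extend(path):
        last = path[-1]
        if last == y:
            yield list(path)
            return
        for nxt in neighbors[last]:
            if nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([x])


def brute_force_d_separated(nodes, edges, x, y, z) -> bool:
    """True iff every undirected simple path from x to y is blocked by z."""
    edges = set(edges)
    z = set(z)
    for path in _undirected_paths(set(nodes), edges, x, y):
        open_path = True
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = (a, b) in edges and (c, b) in edges
            if collider:
                if b not in z and not (_descendants(edges, b) & z):
                    open_path = False
                    break
            elif b in z:
                open_path = False
                break
        if open_path:
            return False
    return True


def brute_force_backdoor(nodes, edges, x, y, z) -> bool:
    """Backdoor criterion by direct path enumeration: no descendant of x
    in z, and every path whose first edge points into x is blocked."""
    edges = set(edges)
    z = set(z)
    if _descendants(edges, x) & z:
        return False
    for path in _undirected_paths(set(nodes), edges, x, y):
        if len(path) < 2 or (path[1], path[0]) not in edges:
            continue  # not a backdoor path
        open_path = True
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = (a, b) in edges and (c, b) in edges
            if collider:
                if b not in z and not (_descendants(edges, b) & z):
                    open_path = False
                    break
            elif b in z:
                open_path = False
                break
        if open_path:
            return False
    return True


def enumerate_dags(k: int):
    """Yield every labeled DAG on nodes '0'..'k-1' as (nodes, edges)."""
    nodes = [str(i) for i in range(k)]
    pairs = list(itertools.combinations(nodes, 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                edges.add((u, v))
            elif c == 2:
                edges.add((v, u))
        if _is_acyclic_edges(nodes, edges):
            yield nodes, edges


def random_dag(k: int, rng: random.Random):
    """One random labeled DAG on k nodes (edges oriented low → high in a
    random node order, so acyclicity is automatic)."""
    nodes = [str(i) for i in range(k)]
    order = nodes[:]
    rng.shuffle(order)
    rank = {n: i for i, n in enumerate(order)}
    edges = set()
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < 0.4:
            edges.add((u, v) if rank[u] < rank[v] else (v, u))
    return nodes, edges


def _is_acyclic_edges(nodes, edges) -> bool:
    indeg = {n: 0 for n in nodes}
    for _, v in edges:
        indeg[v] += 1
    frontier = [n for n in nodes if indeg[n] == 0]
    seen = 0
    children = {}
    for u, v in edges:
        children.setdefault(u, []).append(v)
    while frontier:
        cur = frontier.pop()
        seen += 1
        for child in children.get(cur, []):
            indeg[child] -= 1
            if indeg[child] == 0:
                frontier.append(child)
    return seen == len(nodes)


# ---------------------------------------------------------------------------
# nonparametric standardization on a discrete-confounder cohort

def standardization(table: pd.DataFrame, strata_cols) -> float:
    """Σ_w P̂(W=w) [P̂(Y|A=1,w) − P̂(Y|A=0,w)] from raw stratum counts."""
    n = len(table)
    psi = 0.0
    for _, stratum in table.groupby(list(strata_cols), observed=True):
        p_w = len(stratum) / n
        exposed = stratum[stratum["A"] == 1]
        unexposed = stratum[stratum["A"] == 0]
        psi += p_w * (exposed["Y"].mean() - unexposed["Y"].mean())
    return psi


# ---------------------------------------------------------------------------
# minimal cohort builders for exact (saturated-model) checks

def discrete_cohort(rng: np.random.Generator, n: int = 4000,
                    p_marital: float = 0.5,
                    p_a=(0.3, 0.7), p_y=((0.05, 0.15), (0.10, 0.35))) -> pd.DataFrame:
    """Cohort whose only varying confounder is binary marital status;
    P(A=1|W=w) = p_a[w] and P(Y=1|A=a,W=w) = p_y[w][a].  All other
    schema columns are held constant so saturated models are 2-stratum."""
    w = rng.binomial(1, p_marital, size=n)
    a = rng.binomial(1, np.asarray(p_a)[w])
    p = np.asarray(p_y)[w, a]
    y = rng.binomial(1, p)
    return pd.DataFrame({
        "age": 30, "education": 1, "marital": w, "gravidity": 2,
        "cd4_nadir": 250.0, "A": a, "Y": y,
        "months_observed": 12.0,
        "frac_visits_coc": np.where(a == 1, 0.5, 0.0),
    })


def saturated_fits(table: pd.DataFrame):
    """Empirical-frequency outcome and propensity maps over the marital
    strata of a :func:`discrete_cohort` table (the saturated MLE)."""
    q = {(w, a): grp["Y"].mean()
         for (w, a), grp in table.groupby(["marital", "A"], observed=True)}
    g = {w: grp["A"].mean() for w, grp in table.groupby("marital", observed=True)}

    def q_fn(a, t):
        a_vec = np.broadcast_to(np.asarray(a), (len(t),))
        return np.array([q[(w, ai)] for w, ai in zip(t["marital"], a_vec)])

    def g_fn(t):
        return np.array([g[w] for w in t["marital"]])

    return q_fn, g_fn
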