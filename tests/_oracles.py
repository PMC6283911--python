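"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — exhaustive enumeration, closed
forms — and shares no code path with the implementations it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


# -- literal EAR scanning ----------------------------------------------------

def scan_bruteforce(seq: str) -> list[tuple[str, int, int]]:
    """All (pattern, start, end) 1-based EAR matches by direct substring tests."""
    out = []
    n = len(seq)
    for i in range(n):
        w5 = seq[i : i + 5]
        if len(w5) == 5:
            if w5[0] == "L" and w5[2] == "L" and w5[4] == "L":
                out.append(("LxLxL", i + 1, i + 5))
            if w5[0] == "D" and w5[1] == "L" and w5[2] == "N" and w5[4] == "P":
                out.append(("DLNP", i + 1, i + 5))
        w6 = seq[i : i + 6]
        if len(w6) == 6 and w6[0] == "D" and w6[1] == "L" and w6[2] == "N" and w6[5] == "P":
            out.append(("DLNP", i + 1, i + 6))
    out.sort(key=lambda t: (t[1], t[2] - t[1], t[0]))
    return out


# -- profile HMM path enumeration -------------------------------------------

def hmm_enumerate_score(hmm, seq: str, mode: str) -> float:
    """Max / log-sum score over explicitly enumerated state paths.

    State machine: Begin enters at any sequence offset; match states are
    traversed 0..K-1 via match/insert/delete moves; the path ends on
    reaching the last match or delete state.  Mirrors the model
    definition, not the dynamic program.
    """
    from earminer.hmm import _encode, _log_tables

    mlo, ilo, lb, lm, li, ld = _log_tables(hmm)
    x = _encode(seq)
    L, K = len(x), hmm.n_match
    scores: list[float] = []

    def rec(state: str, m: int, pos: int, acc: float) -> None:
        if m == K - 1 and state in ("M", "D"):
            scores.append(acc)
            return
        out = {"M": lm, "I": li, "D": ld}[state][m]
        if pos < L:
            rec("M", m + 1, pos + 1, acc + out[0] + mlo[m + 1, x[pos]])
            rec("I", m, pos + 1, acc + out[1] + ilo[x[pos]])
        rec("D", m + 1, pos, acc + out[2])

    for s in range(L + 1):
        if s < L:
            rec("M", 0, s + 1, lb[0] + mlo[0, x[s]])
        rec("D", 0, s, lb[1])
    arr = np.array(scores)
    if mode == "viterbi":
        return float(arr.max())
    top = arr.max()
    return float(top + np.log2(np.exp2(arr - top).sum()))


def random_small_profile(rng, max_states: int = 3):
    """Profile with <= ``max_states`` match states from a random tiny alignment."""
    from earminer.hmm import build_profile

    AA = "ACDEFGHIKLMNPQRSTVWY"
    ncol = int(rng.integers(1, max_states + 1))
    nrow = int(rng.integers(1, 4))
    while True:
        rows = [
            "".join(
                "-" if rng.random() < 0.25 else AA[rng.integers(20)]
                for _ in range(ncol)
            )
            for _ in range(nrow)
        ]
        if any(set(r) != {"-"} for r in rows) and all(
            any(r[c] != "-" for r in rows) for c in range(ncol)
        ):
            try:
                return build_profile(rows)
            except ValueError:  # no column reached match-state occupancy
                continue


# -- hypergeometric over-representation tail ---------------------------------

def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) for a size-n draw from N with K marked, by summation."""
    total = comb(N, n)
    upper = min(K, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, upper + 1)) / total


# -- clique percolation -------------------------------------------------------

def clique_percolation_bruteforce(graph, k: int) -> set[frozenset]:
    """k-clique communities by testing every k-subset and union-find chaining."""
    nodes = sorted(graph.nodes)
    cliques = [
        frozenset(sub)
        for sub in combinations(nodes, k)
        if all(graph.has_edge(a, b) for a, b in combinations(sub, 2))
    ]
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return {frozenset(g) for g in groups.values()}


# -- graph neighbourhood ------------------------------------------------------

def bfs_ball(graph, source, depth: int) -> set:
    """Nodes within ``depth`` hops of ``source`` by plain BFS."""
    frontier, seen = {source}, {source}
    for _ in range(depth):
        nxt = set()
        for u in frontier:
            nxt.update(graph.neighbors(u))
        frontier = nxt - seen
        seen |= nxt
    return seen
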