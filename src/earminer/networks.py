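"""Co-expression networks, k-clique-percolation modules, network comparison.

Co-expression edges come from per-gene top-N neighbour lists under either
Pearson correlation (PCC, descending) or mutual rank (MR, ascending),
where ``MR(a,b) = sqrt(rank_a(b) * rank_b(a))`` and ``rank_a(b)`` is b's
1-based position in a's PCC-descending neighbour list.  The edge set is
the union over genes, so it is symmetric and order-independent.

Functional modules are k-clique-percolation communities computed exactly
from the definition: enumerate every k-clique, join cliques sharing k−1
nodes, and take node unions of the connected clique components.  Modules
may overlap in nodes.  Clique enumeration expands maximal cliques
(Bron–Kerbosch via networkx) into k-subsets, exact at desk scale (~10^4
k-cliques); beyond that it refuses rather than approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FunctionalModule",
    "build_coexpression",
    "k_clique_modules",
    "neighborhood",
    "compare_networks",
]

_MAX_K_CLIQUES = 200_000


@dataclass(frozen=True)
class FunctionalModule:
    members: frozenset[str]
    k: int

    def __len__(self) -> int:
        return len(self.members)


def build_coexpression(
    expr: pd.DataFrame,
    method: str = "pcc",
    top_n: int = 300,
    min_abs_pcc: float | None = None,
) -> nx.Graph:
    """Top-N co-expression network from a genes x samples matrix.

    Zero-variance genes are excluded with a warning.  Ties in the
    neighbour ranking are broken by lexicographic gene id, so the result
    is deterministic and invariant to input gene order.  ``min_abs_pcc``
    optionally drops neighbour candidates below an absolute-PCC floor.
    """
    if method not in ("pcc", "mr"):
        raise ValueError("method must be 'pcc' or 'mr'")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    expr = expr.sort_index()
    values = expr.to_numpy(float)
    var = values.var(axis=1)
    if (var == 0).any():
        warnings.warn(f"excluded {int((var == 0).sum())} zero-variance gene(s)")
        expr = expr.loc[var > 0]
        values = expr.to_numpy(float)
    genes = list(expr.index.astype(str))
    n = len(genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    if n < 2:
        return g
    pcc = np.corrcoef(values)
    np.fill_diagonal(pcc, -np.inf)  # exclude self from rankings

    # rank_a(b): 1-based position of b in a's PCC-descending list
    order = np.argsort(-pcc, axis=1, kind="stable")
    rank = np.empty_like(order)
    rows = np.arange(n)[:, None]
    rank[rows, order] = np.arange(1, n + 1)

    for i, gene in enumerate(genes):
        cand = [j for j in range(n) if j != i]
        if min_abs_pcc is not None:
            cand = [j for j in cand if abs(pcc[i, j]) >= min_abs_pcc]
        if method == "pcc":
            cand.sort(key=lambda j: (-pcc[i, j], genes[j]))
        else:
            cand.sort(key=lambda j: (np.sqrt(rank[i, j] * rank[j, i]), genes[j]))
        for j in cand[:top_n]:
            if method == "pcc":
                g.add_edge(gene, genes[j], weight=float(pcc[i, j]))
            else:
                g.add_edge(
                    gene, genes[j], weight=float(np.sqrt(rank[i, j] * rank[j, i]))
                )
    return g


def _k_cliques(graph: nx.Graph, k: int):
    seen: set[frozenset] = set()
    for maximal in nx.find_cliques(graph):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            fs = frozenset(sub)
            if fs not in seen:
                seen.add(fs)
                if len(seen) > _MAX_K_CLIQUES:
                    raise RuntimeError(
                        f"more than {_MAX_K_CLIQUES} {k}-cliques; graph too dense "
                        "for exact clique percolation"
                    )
    return sorted(seen, key=sorted)


def k_clique_modules(graph: nx.Graph, k: int = 4) -> list[FunctionalModule]:
    """Exact clique-percolation communities: unions of k-cliques chained
    through (k−1)-node overlaps.  Deterministic and order-independent."""
    if k < 3:
        raise ValueError("k must be >= 3")
    cliques = _k_cliques(graph, k)
    if not cliques:
        return []
    # index cliques by their (k-1)-subsets; cliques sharing one are adjacent
    overlap: dict[frozenset, list[int]] = {}
    for idx, c in enumerate(cliques):
        for sub in combinations(sorted(c), k - 1):
            overlap.setdefault(frozenset(sub), []).append(idx)
    clique_graph = nx.Graph()
    clique_graph.add_nodes_from(range(len(cliques)))
    for members in overlap.values():
        for a, b in zip(members, members[1:]):
            clique_graph.add_edge(a, b)
    modules = []
    for comp in nx.connected_components(clique_graph):
        nodes = frozenset().union(*(cliques[i] for i in comp))
        modules.append(FunctionalModule(nodes, k))
    modules.sort(key=lambda m: sorted(m.members))
    # postcondition audit: every member sits in at least one k-clique
    for m in modules:
        for node in m.members:
            assert any(node in cliques[i] for i in range(len(cliques)))
    return modules


def neighborhood(graph: nx.Graph, gene: str, depth: int = 1) -> nx.Graph:
    """Induced subgraph of all nodes within ``depth`` hops of ``gene``."""
    if gene not in graph:
        raise ValueError(f"gene {gene!r} not in network")
    return nx.ego_graph(graph, gene, radius=depth)


@dataclass
class NetworkComparison:
    """Cross-species overlay of two networks through ortholog pairs."""

    node_pairs: list[tuple[str, str]]
    n_a: int            # paired nodes present in network A
    n_b: int            # paired nodes present in network B
    overlay: nx.Graph   # edges tagged kind='coexpression' or kind='ortholog'


def compare_networks(
    net_a: nx.Graph, net_b: nx.Graph, pairs: list[tuple[str, str]]
) -> NetworkComparison:
    """Overlay two species' networks: co-expression edges plus ortholog links.

    ``pairs`` maps species-A ids to species-B ids; a pair is reported when
    both members are present in their respective networks.  In the overlay
    graph co-expression edges carry ``kind='coexpression'`` (drawn solid)
    and ortholog links ``kind='ortholog'`` (drawn dashed).
    """
    present = sorted(
        {(a, b) for a, b in pairs if a in net_a and b in net_b}
    )
    overlay = nx.Graph()
    for u, v in net_a.edges():
        overlay.add_edge(("A", u), ("A", v), kind="coexpression")
    for u, v in net_b.edges():
        overlay.add_edge(("B", u), ("B", v), kind="coexpression")
    for a, b in present:
        overlay.add_edge(("A", a), ("B", b), kind="ortholog")
    return NetworkComparison(
        node_pairs=present,
        n_a=len({a for a, _ in present}),
        n_b=len({b for _, b in present}),
        overlay=overlay,
    )
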