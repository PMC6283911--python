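"""Build a co-expression network and extract k-clique functional modules.

Uses a planted-module graph for the percolation step and an expression
matrix for the co-expression step, mirroring how module discovery runs on
real co-expression networks.
"""

from earminer import (
    build_coexpression,
    k_clique_modules,
    simulate_expression,
    simulate_network,
)

graph, truth = simulate_network(n_modules=3, module_size=6, k=4,
                                noise_edge_prob=0.01, seed=9)
modules = k_clique_modules(graph, k=4)
print(f"{len(modules)} functional module(s) at k=4:")
for i, mod in enumerate(modules):
    planted = sorted(set(truth.loc[list(mod.members), "module"]))
    print(f"  module {i}: {len(mod)} genes (planted module id(s): {planted})")

expr, _ = simulate_expression(n_genes=30, n_de=0, seed=10)
net = build_coexpression(expr, method="mr", top_n=3)
print(f"\nmutual-rank co-expression network: {net.number_of_nodes()} genes, "
      f"{net.number_of_edges()} edges (each gene keeps its top-3 neighbours; "
      "the edge set is the union, so degree can exceed 3).")
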