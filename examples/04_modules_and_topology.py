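"""Dense-module detection (MCODE) and the degree-preserving topology null.

MCODE grows modules from high-weight seeds (weight = k × density of the top
k-core of the closed neighborhood). The topology null rewires the network
with double-edge swaps that keep every degree fixed and asks whether the
real average path length is extreme among 1,000 such replicas.
"""
import networkx as nx

from cernet import apl_null_test, find_modules, fit_power_law

# planted structure: two dense cliques plus a sparse background
g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(6))
g = nx.disjoint_union(g, nx.gnp_random_graph(20, 0.08, seed=4))
g.add_edge(0, 14)   # bridge clique 1 ↔ clique 2
g.add_edge(7, 20)   # clique 1 ↔ background

mods = find_modules(g)
print("MCODE modules (score = density × size):")
for m in mods:
    print(f"  rank {m.rank}: size {m.size}, score {m.score:.2f}, seed {m.seed}")

slope, r2 = fit_power_law([d for _, d in g.degree()])
print(f"\ndegree distribution log-log fit: slope {slope:.2f}, R² = {r2:.2f}")

summary = apl_null_test(g, n_random=200, seed=0)
import numpy as np
print(f"average path length: real {summary.apl_real:.3f} "
      f"vs rewired-null mean {np.mean(summary.apl_null):.3f}")
print(f"empirical two-sided p = {summary.empirical_p:.4f} ({summary.direction})")
# A small p with direction 'larger' says the real network's paths are longer
# than degree alone explains — the signature of locally dense modules.
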