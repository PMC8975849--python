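# cliqueperc

k-clique percolation analysis of weighted free-association networks.

Free-association norms (a cue word, the responses people produce, and the
fraction of respondents giving each response) define weighted semantic
networks.  Unlike most graphs, words belong to many overlapping communities,
so the natural community notion is the *k-clique percolation cluster*: the
node union of a maximal set of k-cliques chained together through (k−1)-node
overlaps.  This package computes, for a network and each clique order k,

* `f_cc(k)` — the fraction of nodes in the largest k-clique community, and
  the critical clique order `k_c` (largest k with `f_cc(k)` above a cutoff);
* the analytic Erdős–Rényi threshold `p_c(k) = 1/[N(k−1)]^(1/(k−1))`
  against which observed densities are compared (`p_c(2) < ρ < p_c(3)` for
  all the standard semantic datasets: random graphs of the same density
  would support no 3-clique percolation at all);
* per-edge clique statistics — the edge clustering coefficient
  `C_ij = N_T(ij)/(min(k_i,k_j)−1)`, the edge k-clique number, and the
  log-linear relation between association strength and edge clustering
  (`log⟨w⟩ ≈ a·⟨c⟩ + b` over equal-size bins);
* perturbation experiments — weight thresholding keeping only strong
  (w ≥ τ) or only weak (w < θ) links, and random vs lowest-degree node
  removal, each followed by percolation profiling;
* a triangle-preferential-attachment growth model: each new word attaches
  to both endpoints of m existing edges drawn with probability ∝ k_i + k_j
  (closing a triangle per attachment), plus c random edges per step.  With
  m=4, c=4, l=20, p0=0.2 the grown networks are sparse, heavy-tailed
  (degree exponent γ ≈ 2.6) and highly clustered, and their clique
  organization — percolation up to k_c = 5–6, independent of size —
  matches what free-association data show.  It doubles as the synthetic
  data generator, so every analysis stage is testable without downloading
  any dataset.

Intended users: researchers in cognitive/semantic network analysis and
network science who want reproducible clique-percolation pipelines on
edge lists or cue–response tables.

## Worked example

```python
from cliqueperc import (GrowthParams, grow_network, network_summary,
                        percolation_profile, critical_k, pc_threshold)

g = grow_network(GrowthParams(n_target=2000, seed=1))
s = network_summary(g)
print(f"N={s.n_nodes}  E={s.n_edges}  density={s.density:.4f}  "
      f"transitivity={s.transitivity:.3f}  clustering={s.avg_clustering:.3f}")
print(f"p_c(2)={pc_threshold(s.n_nodes, 2):.2e}  p_c(3)={pc_threshold(s.n_nodes, 3):.4f}")
prof = percolation_profile(g, 8)
for k in prof.k_values:
    print(f"k={k}  f_cc={prof.entries[k]:.3f}")
print("k_c =", critical_k(prof))
```

prints

```
N=2000  E=23325  density=0.0117  transitivity=0.049  clustering=0.154
p_c(2)=5.00e-04  p_c(3)=0.0158
k=2  f_cc=1.000
k=3  f_cc=1.000
k=4  f_cc=0.733
k=5  f_cc=0.174
k=6  f_cc=0.044
k=7  f_cc=0.008
k=8  f_cc=0.000
k_c = 6
```

Read it as: the grown network's density (0.0117) lies between p_c(2) and
p_c(3), so a random graph of this size and density would have a giant
connected component but no 3-clique percolation — yet here *every* node sits
in the giant 3-clique community, 73% in the 4-clique community, and
percolation persists up to k_c = 6 before dying out.  That is the clique
organization observed in free-association networks.

The same stages run from the shell on any edge list
(`cliqueperc summarize|percolate|sweep-tau|sweep-theta|robustness|edgestats|degree-fit|simulate`),
or end-to-end from a YAML config with `cliqueperc run --config cfg.yaml`,
which writes per-stage TSV/JSON outputs plus a manifest with all seeds.

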