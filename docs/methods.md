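# Methods

## The quantity being computed

A *k-clique* is a complete subgraph on k nodes.  Two k-cliques are *adjacent*
when they share k−1 nodes; a *k-clique percolation cluster* (community) is
the node union of a maximal set of k-cliques linked by chains of adjacent
k-cliques.  For a fixed graph we compute, for every k from 2 up to a chosen
k_max, the fraction of nodes in the largest such community,

    f_cc(k) = |largest k-clique community| / N ,

and define the critical clique size k_c as the largest k whose largest
community still covers at least a fraction `min_fraction` of the nodes.
At k = 2 this reduces to the giant-component fraction.  For Erdős–Rényi
graphs G(N, p) the appearance of a giant k-clique community has the analytic
threshold

    p_c(k) = 1 / [N (k − 1)]^(1/(k−1)) ,

which is 1/N at k = 2.  Free-association networks have densities between
p_c(2) and p_c(3): were their links random, nothing beyond ordinary
connectivity could percolate, so any k-clique percolation at k ≥ 3 reflects
non-random structure.

### Choice of the `min_fraction` cutoff

No explicit cutoff defines "percolation exists" in empirical work on these
networks; we use 0.01 (the largest community must cover 1% of nodes) as the
default, exposed as a parameter.  On networks grown with the default model
parameters, f_cc(7) fluctuates around exactly this cutoff at N = 2000
(roughly 0.004–0.010 across seeds), so a single-seed k_c occasionally reads
7 rather than 5–6; seed-averaged profiles give k_c = 6 stably.  Tests that
assert k_c therefore average profiles over seeds.

## Algorithm

Maximal cliques are enumerated with Bron–Kerbosch with pivoting (networkx's
`find_cliques`); a configurable guard (default 10^7 cliques) aborts cleanly
on pathological dense inputs.  Communities are built by a union-find over
maximal cliques of size ≥ k, joining two cliques when they share ≥ k−1
nodes.  This is equivalent to connected components of the direct k-clique
adjacency relation: every k-clique lies in some maximal clique, any two
k-cliques inside one clique are chain-connected, and a (k−1)-node overlap
between maximal cliques supplies the bridging k-cliques.  The test suite
validates the equivalence on hundreds of small random graphs against a
brute-force implementation of the definition (explicit k-clique enumeration,
pairwise adjacency, BFS) and cross-checks against networkx's independent
implementation of the clique percolation method.  For k = 2 the overlap
condition degenerates to "share a node", and the union-find skips the
intersection computation.

Edge weights are ignored by all clique operations; weight effects enter only
through the perturbation protocols below.

## Edge-level statistics

The edge clustering coefficient C_ij = N_T(ij) / (min(k_i, k_j) − 1) divides
the triangle count of an edge by its maximum given the endpoint degrees.  We
define C_ij = 0 when min(k_i, k_j) = 1 (the formula would divide by zero and
no triangle is possible).  The *edge k-clique number* is the size of the
largest clique containing the edge, computed in one pass over the maximal
cliques.

The weight–clustering relation is estimated by sorting edges by C_ij (ties
broken by the lexicographic node-id pair, making the binning deterministic),
splitting them into b contiguous near-equal bins (default b = 100, remainder
spread over the first bins), averaging C and w arithmetically within bins,
and fitting a least-squares line of log⟨w⟩ on ⟨c⟩ with every bin weighted
equally.  The log base defaults to 10 and is configurable.  Because w is
averaged arithmetically *before* the log, mixed-C bins carry a small
convexity (Jensen) bias even for noiseless log-linear weights; the fit is
exact only in the singleton-bin limit, and the tests document both regimes.

## Perturbation protocols

Weight thresholding: the *weak* filter removes edges with w < τ (keeping
strong links, strict comparison); the *strong* filter removes edges with
w ≥ θ (keeping the weak-association subgraph, non-strict).  The two outputs
partition the edge set at equal cutoff.  Node removal deletes floor(αN)
nodes either uniformly at random or smallest-degree-first with random tie
breaks; surviving isolated nodes stay in the graph, so f_cc is always a
fraction of the perturbed node set.  Stochastic sweeps default to 10
replicates with sub-seeds spawned deterministically from a master seed via
`numpy.random.SeedSequence`.

## The growth model (synthetic-data generator)

Growth starts from an Erdős–Rényi seed graph G(l, p0) and adds one node per
step until N nodes exist.  The arriving node selects m distinct existing
edges, each drawn without replacement with probability proportional to the
sum of its endpoint degrees k_i + k_j (degrees frozen at the step start),
and links to both endpoints of every selected edge — each attachment closes
a triangle.  Then c extra edges are placed between uniformly chosen
non-adjacent old nodes (up to 100 redraws per edge; a saturated step is
skipped).  When two selected edges share an endpoint the duplicate link
collapses, so realized edge counts fall slightly below the (2m + c) per-step
bound.  The defaults m = 4, c = 4, l = 20, p0 = 0.2 are the study
conditions: at N = 2000 they give density ≈ 0.0116–0.0118 and mean local
clustering ≈ 0.145, and profiles with f_cc(3) ≈ 1 and k_c = 5–6 that are
essentially independent of N.  m is the controlling parameter for clique
percolation; c mainly dilutes density.

Alternatives the model description leaves open — drawing edges with
replacement, and updating degrees within a step (`sequential_degrees`) —
are config-exposed; we measured both and they shift N = 2000 clustering by
less than 0.003, so the simpler frozen/no-replacement variant is the
default.

Weights for synthetic networks follow the empirical weight–clustering
relation: w = 10^(slope·C_ij + intercept + ε), ε ~ N(0, noise_sd), clipped
to (10⁻⁶, 1], with defaults slope 5.0, intercept −4.4, noise_sd 0.2.  The
clip at 1 bends the relation for edges with C_ij ≳ 0.88 under the default
line; parameter-recovery tests either tolerate this (±0.3) or use lines that
stay inside (0, 1].

What the generator does *not* emulate: real association networks are built
from human cue–response norms with heavy measurement discretization (w is a
fraction of a finite respondent pool), lexical structure, and a directed
asymmetry that the symmetrization discards.  Passing tests on grown networks
show the machinery and the model's clique organization, not properties of
any specific empirical dataset.

## Degree-distribution fitting

`fit_degree_exponent` offers two estimators for p(d) ∝ d^(−γ) over degrees
≥ x_min: a discrete maximum-likelihood estimator (Hurwitz-zeta normalized
likelihood, maximized by bounded scalar search on γ ∈ (1.01, 10)) and a
tail regression of log CCDF on log degree with γ = |slope| + 1.  Both
require at least 10 distinct degrees in the tail.  On grown networks the
degree distribution has visible curvature: the MLE is strongly x_min-
sensitive (≈2.1 at x_min = 8 up to ≈3.2 at x_min = 30 for N = 8000), while
the CCDF tail regression is stable near 2.6 across that range.  Since the
exponent of interest is read off a CCDF, tail regression at x_min = 2m is
the default for reproducing it; automatic x_min selection (e.g. by KS
minimization) is deliberately out of scope.

## Numerical and reproducibility choices

* All randomness is numpy `default_rng`; growth is reproducible edge-for-edge
  from (params, seed).
* Pipeline stages derive sub-seeds by CRC-hashing the stage name with the
  master seed, so results are invariant to stage reordering.
* Problem sizes in the test suite: grown networks at N = 2000–8000 (a few
  seeds each), ER oracles at N ≤ 500, brute-force equivalence on graphs of
  ≤ 12 nodes — sizes at which every check closes in minutes on one core.
* Published node/edge counts for the nine semantic datasets ship in
  `reference_data` so threshold arithmetic is testable offline; the one row
  whose printed density matches a directed normalization is flagged there
  and excluded from the undirected-density identity.

## Known limitations

* Community construction materializes all maximal cliques; graphs far denser
  than the semantic regime (ρ ≫ p_c(3)) can exceed the clique guard.
* The weak/strong threshold semantics (strict vs non-strict) follow the
  experimental protocol wording; datasets with many ties exactly at a cutoff
  will be sensitive to that convention.
* αN is rounded down in node removal; at small N this can make a nominal α
  grid collapse onto fewer distinct removal counts.
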