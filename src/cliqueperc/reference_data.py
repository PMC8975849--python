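"""Published structural properties of public semantic-network datasets.

Node and edge counts, densities and random-graph percolation thresholds as
reported for widely used free-association and lexical networks (SWOW-EN, the
South Florida norms, the Edinburgh Associative Thesaurus, WordNet-derived
layers, Russian and Dutch association data), plus the same quantities for
networks grown with the triangle-preferential-attachment model at its default
parameters.  These serve as fixed inputs for threshold cross-checks; none of
the underlying datasets is needed.

Values are quoted to their published precision; ``pc2``/``pc3`` are the
analytic Erdos-Renyi thresholds p_c(2), p_c(3) evaluated at the dataset size.
The RUS-thesaurus density is published as 0.002, which matches an
ordered-pair (directed) normalization E/N^2 rather than E/(N(N-1)/2) — the
only row where the two disagree; see ``density_consistent``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["NetworkRecord", "SEMANTIC_NETWORKS", "SIMULATED_NETWORKS"]


@dataclass(frozen=True)
class NetworkRecord:
    name: str
    n_nodes: int
    n_edges: int
    density: float
    transitivity: float
    clustering: float
    pc2: float
    pc3: float
    #: True where the published density equals E/(N(N-1)/2) at printed precision
    density_consistent: bool = True


SEMANTIC_NETWORKS: tuple[NetworkRecord, ...] = (
    NetworkRecord("SWOW-EN free association", 12217, 352403, 0.0047, 0.052, 0.113,
                  8.2e-5, 0.0064),
    NetworkRecord("Florida free association", 5019, 55246, 0.0044, 0.083, 0.186,
                  2.0e-4, 0.0100),
    NetworkRecord("Edinburgh free association", 8210, 241461, 0.0072, 0.048, 0.103,
                  1.2e-4, 0.0078),
    NetworkRecord("Taxonomic", 7943, 42042, 0.0013, 0.048, 0.093, 1.3e-4, 0.0079),
    NetworkRecord("Synonyms", 6526, 13134, 0.0006, 0.284, 0.344, 1.5e-4, 0.0088),
    NetworkRecord("Phonological", 4618, 15447, 0.0014, 0.345, 0.246, 2.2e-4, 0.0104),
    NetworkRecord("Multiplex", 8383, 68505, 0.0019, 0.112, 0.283, 1.2e-4, 0.0078),
    NetworkRecord("RUS thesaurus", 5377, 51191, 0.002, 0.067, 0.163, 1.9e-4, 0.0096,
                  density_consistent=False),
    NetworkRecord("Dutch data", 10486, 207810, 0.0038, 0.067, 0.163, 9.5e-5, 0.0069),
)

#: Grown networks (m=4, c=4, l=20, p0=0.2) at increasing target sizes.
SIMULATED_NETWORKS: tuple[NetworkRecord, ...] = (
    NetworkRecord("simulated N=2000", 2000, 23213, 0.0116, 0.048, 0.175,
                  5e-4, 0.0158),
    NetworkRecord("simulated N=4000", 4000, 46783, 0.0058, 0.028, 0.158,
                  2.5e-4, 0.0111),
    NetworkRecord("simulated N=6000", 6000, 69307, 0.0039, 0.016, 0.172,
                  1.66e-4, 0.0091),
    NetworkRecord("simulated N=8000", 8000, 91275, 0.0028, 0.010, 0.187,
                  1.25e-4, 0.0079),
)
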