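"""SNP-based diseasome networks and network-coherence z-scores.

The diseasome is the projection, on disease nodes, of the bipartite network
relating diseases to their associated SNPs: an edge joins two diseases when
they share at least ``edge_threshold`` SNPs of the prescribed class (border
SNPs by the majority rule, or the complementary non-border SNPs, optionally
restricted to intergenic SNPs).

Network coherence of a node subset is the z-score of its induced edge count
against random same-size node subsets drawn from the same network: positive
when the subset is more internally connected than random groups, near zero
for a random subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import DiseaseCatalog

__all__ = [
    "CoherenceResult",
    "build_diseasome",
    "induced_edge_count",
    "network_coherence",
    "coherence_report",
]

EXACT_ENUMERATION_BUDGET = 100_000


@dataclass
class CoherenceResult:
    """z-score of a subset's induced edge count vs random subsets."""

    label: str
    size: int
    m_obs: int
    mu: float
    sigma: float
    z: float  # NaN when undefined (sigma == 0)
    n_draws: int
    exact: bool
    seed: int | None = None

    @property
    def defined(self) -> bool:
        return self.sigma > 0


def build_diseasome(
    catalog: DiseaseCatalog,
    border_snp_set: set[str],
    snp_class: str = "border",
    intergenic_only: bool = False,
    edge_threshold: int = 1,
) -> nx.Graph:
    """Project the disease--SNP bipartite relation onto disease nodes.

    ``border_snp_set`` is the majority-rule border SNP set;
    ``snp_class='border'`` keeps those SNPs, ``'non_border'`` the
    complement.  Diseases whose filtered SNP set is empty are dropped.
    Node attributes: ``is_cancer``; edge attribute ``shared`` counts the
    shared SNPs.
    """
    if snp_class not in ("border", "non_border"):
        raise ValueError(f"unknown snp_class {snp_class!r}")
    snps = catalog.snps
    keep = set(snps["snpId"])
    if intergenic_only:
        keep &= set(snps.loc[snps["category"] == "intergenic", "snpId"])
    if snp_class == "border":
        keep &= border_snp_set
    else:
        keep -= border_snp_set
    is_cancer = catalog.diseases.set_index("efoId")["isCancer"]
    sets = {
        efo: catalog.snp_ids(efo) & keep for efo in catalog.diseases["efoId"]
    }
    sets = {efo: s for efo, s in sets.items() if s}
    g = nx.Graph()
    for efo, s in sets.items():
        g.add_node(efo, is_cancer=bool(is_cancer.loc[efo]), n_snps=len(s))
    for d1, d2 in itertools.combinations(sets, 2):
        shared = len(sets[d1] & sets[d2])
        if shared >= edge_threshold:
            g.add_edge(d1, d2, shared=shared)
    return g


def induced_edge_count(network: nx.Graph, subset) -> int:
    """Number of edges with both endpoints in ``subset``."""
    subset = set(subset)
    unknown = subset - set(network.nodes)
    if unknown:
        raise ValueError(f"unknown node ids: {sorted(unknown)[:5]}")
    return network.subgraph(subset).number_of_edges()


def network_coherence(
    network: nx.Graph,
    subset,
    n_draws: int = 1000,
    seed: int | None = None,
    label: str = "",
    exact: str | bool = "auto",
) -> CoherenceResult:
    """Coherence z-score of ``subset`` within ``network``.

    The null is the induced edge count of uniform random node subsets of the
    same size drawn (without replacement within a draw) from the network's
    nodes.  When the number of possible subsets is within the enumeration
    budget (<= 1e5) the null mean and population standard deviation are
    computed exactly over all subsets; otherwise ``n_draws`` independent
    samples are used.  ``sigma == 0`` (e.g., an edgeless network or the full
    node set) leaves z undefined (NaN), flagged via ``defined``.
    """
    subset = list(dict.fromkeys(subset))
    nodes = list(network.nodes)
    s = len(subset)
    if not 1 <= s <= len(nodes):
        raise ValueError(f"subset size {s} outside [1, {len(nodes)}]")
    m_obs = induced_edge_count(network, subset)
    n_comb = math.comb(len(nodes), s)
    use_exact = (exact is True) or (exact == "auto" and n_comb <= EXACT_ENUMERATION_BUDGET)
    if use_exact:
        counts = np.fromiter(
            (network.subgraph(c).number_of_edges()
             for c in itertools.combinations(nodes, s)),
            dtype=float,
            count=n_comb,
        )
        draws_used = n_comb
    else:
        rng = np.random.default_rng(seed)
        idx = np.arange(len(nodes))
        counts = np.empty(n_draws)
        for i in range(n_draws):
            pick = rng.choice(idx, size=s, replace=False)
            counts[i] = network.subgraph([nodes[j] for j in pick]).number_of_edges()
        draws_used = n_draws
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=0))
    z = (m_obs - mu) / sigma if sigma > 0 else float("nan")
    return CoherenceResult(
        label=label, size=s, m_obs=m_obs, mu=mu, sigma=sigma, z=z,
        n_draws=draws_used, exact=use_exact, seed=seed,
    )


def coherence_report(
    catalog: DiseaseCatalog,
    border_snp_set: set[str],
    enriched_flags: pd.Series,
    n_draws: int = 1000,
    seed: int = 0,
    edge_threshold: int = 1,
) -> pd.DataFrame:
    """Coherence of every standard node grouping in every network variant.

    Variants: {border, non_border} x {all SNPs, intergenic only}.  Node
    types: cancer / non-cancer crossed with enriched / not-enriched / all
    (enrichment = majority-rule TAD-border enrichment flags).  Empty node
    types are skipped.
    """
    rows = []
    for snp_class in ("border", "non_border"):
        for intergenic_only in (False, True):
            net = build_diseasome(
                catalog, border_snp_set, snp_class, intergenic_only, edge_threshold
            )
            variant = f"{snp_class}{'_intergenic' if intergenic_only else ''}"
            cancer = {n for n, d in net.nodes(data=True) if d["is_cancer"]}
            groups = {}
            for cls_name, cls_nodes in (("cancer", cancer),
                                        ("non_cancer", set(net.nodes) - cancer)):
                enr = {n for n in cls_nodes if enriched_flags.get(n, False)}
                groups[f"{cls_name}_enriched"] = enr
                groups[f"{cls_name}_not_enriched"] = cls_nodes - enr
                groups[f"{cls_name}_all"] = cls_nodes
            for gname, members in groups.items():
                if not members or len(members) > len(net):
                    continue
                res = network_coherence(
                    net, members, n_draws=n_draws, seed=seed,
                    label=f"{variant}/{gname}",
                )
                rows.append(
                    {
                        "network": variant,
                        "node_type": gname,
                        "size": res.size,
                        "m_obs": res.m_obs,
                        "mu": res.mu,
                        "sigma": res.sigma,
                        "z": res.z,
                        "defined": res.defined,
                        "exact": res.exact,
                    }
                )
    return pd.DataFrame(rows)
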