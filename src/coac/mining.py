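"""Closed association-rule mining and subnetwork construction.

A ternary components x genes matrix, collapsed to presence (0/1), is a
transaction database: each component is a transaction, each gene an item.
An association rule pairs a gene collection with the full set of
components in which *every* one of those genes is marked — the Cartesian
product of the two collections is all-ones in the presence matrix.  Only
closed rules are kept: the gene collection cannot be extended without
shrinking its component collection, and it carries its maximal component
collection.  Closed sets are enumerated LCM-style (prefix-preserving
closure extension); a brute-force subset oracle in the test suite defines
correctness.

Each rule then becomes a co-expression subnetwork: edges join rule genes
whose expression profiles correlate strongly, and the largest connected
component is the subnetwork.  Two metrics summarize it — the average
pairwise correlation of the genes' cell-space reconstructions restricted
to the rule's components (homogeneity given those components) and the
average component ratio (how much of each gene's squared component-space
norm the rule's components capture).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import networkx as nx
import numpy as np

from .decomposition import Decomposition, TernaryMatrix
from .matrix import ExpressionMatrix

__all__ = [
    "AssociationRule",
    "Subnetwork",
    "enumerate_closed_rules",
    "build_subnetwork",
    "average_correlation",
    "component_ratio",
    "average_component_ratio",
    "filter_subnetworks",
]


@dataclass(frozen=True)
class AssociationRule:
    """A closed (gene collection, component collection) pair.

    ``sign_profile`` maps (component, gene) to the ternary sign (+1/-1)
    that supports the pair; mining itself runs on presence (signs
    collapsed).
    """

    genes: tuple[str, ...]
    components: tuple[int, ...]
    sign_profile: dict[tuple[int, str], int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "components", tuple(sorted(self.components)))

    def __hash__(self) -> int:
        return hash((self.genes, self.components))

    def __eq__(self, other) -> bool:
        return (self.genes, self.components) == (other.genes, other.components)


@dataclass
class Subnetwork:
    """Largest connected component of a rule's co-expression graph."""

    rule: AssociationRule
    giant_genes: tuple[str, ...]
    edges: list[tuple[str, str, float]]
    correlations: np.ndarray  # restricted-profile corr among giant genes
    avg_correlation: float
    avg_component_ratio: float


def enumerate_closed_rules(
    t: TernaryMatrix, min_genes: int = 2, min_components: int = 1
) -> list[AssociationRule]:
    """All closed association rules of the presence matrix.

    Output is deterministic: sorted by gene-collection size (descending)
    then lexicographic gene ids.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    if min_components < 1:
        raise ValueError("min_components must be >= 1")
    presence = t.presence.tocsc()
    n_comp, n_genes = presence.shape
    # per-gene support as bitmask over components
    supports = []
    for g in range(n_genes):
        col = presence.indices[presence.indptr[g] : presence.indptr[g + 1]]
        mask = 0
        for c in col:
            mask |= 1 << int(c)
        supports.append(mask)
    all_comps = (1 << n_comp) - 1

    def closure_of(support: int) -> int:
        gene_mask = 0
        for g in range(n_genes):
            if support and (supports[g] & support) == support:
                gene_mask |= 1 << g
        return gene_mask

    results: list[tuple[int, int]] = []

    def dfs(gene_mask: int, support: int, core: int) -> None:
        if bin(gene_mask).count("1") >= min_genes:
            results.append((gene_mask, support))
        for g in range(core + 1, n_genes):
            if gene_mask >> g & 1:
                continue
            new_support = support & supports[g]
            if bin(new_support).count("1") < min_components:
                continue
            new_closure = closure_of(new_support)
            # prefix-preserving check: closure may only add genes >= g
            if new_closure & ((1 << g) - 1) & ~gene_mask:
                continue
            dfs(new_closure, new_support, g)

    root_support = all_comps
    root_closure = closure_of(root_support) if n_comp else 0
    if n_comp and bin(root_support).count("1") >= min_components:
        dfs(root_closure, root_support, -1)
    else:
        # fewer components than min_components: nothing to mine
        results.clear()

    sign = t.M.tocsc()
    rules = []
    for gene_mask, support in results:
        gidx = [g for g in range(n_genes) if gene_mask >> g & 1]
        comps = tuple(c for c in range(n_comp) if support >> c & 1)
        genes = tuple(sorted(t.gene_ids[g] for g in gidx))
        profile = {
            (c, t.gene_ids[g]): int(sign[c, g]) for c in comps for g in gidx
        }
        rules.append(AssociationRule(genes=genes, components=comps, sign_profile=profile))
    rules.sort(key=lambda r: (-len(r.genes), r.genes))
    return rules


def _restricted_reconstruction(
    rule: AssociationRule, d: Decomposition, m: ExpressionMatrix
) -> np.ndarray:
    """Cell-space profiles of the rule's genes using only the rule's
    components: A_hat[:, i] = sum_{j in comps} sigma_j V(i,j) U(:,j)."""
    gidx = m.gene_index(list(rule.genes))
    comps = np.array(rule.components, dtype=int)
    w = d.weights()[np.ix_(gidx, comps)]  # genes x |comps|
    return d.U[:, comps] @ w.T  # cells x genes


def _safe_corrcoef(profiles: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations; constant columns correlate 0."""
    sd = profiles.std(axis=0)
    ok = sd > 0
    corr = np.zeros((profiles.shape[1], profiles.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(profiles[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


def build_subnetwork(
    rule: AssociationRule,
    d: Decomposition,
    m: ExpressionMatrix,
    edge_threshold: float = 0.5,
    edge_source: str = "profile",
) -> Subnetwork:
    """Co-expression graph of a rule, reduced to its largest component.

    Edges join gene pairs with |Pearson correlation| >= ``edge_threshold``.
    With ``edge_source="profile"`` (default) the correlations come from
    the genes' full expression profiles — the co-expression network of the
    data itself; ``"restricted"`` uses the component-restricted
    reconstructions instead (note that for a single-component rule those
    are all collinear, making the graph complete).  The largest connected
    component wins, ties broken by the smallest lexicographic gene id it
    contains.  The Eq-style average-correlation metric is always computed
    on the component-restricted reconstructions of the giant genes.
    """
    if not 0 <= edge_threshold < 1:
        raise ValueError("edge_threshold must be in [0, 1)")
    if edge_source not in ("profile", "restricted"):
        raise ValueError("edge_source must be 'profile' or 'restricted'")
    if not rule.genes:
        raise ValueError("empty rule")
    restricted = _restricted_reconstruction(rule, d, m)
    restricted_corr = _safe_corrcoef(restricted)
    if edge_source == "profile":
        corr = _safe_corrcoef(m.dense()[:, m.gene_index(list(rule.genes))])
    else:
        corr = restricted_corr
    genes = list(rule.genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= edge_threshold:
                g.add_edge(genes[i], genes[j], weight=float(corr[i, j]))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    giant = tuple(components[0])
    gi = [genes.index(x) for x in giant]
    sub_corr = restricted_corr[np.ix_(gi, gi)]
    edges = [
        (u, v, float(data["weight"]))
        for u, v, data in g.edges(data=True)
        if u in giant and v in giant
    ]
    edges.sort(key=lambda e: (e[0], e[1]))
    s = Subnetwork(
        rule=rule,
        giant_genes=giant,
        edges=edges,
        correlations=sub_corr,
        avg_correlation=np.nan,
        avg_component_ratio=np.nan,
    )
    s.avg_correlation = average_correlation(s) if len(giant) >= 2 else 1.0
    s.avg_component_ratio = average_component_ratio(rule, d, m)
    return s


def average_correlation(s: Subnetwork) -> float:
    """Mean pairwise correlation over ordered gene pairs of the giant
    component (restricted to the rule's components)."""
    n = len(s.giant_genes)
    if n < 2:
        raise ValueError("average correlation needs at least 2 genes")
    c = s.correlations
    return float((c.sum() - np.trace(c)) / (n * (n - 1)))


def component_ratio(
    gene: str, rule: AssociationRule, d: Decomposition, m: ExpressionMatrix
) -> float:
    """Fraction of a gene's squared component-space norm carried by the
    rule's components: sum_{j in comps} w_ij^2 / sum_{j<=k} w_ij^2."""
    gi = int(m.gene_index([gene])[0])
    w = d.weights()[gi]
    total = float(np.sum(w**2))
    if total == 0:
        raise ValueError(f"gene {gene!r} has zero component-space norm")
    sel = float(np.sum(w[list(rule.components)] ** 2))
    return sel / total


def average_component_ratio(
    rule: AssociationRule, d: Decomposition, m: ExpressionMatrix
) -> float:
    """Mean of :func:`component_ratio` over the rule's gene collection."""
    return float(
        np.mean([component_ratio(g, rule, d, m) for g in rule.genes])
    )


def filter_subnetworks(
    subs: list[Subnetwork],
    min_avg_corr: float = 0.5,
    min_avg_comp_ratio: float = 0.5,
    top_fraction: float | None = None,
) -> list[Subnetwork]:
    """Keep subnetworks passing both metric thresholds; optionally keep
    only the top fraction by average correlation.

    Output order is deterministic: descending average correlation, ties by
    larger rule then lexicographic gene ids.
    """
    if top_fraction is not None and not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    kept = [
        s
        for s in subs
        if s.avg_correlation >= min_avg_corr
        and s.avg_component_ratio >= min_avg_comp_ratio
    ]
    kept.sort(key=lambda s: (-s.avg_correlation, -len(s.rule.genes), s.rule.genes))
    if top_fraction is not None and kept:
        n_keep = max(1, int(floor(len(subs) * top_fraction + 0.5)))
        kept = kept[:n_keep]
    return kept
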