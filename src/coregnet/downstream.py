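"""Host-gene/CRM sharing analysis and 1-r hierarchical clustering.

Some miRNAs sit in the intron of a protein-coding host gene; a CRM that
both regulates such a miRNA (CRM->miRNA edge) and targets its host gene
drives an intrinsic feed-forward loop.  The clustering view groups a
module's genes by the distance d = 1 - r, r being the max-over-probesets
Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coherence import CoherenceEngine
from .containers import ExpressionMatrix, TargetMap


@dataclass
class HostGeneRecord:
    mirna_id: str
    host_gene_id: str
    shared_crms: set[str]


def shared_crm_hostgenes(
    host_map: Mapping[str, str],
    c2m_edges: Sequence[tuple[str, str]],
    crm_targets: TargetMap,
) -> list[HostGeneRecord]:
    """Per hosted miRNA, the CRMs that regulate it and also target its host."""
    crms_of_mirna: dict[str, set[str]] = {}
    for crm_id, mirna_id in c2m_edges:
        crms_of_mirna.setdefault(mirna_id, set()).add(crm_id)
    records: list[HostGeneRecord] = []
    for mirna_id in sorted(host_map):
        host = host_map[mirna_id]
        shared = {
            crm_id
            for crm_id in crms_of_mirna.get(mirna_id, set())
            if host in crm_targets.entries.get(crm_id, set())
        }
        records.append(HostGeneRecord(mirna_id, host, shared))
    return records


def count_shared(records: Sequence[HostGeneRecord]) -> int:
    """Number of hosted miRNAs sharing at least one CRM with their host."""
    return sum(1 for r in records if r.shared_crms)


@dataclass
class Dendrogram:
    labels: list[str]  # leaf labels in input order (linkage indexes into this)
    linkage: np.ndarray  # scipy linkage matrix

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        body = render(tree, tree.dist)
        # strip the root's branch length
        return body.rsplit(":", 1)[0] + ";"

    def cluster_leafsets(self) -> list[frozenset[str]]:
        """Leaf set of every internal merge, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out: list[frozenset[str]] = []
        for k, (a, b, _h, _c) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out


def distance_matrix(
    engine: CoherenceEngine, genes: Sequence[str]
) -> np.ndarray:
    """Pairwise 1 - r distances; undefined correlations become the maximal
    distance 2 (with a warning)."""
    corr = engine.correlation_matrix(list(genes))
    dist = 1.0 - corr
    undefined = np.isnan(dist)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum()) // 2} undefined gene-pair correlations "
            "assigned the maximal distance 2"
        )
        dist[undefined] = 2.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_genes(
    expr: ExpressionMatrix | CoherenceEngine,
    genes: Sequence[str],
    method: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of genes with distance 1 - correlation."""
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    usable = engine.usable_genes(genes)
    if len(usable) < 2:
        raise ValueError("need >= 2 genes with expression to cluster")
    dist = distance_matrix(engine, usable)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return Dendrogram(labels=usable, linkage=linkage)


def forms_exact_subtree(dendrogram: Dendrogram, genes: Sequence[str]) -> bool:
    """True iff the gene set appears as the exact leaf set of one cluster
    (i.e. the genes merge together before any outsider joins)."""
    target = frozenset(genes)
    if len(target) == 1:
        return target <= set(dendrogram.labels)
    return target in set(dendrogram.cluster_leafsets())
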