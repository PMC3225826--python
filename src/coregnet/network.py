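"""Tripartite regulatory network assembly, regulation-pattern census and
significance against degree-preserving edge-swap null networks.

The pattern catalog is the exhaustive, isomorphism-deduplicated set of
weakly connected typed digraphs on at most three nodes over the four
allowed edge types (CRM->gene, miRNA->gene, CRM->miRNA, miRNA->CRM).  It
contains, among others, both feed-forward-loop variants, the CRM/miRNA
co-regulation fork, the two regulator chains and the CRM<->miRNA mutual
pair.  Counting is subgraph-occurrence counting (a triangle contains its
sub-fork), with distinct node assignments divided by pattern automorphisms.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Mapping, Sequence

import numpy as np

from .containers import (
    CRMDefinition,
    EDGE_TYPES,
    NODE_TYPES,
    RegulatoryNetwork,
    TargetMap,
)

#: (source type, target type) -> edge type
ALLOWED_PAIR: dict[tuple[str, str], str] = {
    ("CRM", "GENE"): "C2G",
    ("MIRNA", "GENE"): "M2G",
    ("CRM", "MIRNA"): "C2M",
    ("MIRNA", "CRM"): "M2C",
}


# ---------------------------------------------------------------------------
# Edge derivation and assembly


def derive_mirna_crm_edges(
    mirna_targets: TargetMap,
    crms: Sequence[CRMDefinition],
    pwm_gene_map: Mapping[str, set[str]],
) -> list[tuple[str, str]]:
    """miRNA -> CRM edges: the miRNA targets the gene of at least one TF
    whose motif belongs to the CRM.  Motifs missing from the PWM->gene map
    are skipped with a warning."""
    missing = sorted(
        {m for crm in crms for m in crm.motif_ids if m not in pwm_gene_map}
    )
    if missing:
        warnings.warn(f"motifs without TF-gene mapping skipped: {missing}")
    crm_tf_genes = {
        crm.crm_id: set().union(
            *(pwm_gene_map.get(m, set()) for m in crm.motif_ids)
        )
        for crm in crms
    }
    edges: list[tuple[str, str]] = []
    for mirna_id in sorted(mirna_targets.entries):
        targets = mirna_targets.entries[mirna_id]
        for crm_id in sorted(crm_tf_genes):
            if crm_tf_genes[crm_id] & targets:
                edges.append((mirna_id, crm_id))
    return edges


def build_network(
    crm_targets: TargetMap,
    mirna_targets: TargetMap,
    c2m_edges: Sequence[tuple[str, str]],
    m2c_edges: Sequence[tuple[str, str]],
) -> RegulatoryNetwork:
    """Union of the four typed edge sets, nodes inferred, duplicates collapsed."""
    edges: list[tuple[str, str, str]] = []
    for crm_id, genes in crm_targets.entries.items():
        edges.extend((crm_id, g, "C2G") for g in genes)
    for mirna_id, genes in mirna_targets.entries.items():
        edges.extend((mirna_id, g, "M2G") for g in genes)
    edges.extend((c, m, "C2M") for c, m in c2m_edges)
    edges.extend((m, c, "M2C") for m, c in m2c_edges)
    return RegulatoryNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# Pattern catalog


@dataclass(frozen=True)
class PatternCatalogEntry:
    pattern_id: str
    node_types: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]  # placeholder-node index pairs
    automorphisms: int
    name: str | None = None

    @property
    def edge_types(self) -> tuple[str, ...]:
        return tuple(
            ALLOWED_PAIR[(self.node_types[i], self.node_types[j])]
            for i, j in self.edges
        )

    def describe(self) -> str:
        parts = [
            f"{self.node_types[i]}{i}->{self.node_types[j]}{j}"
            for i, j in self.edges
        ]
        return ";".join(parts)


_NAMED_SHAPES = {
    "ffl_crm_master": (("CRM", "MIRNA", "GENE"), ((0, 1), (0, 2), (1, 2))),
    "ffl_mirna_master": (("CRM", "MIRNA", "GENE"), ((1, 0), (0, 2), (1, 2))),
    "coregulation_fork": (("CRM", "MIRNA", "GENE"), ((0, 2), (1, 2))),
    "chain_crm_mirna_gene": (("CRM", "MIRNA", "GENE"), ((0, 1), (1, 2))),
    "chain_mirna_crm_gene": (("CRM", "MIRNA", "GENE"), ((1, 0), (0, 2))),
    "mutual_crm_mirna": (("CRM", "MIRNA"), ((0, 1), (1, 0))),
}


def _canonical(
    types: tuple[str, ...], edges: frozenset[tuple[int, int]]
) -> tuple[tuple[str, ...], tuple[tuple[int, int], ...]]:
    """Minimum over node relabelings of (type tuple, sorted edge tuple)."""
    n = len(types)
    best = None
    for perm in permutations(range(n)):
        new_types = tuple(types[perm.index(i)] for i in range(n))
        new_edges = tuple(sorted((perm[i], perm[j]) for i, j in edges))
        key = (new_types, new_edges)
        if best is None or key < best:
            best = key
    return best


def _is_weakly_connected(n: int, edges: frozenset[tuple[int, int]]) -> bool:
    touched = {i for e in edges for i in e}
    if touched != set(range(n)):
        return False
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1


def _automorphism_count(
    types: tuple[str, ...], edges: tuple[tuple[int, int], ...]
) -> int:
    edge_set = set(edges)
    count = 0
    for perm in permutations(range(len(types))):
        if any(types[perm[i]] != types[i] for i in range(len(types))):
            continue
        if {(perm[i], perm[j]) for i, j in edges} == edge_set:
            count += 1
    return count


def generate_pattern_catalog() -> list[PatternCatalogEntry]:
    """Exhaustive catalog of connected typed patterns on 2-3 nodes."""
    seen: dict[tuple, tuple[tuple[str, ...], tuple[tuple[int, int], ...]]] = {}
    for n in (2, 3):
        for types in product(NODE_TYPES, repeat=n):
            allowed = [
                (i, j)
                for i in range(n)
                for j in range(n)
                if i != j and (types[i], types[j]) in ALLOWED_PAIR
            ]
            for r in range(1, len(allowed) + 1):
                for sub in combinations(allowed, r):
                    edge_set = frozenset(sub)
                    if not _is_weakly_connected(n, edge_set):
                        continue
                    key = _canonical(types, edge_set)
                    seen.setdefault(key, key)

    named = {
        _canonical(types, frozenset(edges)): name
        for name, (types, edges) in _NAMED_SHAPES.items()
    }
    ordered = sorted(seen, key=lambda k: (len(k[0]), len(k[1]), k))
    catalog = []
    for idx, key in enumerate(ordered, start=1):
        types, edges = key
        catalog.append(
            PatternCatalogEntry(
                pattern_id=f"P{idx:02d}",
                node_types=types,
                edges=edges,
                automorphisms=_automorphism_count(types, edges),
                name=named.get(key),
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# Census


class _TypedIndex:
    """Typed adjacency index of a network for fast pattern matching."""

    def __init__(self, network: RegulatoryNetwork):
        self.nodes_by_type: dict[str, list[str]] = {
            t: network.nodes_of_type(t) for t in NODE_TYPES
        }
        self.succ: dict[str, dict[str, set[str]]] = {
            e: defaultdict(set) for e in EDGE_TYPES
        }
        self.pred: dict[str, dict[str, set[str]]] = {
            e: defaultdict(set) for e in EDGE_TYPES
        }
        for src, tgt, etype in network.edges:
            self.succ[etype][src].add(tgt)
            self.pred[etype][tgt].add(src)

    def has_edge(self, src: str, tgt: str, etype: str) -> bool:
        return tgt in self.succ[etype].get(src, ())


def _match_order(entry: PatternCatalogEntry) -> list[int]:
    """Template-node visit order so each node after the first touches an
    already-visited one (patterns are weakly connected, so this exists)."""
    n = len(entry.node_types)
    order = [entry.edges[0][0]]
    while len(order) < n:
        for i in range(n):
            if i in order:
                continue
            if any(
                (i in e and (e[0] in order or e[1] in order)) for e in entry.edges
            ):
                order.append(i)
                break
    return order


def _count_entry(index: _TypedIndex, entry: PatternCatalogEntry) -> int:
    types = entry.node_types
    edges = [
        (i, j, ALLOWED_PAIR[(types[i], types[j])]) for i, j in entry.edges
    ]
    order = _match_order(entry)
    assignment: dict[int, str] = {}
    total = 0

    def candidates(t_node: int) -> set[str]:
        cands: set[str] | None = None
        for i, j, etype in edges:
            if i == t_node and j in assignment:
                pool = index.pred[etype].get(assignment[j], set())
            elif j == t_node and i in assignment:
                pool = index.succ[etype].get(assignment[i], set())
            else:
                continue
            cands = pool.copy() if cands is None else cands & pool
        if cands is None:
            cands = set(index.nodes_by_type[types[t_node]])
        return cands

    def extend(pos: int) -> None:
        nonlocal total
        if pos == len(order):
            total += 1
            return
        t_node = order[pos]
        for node in candidates(t_node):
            if node in assignment.values():
                continue
            assignment[t_node] = node
            ok = all(
                index.has_edge(assignment[i], assignment[j], etype)
                for i, j, etype in edges
                if i in assignment and j in assignment
            )
            if ok:
                extend(pos + 1)
            del assignment[t_node]

    extend(0)
    assert total % entry.automorphisms == 0
    return total // entry.automorphisms


def count_patterns(
    network: RegulatoryNetwork, catalog: Sequence[PatternCatalogEntry]
) -> dict[str, int]:
    """Subgraph-occurrence count of every catalog pattern in the network."""
    index = _TypedIndex(network)
    return {entry.pattern_id: _count_entry(index, entry) for entry in catalog}


# ---------------------------------------------------------------------------
# Edge-swap null model and Z-scores


def random_network(
    network: RegulatoryNetwork,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> RegulatoryNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Swaps act within each edge type independently ((a->b, c->d) becomes
    (a->d, c->b)), rejecting moves that would duplicate an edge; per-type
    in/out degrees of every node and all edge-type counts are preserved.
    Every edge type is bipartite between distinct node types, so swaps can
    never create self-edges.
    """
    new_edges: set[tuple[str, str, str]] = set()
    for etype in EDGE_TYPES:
        edges = network.edges_of_type(etype)
        edge_set = set(edges)
        if len(edges) >= 2:
            n_attempts = swaps_per_edge * len(edges)
            pairs = rng.integers(0, len(edges), size=(n_attempts, 2))
            for i, j in pairs:
                if i == j:
                    continue
                a, b = edges[i]
                c, d = edges[j]
                if a == c or b == d:
                    continue
                if (a, d) in edge_set or (c, b) in edge_set:
                    continue
                edge_set.discard((a, b))
                edge_set.discard((c, d))
                edge_set.add((a, d))
                edge_set.add((c, b))
                edges[i] = (a, d)
                edges[j] = (c, b)
        new_edges |= {(s, t, etype) for s, t in edge_set}
    return RegulatoryNetwork(dict(network.nodes), new_edges)


@dataclass
class PatternStats:
    pattern_id: str
    observed: int
    null_mean: float
    null_sd: float
    z: float | None  # None when the null standard deviation is zero
    name: str | None = None


def pattern_zscores(
    network: RegulatoryNetwork,
    catalog: Sequence[PatternCatalogEntry],
    n_random: int = 100,
    rng: np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> list[PatternStats]:
    """Observed counts vs the mean/sd over ``n_random`` edge-swap nulls."""
    if rng is None:
        rng = np.random.default_rng()
    observed = count_patterns(network, catalog)
    null_counts = {entry.pattern_id: [] for entry in catalog}
    for _ in range(n_random):
        null_net = random_network(network, rng, swaps_per_edge)
        counts = count_patterns(null_net, catalog)
        for pid, c in counts.items():
            null_counts[pid].append(c)
    stats: list[PatternStats] = []
    for entry in catalog:
        arr = np.array(null_counts[entry.pattern_id], dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        z = (observed[entry.pattern_id] - mean) / sd if sd > 0 else None
        stats.append(
            PatternStats(
                pattern_id=entry.pattern_id,
                observed=observed[entry.pattern_id],
                null_mean=mean,
                null_sd=sd,
                z=round(z, 4) if z is not None else None,
                name=entry.name,
            )
        )
    return stats


def write_pattern_stats(
    stats: Sequence[PatternStats],
    catalog: Sequence[PatternCatalogEntry],
    path,
) -> None:
    by_id = {e.pattern_id: e for e in catalog}
    with open(path, "w") as handle:
        handle.write("pattern_id\tname\tedges\tobserved\tnull_mean\tnull_sd\tz\n")
        for s in stats:
            entry = by_id[s.pattern_id]
            z = "NA" if s.z is None else f"{s.z:.4f}"
            handle.write(
                f"{s.pattern_id}\t{s.name or 'NA'}\t{entry.describe()}\t"
                f"{s.observed}\t{s.null_mean!r}\t{s.null_sd!r}\t{z}\n"
            )
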