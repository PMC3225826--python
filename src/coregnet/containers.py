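"""Core in-memory containers shared across the pipeline.

All containers validate their invariants at construction time so that
malformed objects fail close to where they were built, not three stages
later inside a permutation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX["N"] = 4

NODE_TYPES = ("CRM", "MIRNA", "GENE")

#: edge type -> (source node type, target node type)
EDGE_TYPES: dict[str, tuple[str, str]] = {
    "C2G": ("CRM", "GENE"),
    "M2G": ("MIRNA", "GENE"),
    "C2M": ("CRM", "MIRNA"),
    "M2C": ("MIRNA", "CRM"),
}

REGULATOR_CLASSES = ("CRM", "MIRNA", "MODULE")


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class FormatError(ValueError):
    """An input file is malformed; message names the offending line."""


@dataclass
class ExpressionMatrix:
    """Probeset-level expression values plus a partial probeset->gene map.

    Rows are probesets, columns are samples.  A gene may own several
    probesets; probesets with no mapped gene are retained but ignored by
    gene-level computations.
    """

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probeset_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_rows, n_cols = self.values.shape
        if n_rows != len(self.probeset_ids):
            raise ValidationError(
                f"{len(self.probeset_ids)} probeset IDs but {n_rows} value rows"
            )
        if n_cols != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample IDs but {n_cols} value columns"
            )
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            dupes = {p for p in self.probeset_ids if self.probeset_ids.count(p) > 1}
            raise ValidationError(f"duplicate probeset IDs: {sorted(dupes)[:5]}")
        known = set(self.probeset_ids)
        for probeset in self.probeset_to_gene:
            if probeset not in known:
                raise ValidationError(
                    f"gene map references unknown probeset {probeset!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_to_probesets(self) -> dict[str, list[str]]:
        """Invert the probeset->gene map; probeset order follows the matrix."""
        out: dict[str, list[str]] = {}
        for probeset in self.probeset_ids:
            gene = self.probeset_to_gene.get(probeset)
            if gene is not None:
                out.setdefault(gene, []).append(probeset)
        return out

    def genes(self) -> set[str]:
        return set(self.probeset_to_gene.values())


@dataclass
class TargetMap:
    """Regulator ID -> set of target gene IDs for one regulator class."""

    regulator_class: str
    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValidationError(
                f"regulator_class must be one of {REGULATOR_CLASSES}, "
                f"got {self.regulator_class!r}"
            )
        for regulator, genes in self.entries.items():
            if regulator == "":
                raise ValidationError("empty regulator ID")
            self.entries[regulator] = set(genes)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, regulator: str) -> set[str]:
        return self.entries[regulator]

    def gene_universe(self) -> set[str]:
        union: set[str] = set()
        for genes in self.entries.values():
            union |= genes
        return union


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over A,C,G,T."""

    motif_id: str
    probs: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValidationError(
                f"PWM {self.motif_id}: probs must be 4 x L, got {self.probs.shape}"
            )
        if self.probs.shape[1] < 1:
            raise ValidationError(f"PWM {self.motif_id}: length must be >= 1")
        if np.any(self.probs < 0):
            raise ValidationError(f"PWM {self.motif_id}: negative probabilities")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(
                f"PWM {self.motif_id}: columns do not sum to 1 (max dev "
                f"{np.max(np.abs(sums - 1.0)):.2e})"
            )

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=0)
        if np.any(sums <= 0):
            bad = int(np.argmin(sums))
            raise ValidationError(
                f"PWM {motif_id}: position {bad + 1} has zero total count"
            )
        return cls(motif_id, counts / sums)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))


@dataclass
class CRMDefinition:
    """A cis-regulatory module: a set of binding-motif (PWM) identifiers."""

    crm_id: str
    motif_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.motif_ids = frozenset(self.motif_ids)
        if not self.motif_ids:
            raise ValidationError(f"CRM {self.crm_id}: needs >= 1 motif")


@dataclass
class CRMiRNAModule:
    """Genes targeted by both a CRM and a miRNA, with optional statistics."""

    crm_id: str
    mirna_id: str
    genes: frozenset[str]
    coherence: float | None = None
    p_value: float | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if len(self.genes) < 2:
            raise ValidationError(
                f"module ({self.crm_id},{self.mirna_id}): needs >= 2 genes"
            )


@dataclass
class RegulatoryNetwork:
    """Typed tripartite network over CRM, miRNA and gene nodes.

    Edges are (source, target, edge_type) with edge_type one of C2G, M2G,
    C2M, M2C; endpoint node types must match the edge type and self-edges
    are impossible by construction (every edge type joins distinct types).
    """

    nodes: dict[str, str]
    edges: set[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for node, ntype in self.nodes.items():
            if ntype not in NODE_TYPES:
                raise ValidationError(f"node {node!r}: unknown type {ntype!r}")
        for src, tgt, etype in self.edges:
            if etype not in EDGE_TYPES:
                raise ValidationError(f"unknown edge type {etype!r}")
            want_src, want_tgt = EDGE_TYPES[etype]
            if self.nodes.get(src) != want_src or self.nodes.get(tgt) != want_tgt:
                raise ValidationError(
                    f"edge ({src},{tgt},{etype}): endpoint types "
                    f"({self.nodes.get(src)},{self.nodes.get(tgt)}) do not match"
                )
            if src == tgt:
                raise ValidationError(f"self-edge on {src!r}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "RegulatoryNetwork":
        """Build a network inferring node types from edge types."""
        nodes: dict[str, str] = {}
        edge_set: set[tuple[str, str, str]] = set()
        for src, tgt, etype in edges:
            if etype not in EDGE_TYPES:
                raise ValidationError(f"unknown edge type {etype!r}")
            src_t, tgt_t = EDGE_TYPES[etype]
            for node, ntype in ((src, src_t), (tgt, tgt_t)):
                prev = nodes.setdefault(node, ntype)
                if prev != ntype:
                    raise ValidationError(
                        f"node {node!r} used both as {prev} and {ntype}"
                    )
            edge_set.add((src, tgt, etype))
        return cls(nodes, edge_set)

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t == ntype)

    def edges_of_type(self, etype: str) -> list[tuple[str, str]]:
        return sorted((s, t) for s, t, e in self.edges if e == etype)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class KnockdownDataset:
    """Per-gene knockdown log-ratios with TF and miRNA target indicators.

    ``g`` holds, per gene, the log ratio of expression after TF depletion
    versus before treatment; ``b_tf`` and ``b_mir`` are 0/1 indicators of
    whether the gene is targeted by the TF / by each miRNA.
    """

    gene_ids: list[str]
    g: np.ndarray
    b_tf: np.ndarray
    b_mir: np.ndarray  # genes x miRNAs
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.b_tf = np.asarray(self.b_tf, dtype=float)
        self.b_mir = np.asarray(self.b_mir, dtype=float)
        n = len(self.gene_ids)
        if self.g.shape != (n,) or self.b_tf.shape != (n,):
            raise ValidationError("g and b_tf must have one entry per gene")
        if self.b_mir.shape != (n, len(self.mirna_ids)):
            raise ValidationError(
                f"b_mir shape {self.b_mir.shape} != ({n}, {len(self.mirna_ids)})"
            )
        for arr, name in ((self.b_tf, "b_tf"), (self.b_mir, "b_mir")):
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ValidationError(f"{name} entries must be 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic-data generators."""

    planted_blocks: list[tuple[frozenset[str], float]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    planted_ffls: list[tuple[str, str, str]] = field(default_factory=list)
    active_mirnas: set[str] = field(default_factory=set)
    coefficients: dict[str, float] = field(default_factory=dict)
    #: (crm_id, mirna_id, genes) forced into both regulators' target sets
    planted_overlaps: list[tuple[str, str, frozenset[str]]] = field(
        default_factory=list
    )

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            planted_blocks=self.planted_blocks + other.planted_blocks,
            planted_sites=self.planted_sites + other.planted_sites,
            planted_ffls=self.planted_ffls + other.planted_ffls,
            active_mirnas=self.active_mirnas | other.active_mirnas,
            coefficients={**self.coefficients, **other.coefficients},
            planted_overlaps=self.planted_overlaps + other.planted_overlaps,
        )
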