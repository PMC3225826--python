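"""Gene-pair Pearson correlation with the max-over-probesets rule, and the
coherence statistic (mean pairwise correlation) of a gene set.

A gene on a microarray may be measured by several probesets; the
correlation between two genes is taken as the maximum Pearson correlation
over all of their probeset pairs.  Probeset pairs in which either member
has zero variance are skipped; if every pair is skipped the gene-pair
correlation is undefined (``None`` / NaN), and undefined pairs are excluded
from the coherence mean rather than being counted as zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float | None  # None when every probeset pair has a zero-variance member


class CoherenceEngine:
    """Caches standardized probeset rows for fast repeated correlations.

    Centers and L2-normalizes every probeset row once; any gene-pair
    correlation is then a dot-product maximum over the two genes' rows.
    Gene-level results are memoized, which makes permutation testing over
    many overlapping gene sets cheap.
    """

    def __init__(self, expr: ExpressionMatrix):
        if expr.n_samples < 3:
            raise ValueError("need >= 3 samples for meaningful correlations")
        self.expr = expr
        values = expr.values
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        self._zero_var = norms == 0
        safe = np.where(self._zero_var, 1.0, norms)
        self._z = centered / safe[:, None]
        self._row_index = {p: i for i, p in enumerate(expr.probeset_ids)}
        self._gene_rows = {
            gene: np.array([self._row_index[p] for p in probes])
            for gene, probes in expr.gene_to_probesets().items()
        }
        self._pair_cache: dict[tuple[str, str], float] = {}

    @property
    def genes(self) -> set[str]:
        return set(self._gene_rows)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_rows

    def pair(self, gene_a: str, gene_b: str) -> float:
        """Max-over-probeset-pairs Pearson r; NaN when undefined."""
        key = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        cached = self._pair_cache.get(key)
        if cached is not None:
            return cached
        try:
            rows_a = self._gene_rows[gene_a]
            rows_b = self._gene_rows[gene_b]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} has no probeset in the matrix")
        rmat = self._z[rows_a] @ self._z[rows_b].T
        mask = np.logical_or.outer(self._zero_var[rows_a], self._zero_var[rows_b])
        rmat = np.where(mask, np.nan, rmat)
        r = np.nan if np.isnan(rmat).all() else float(np.clip(np.nanmax(rmat), -1, 1))
        self._pair_cache[key] = r
        return r

    def usable_genes(self, genes: Iterable[str]) -> list[str]:
        """Genes present in the matrix, sorted for deterministic iteration."""
        return sorted(g for g in set(genes) if g in self._gene_rows)

    def coherence(self, genes: Iterable[str]) -> float:
        """Mean pairwise correlation over the set; NaN when undefined."""
        usable = self.usable_genes(genes)
        if len(usable) < 2:
            return float("nan")
        rs = [self.pair(a, b) for a, b in itertools.combinations(usable, 2)]
        rs = [r for r in rs if not np.isnan(r)]
        return float(np.mean(rs)) if rs else float("nan")

    def correlation_matrix(self, genes: Sequence[str]) -> np.ndarray:
        """Symmetric gene-level correlation matrix (NaN where undefined)."""
        genes = list(genes)
        n = len(genes)
        out = np.full((n, n), np.nan)
        np.fill_diagonal(out, 1.0)
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = self.pair(genes[i], genes[j])
        return out


def gene_pair_correlation(
    expr: ExpressionMatrix | CoherenceEngine, gene_a: str, gene_b: str
) -> CorrelationResult:
    """Pearson correlation of a gene pair under the max-over-probesets rule."""
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    r = engine.pair(gene_a, gene_b)
    return CorrelationResult(gene_a, gene_b, None if np.isnan(r) else r)


def pairwise_correlations(
    expr: ExpressionMatrix | CoherenceEngine, genes: Iterable[str]
) -> list[CorrelationResult]:
    """All unordered gene-pair correlations, in sorted gene order."""
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    usable = engine.usable_genes(genes)
    return [
        gene_pair_correlation(engine, a, b)
        for a, b in itertools.combinations(usable, 2)
    ]


def coherence(expr: ExpressionMatrix | CoherenceEngine, genes: Iterable[str]) -> float:
    """Mean Pearson correlation over all unordered gene pairs in the set.

    Returns NaN when fewer than two usable genes remain or every pair is
    undefined.
    """
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    return engine.coherence(genes)
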