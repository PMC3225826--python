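"""Randomization backgrounds, empirical p-values and FDR correction for
module coherence.

Two nulls are implemented for a CRM-miRNA module:

* background 1 — redraw the module's genes (same size) from the CRM's
  target pool, isolating the miRNA's contribution on top of the CRM;
* background 2 — build an artificial miRNA by redrawing the real miRNA's
  target count from the union of all miRNA target genes, then intersect
  with the CRM's targets, preserving the miRNA target-number distribution.

A third null redraws a regulator's targets from the whole gene universe
(used for plain CRM / miRNA coherence baselines).  The empirical p-value
is the proportion of random sets whose coherence is at least the observed
one (ties count), over ``n_reps`` draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coherence import CoherenceEngine
from .containers import CRMiRNAModule, ExpressionMatrix, TargetMap

BG1_CRM_POOL = "BG1_CRM_POOL"
BG2_ARTIFICIAL_MIRNA = "BG2_ARTIFICIAL_MIRNA"
WHOLE_GENE_SET = "WHOLE_GENE_SET"

_KINDS = (BG1_CRM_POOL, BG2_ARTIFICIAL_MIRNA, WHOLE_GENE_SET)

#: cap on redraws of a degenerate background set before scoring it -inf
MAX_REDRAWS = 1000


@dataclass
class BackgroundSpec:
    kind: str
    n_reps: int = 100
    seed: int = 0
    bg1_pool: str = "crm"  # "crm": that CRM's targets; "union": all CRM targets

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.bg1_pool not in ("crm", "union"):
            raise ValueError("bg1_pool must be 'crm' or 'union'")


def _sorted_sample(pool: Sequence[str], k: int, rng: np.random.Generator) -> set[str]:
    idx = rng.choice(len(pool), size=k, replace=False)
    return {pool[i] for i in idx}


def sample_background1(
    module: CRMiRNAModule,
    crm_targets: TargetMap,
    rng: np.random.Generator,
    pool: str = "crm",
) -> set[str]:
    """Uniform same-size redraw of the module's genes from the CRM pool."""
    if pool == "crm":
        universe = sorted(crm_targets.entries[module.crm_id])
    elif pool == "union":
        universe = sorted(crm_targets.gene_universe())
    else:
        raise ValueError(f"unknown pool {pool!r}")
    if len(universe) < len(module.genes):
        raise ValueError(
            f"background pool ({len(universe)}) smaller than module "
            f"({len(module.genes)})"
        )
    return _sorted_sample(universe, len(module.genes), rng)


def sample_background2(
    module: CRMiRNAModule,
    crm_targets: TargetMap,
    mirna_targets: TargetMap,
    rng: np.random.Generator,
) -> set[str]:
    """Artificial-miRNA redraw: degree-matched targets, then CRM intersection.

    The returned set may have any size, including fewer than two genes.
    """
    universe = sorted(mirna_targets.gene_universe())
    k = len(mirna_targets.entries[module.mirna_id])
    artificial = _sorted_sample(universe, k, rng)
    return artificial & crm_targets.entries[module.crm_id]


def sample_regulator_background(
    target_count: int, gene_universe: Iterable[str], rng: np.random.Generator
) -> set[str]:
    """Uniform redraw of a regulator's targets from the whole gene set."""
    universe = sorted(set(gene_universe))
    if target_count > len(universe):
        raise ValueError("target_count exceeds universe size")
    return _sorted_sample(universe, target_count, rng)


def _draw_background(
    module: CRMiRNAModule,
    background: BackgroundSpec,
    crm_targets: TargetMap,
    mirna_targets: TargetMap | None,
    rng: np.random.Generator,
) -> set[str]:
    if background.kind == BG1_CRM_POOL:
        return sample_background1(module, crm_targets, rng, pool=background.bg1_pool)
    if background.kind == BG2_ARTIFICIAL_MIRNA:
        if mirna_targets is None:
            raise ValueError("background 2 requires the miRNA target map")
        return sample_background2(module, crm_targets, mirna_targets, rng)
    universe = crm_targets.gene_universe()
    if mirna_targets is not None:
        universe |= mirna_targets.gene_universe()
    return sample_regulator_background(len(module.genes), universe, rng)


@dataclass
class PvalueResult:
    p: float | None
    redraws: int = 0
    background_coherences: list[float] = field(default_factory=list)


def module_pvalue(
    expr: ExpressionMatrix | CoherenceEngine,
    module: CRMiRNAModule,
    background: BackgroundSpec,
    crm_targets: TargetMap,
    mirna_targets: TargetMap | None = None,
    module_index: int = 0,
) -> float | None:
    """Empirical coherence p-value of one module against a background null."""
    return _module_pvalue_full(
        expr, module, background, crm_targets, mirna_targets, module_index
    ).p


def _module_pvalue_full(
    expr: ExpressionMatrix | CoherenceEngine,
    module: CRMiRNAModule,
    background: BackgroundSpec,
    crm_targets: TargetMap,
    mirna_targets: TargetMap | None,
    module_index: int,
) -> PvalueResult:
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    observed = (
        module.coherence
        if module.coherence is not None
        else engine.coherence(module.genes)
    )
    if observed is None or np.isnan(observed):
        return PvalueResult(p=None)

    # one generator per (run seed, module index): reproducible and
    # independent of evaluation order across modules
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=background.seed, spawn_key=(module_index,))
    )
    hits = 0
    redraws = 0
    coherences: list[float] = []
    for _ in range(background.n_reps):
        value = -np.inf
        for _attempt in range(MAX_REDRAWS):
            genes = _draw_background(
                module, background, crm_targets, mirna_targets, rng
            )
            value = engine.coherence(genes) if len(genes) >= 2 else np.nan
            if not np.isnan(value):
                break
            redraws += 1
        else:
            value = -np.inf  # persistently degenerate draw: never >= observed
        coherences.append(value)
        if value >= observed:
            hits += 1
    return PvalueResult(
        p=hits / background.n_reps, redraws=redraws, background_coherences=coherences
    )


def score_modules(
    expr: ExpressionMatrix | CoherenceEngine,
    modules: Sequence[CRMiRNAModule],
    background: BackgroundSpec,
    crm_targets: TargetMap,
    mirna_targets: TargetMap | None = None,
) -> list[CRMiRNAModule]:
    """Coherence, empirical p and BH q for every module (new objects)."""
    engine = expr if isinstance(expr, CoherenceEngine) else CoherenceEngine(expr)
    scored: list[CRMiRNAModule] = []
    for idx, module in enumerate(modules):
        obs = engine.coherence(module.genes)
        obs_val = None if np.isnan(obs) else obs
        mod = CRMiRNAModule(module.crm_id, module.mirna_id, module.genes, obs_val)
        if obs_val is not None:
            mod.p_value = module_pvalue(
                engine, mod, background, crm_targets, mirna_targets, module_index=idx
            )
        scored.append(mod)
    qvals = fdr_correct([m.p_value for m in scored])
    for mod, q in zip(scored, qvals):
        mod.q_value = q
    return scored


def fdr_correct(pvalues: Sequence[float | None]) -> list[float | None]:
    """Benjamini-Hochberg step-up q-values; ``None`` entries pass through.

    q for the i-th smallest p is ``min_{j >= i} p_(j) * m / j`` capped at 1,
    which preserves the input order of significance.
    """
    defined = [(i, p) for i, p in enumerate(pvalues) if p is not None]
    out: list[float | None] = [None] * len(pvalues)
    if defined:
        p = np.array([v for _, v in defined], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q_sorted = np.minimum(q_sorted, 1.0)
        q = np.empty(m)
        q[order] = q_sorted
        for (i, _), value in zip(defined, q):
            out[i] = float(value)
    return out
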