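"""Linear co-regulation model for TF-knockdown expression log-ratios.

Each gene's log expression ratio (after TF depletion vs before) is modelled
as

    g_k = c + a_TF * b_TF,k + sum_i a_mir_i * b_mir_i,k + error

with 0/1 target indicators and effect sizes shared across genes.  Candidate
miRNAs are first prescreened one at a time (intercept + TF + one miRNA;
two-sided t-test on the miRNA coefficient), and the survivors enter a
bidirectional stepwise search over miRNA terms minimising
AIC = n*ln(RSS/n) + 2k, with the intercept and TF term always kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .containers import KnockdownDataset


@dataclass
class FitResult:
    intercept: float
    a_tf: float
    a_mir: dict[str, float]
    se: dict[str, float]  # keys: "intercept", "tf", and miRNA IDs
    pvalues: dict[str, float]
    aic: float
    selected: list[str]
    aic_trace: list[tuple[str, float]] = field(default_factory=list)


def _design(data: KnockdownDataset, mirna_subset: Sequence[str]) -> np.ndarray:
    cols = [np.ones(data.n_genes), data.b_tf]
    idx = {m: i for i, m in enumerate(data.mirna_ids)}
    for m in mirna_subset:
        cols.append(data.b_mir[:, idx[m]])
    return np.column_stack(cols)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian profile log-likelihood up to a constant shared by all models
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + 2 * k)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def prescreen_mirna(data: KnockdownDataset, mirna_id: str) -> float | None:
    """Two-sided p-value of the miRNA term in the one-miRNA-at-a-time model.

    Returns ``None`` (with a warning) when the design is rank deficient,
    e.g. the miRNA targets no gene or every gene.
    """
    X = _design(data, [mirna_id])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(f"prescreen design rank-deficient for {mirna_id}; excluded")
        return None
    fit = sm.OLS(data.g, X).fit()
    return float(fit.pvalues[2])


def fit_full_model(
    data: KnockdownDataset, mirna_subset: Sequence[str]
) -> FitResult:
    """OLS fit of the full linear model on the given miRNA subset."""
    mirna_subset = list(mirna_subset)
    X = _design(data, mirna_subset)
    fit = sm.OLS(data.g, X).fit()
    names = ["intercept", "tf"] + mirna_subset
    se = dict(zip(names, (float(v) for v in fit.bse)))
    pvals = dict(zip(names, (float(v) for v in fit.pvalues)))
    rss = float(fit.ssr)
    return FitResult(
        intercept=float(fit.params[0]),
        a_tf=float(fit.params[1]),
        a_mir={m: float(v) for m, v in zip(mirna_subset, fit.params[2:])},
        se=se,
        pvalues=pvals,
        aic=_aic(rss, data.n_genes, X.shape[1]),
        selected=mirna_subset,
    )


def stepwise_select(
    data: KnockdownDataset,
    candidate_mirnas: Sequence[str],
    prescreen_alpha: float = 0.05,
) -> FitResult:
    """Prescreen + bidirectional stepwise-AIC selection of miRNA terms.

    Deterministic for a given candidate order; ties in AIC are broken by
    candidate order (adds considered before drops).
    """
    if data.n_genes < 2:
        raise ValueError("need >= 2 genes")
    if not candidate_mirnas:
        raise ValueError("candidate list is empty")

    survivors = []
    for m in candidate_mirnas:
        p = prescreen_mirna(data, m)
        if p is not None and p < prescreen_alpha:
            survivors.append(m)

    y = data.g
    n = data.n_genes
    selected: list[str] = []
    current_aic = _aic(_rss(_design(data, selected), y), n, 2)
    trace: list[tuple[str, float]] = [("start", current_aic)]

    while True:
        best_move: tuple[str, str] | None = None
        best_aic = current_aic
        for m in survivors:  # forward adds, candidate order
            if m in selected:
                continue
            aic = _aic(_rss(_design(data, selected + [m]), y), n, 3 + len(selected))
            if aic < best_aic - 1e-12:
                best_aic, best_move = aic, ("add", m)
        for m in selected:  # backward drops
            rest = [x for x in selected if x != m]
            aic = _aic(_rss(_design(data, rest), y), n, 2 + len(rest))
            if aic < best_aic - 1e-12:
                best_aic, best_move = aic, ("drop", m)
        if best_move is None:
            break
        action, m = best_move
        if action == "add":
            selected.append(m)
        else:
            selected.remove(m)
        current_aic = best_aic
        trace.append((f"{action}:{m}", current_aic))

    result = fit_full_model(data, selected)
    result.aic_trace = trace
    return result


def write_fit_result(result: FitResult, path) -> None:
    with open(path, "w") as handle:
        handle.write("term\tcoefficient\tse\tp_value\n")
        rows = [("intercept", result.intercept), ("tf", result.a_tf)]
        rows += [(m, result.a_mir[m]) for m in result.selected]
        for name, coef in rows:
            handle.write(
                f"{name}\t{coef!r}\t{result.se.get(name)!r}\t"
                f"{result.pvalues.get(name)!r}\n"
            )
        handle.write(f"# aic\t{result.aic!r}\n")
        for step, aic in result.aic_trace:
            handle.write(f"# step\t{step}\t{aic!r}\n")
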