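import numpy as np
import pytest

from coregnet import synthetic_data
from coregnet.coherence import CoherenceEngine
from coregnet.containers import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def block_expr():
    """Small matrix with one strong co-expression block and noisy extra
    probesets, for max-over-probesets exercises."""
    expr, truth = synthetic_data.gen_expression(
        n_genes=30,
        n_samples=40,
        blocks=[(6, 0.9)],
        noise_sd=0.6,
        seed=11,
        extra_probesets=1,
    )
    return expr, truth


@pytest.fixture
def block_engine(block_expr):
    expr, truth = block_expr
    return CoherenceEngine(expr), truth


def make_expr(values, genes, sample_prefix="S"):
    """Expression matrix where probeset i maps to genes[i]; values row-wise."""
    values = np.asarray(values, dtype=float)
    probesets = [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        probeset_ids=probesets,
        sample_ids=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values=values,
        probeset_to_gene={p: g for p, g in zip(probesets, genes) if g is not None},
    )
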