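import numpy as np
import pandas as pd
import pytest

from netqtl.io_model import ExpressionMatrix, GeneMap, GenotypeMatrix, ProcessingState


def planted_tensor(p=50, support=5, lam=2.5, q=3, seed=0):
    """Exact rank-1 sparse tensor lam * v0 o v0 o u0 plus its factors."""
    rng = np.random.default_rng(seed)
    v = np.zeros(p)
    idx = rng.choice(p, support, replace=False)
    v[idx] = rng.standard_normal(support)
    v /= np.linalg.norm(v)
    u = rng.standard_normal(q)
    u /= np.linalg.norm(u)
    return lam * np.einsum("j,k,l->jkl", v, v, u), v, u


def random_symmetric(p, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, p))
    return A + A.T


@pytest.fixture
def tiny_expression(tmp_path):
    """3-gene x 2-sample raw-count TSV plus its path."""
    path = tmp_path / "expr.tsv"
    path.write_text("gene_id\ts1\ts2\ng1\t10\t20\ng2\t0\t5\ng3\t7\t3\n")
    return path


@pytest.fixture
def residual_expr():
    """Residualized 5-gene x 20-sample Gaussian matrix."""
    rng = np.random.default_rng(11)
    vals = rng.standard_normal((5, 20))
    vals -= vals.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        vals,
        [f"g{j}" for j in range(5)],
        [f"s{i}" for i in range(20)],
        ProcessingState.RESIDUALIZED,
    )


@pytest.fixture
def gene_map_two_chrom():
    """Genes g0, g1 on chr 1; g2, g3, g4 on chr 2."""
    table = pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(5)],
            "chrom": [1, 1, 2, 2, 2],
            "pos": [1, 2, 1, 2, 3],
        }
    ).set_index("gene_id")
    return GeneMap(table)


@pytest.fixture
def six_sample_genotypes():
    codes = np.array([[0, 0, 1, 1, 2, 2], [0, 0, 0, 0, 0, 0], [0, 0, 1, -1, 2, 2]], dtype=np.int8)
    return GenotypeMatrix(
        codes, ["m1", "m2", "m3"], [f"s{i}" for i in range(6)]
    )
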