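import numpy as np
import pytest

from coac.matrix import ExpressionMatrix


@pytest.fixture
def toy_dense() -> ExpressionMatrix:
    """4 cells x 3 genes, small integers, full rank."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 9, size=(4, 3)).astype(float)
    return ExpressionMatrix(values, gene_ids=["gA", "gB", "gC"], cell_ids=["c1", "c2", "c3", "c4"])


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """6 cells x 5 genes of random nonnegative values."""
    rng = np.random.default_rng(11)
    values = rng.random((6, 5)) * 5
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(5)],
        cell_ids=[f"c{i}" for i in range(6)],
    )


def write_mtx_triple(tmpdir, shape=(5, 4), nnz=6, seed=3):
    """Write a 10x-style triple (genes x cells on disk) and return its dir."""
    rng = np.random.default_rng(seed)
    rows = rng.choice(shape[0] * shape[1], size=nnz, replace=False)
    g, c = np.unravel_index(rows, shape)
    lines = [f"{gi + 1} {ci + 1} {rng.integers(1, 9)}" for gi, ci in zip(g, c)]
    (tmpdir / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        f"{shape[0]} {shape[1]} {nnz}\n" + "\n".join(lines) + "\n"
    )
    (tmpdir / "genes.tsv").write_text("".join(f"G{i}\tG{i}\n" for i in range(shape[0])))
    (tmpdir / "barcodes.tsv").write_text("".join(f"BC{i}\n" for i in range(shape[1])))
    return tmpdir
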