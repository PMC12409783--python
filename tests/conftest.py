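import numpy as np
import pytest

from stweave import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A small easy simulation shared by mechanics tests (distinct, k=4)."""
    return simulate(SimConfig(grid=(12, 12), k=4, pattern="distinct",
                              dropout=0.0, noise=0.5, n_genes=60,
                              n_imgfeat=40, markers_per_group=10, seed=3))


@pytest.fixture
def visium_dir(tmp_path):
    """Write a tiny Visium-like directory (3 spots x 5 genes, genes-in-rows
    MTX as CellRanger emits) and return (path, expression spots x genes)."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    rng = np.random.default_rng(0)
    expr = rng.integers(0, 6, size=(3, 5)).astype(float)
    spio.mmwrite(str(tmp_path / "matrix.mtx"), csr_matrix(expr.T))  # genes x spots
    (tmp_path / "barcodes.tsv").write_text("BC-1\nBC-2\nBC-3\n")
    (tmp_path / "features.tsv").write_text(
        "".join(f"ENSG{j}\tGene{j}\tGene Expression\n" for j in range(5)))
    # headerless 6-column positions incl. one extra barcode not in the matrix
    rows = ["BC-1,1,0,0,10,20", "BC-2,1,0,1,10,40", "BC-3,1,1,0,30,20",
            "BC-9,1,9,9,99,99"]
    (tmp_path / "tissue_positions_list.csv").write_text("\n".join(rows) + "\n")
    return tmp_path, expr
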