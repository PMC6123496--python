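import numpy as np
import pandas as pd
import pytest

from sctnbc.types import ExpressionMatrix


@pytest.fixture
def make_expr():
    """Factory for small expression matrices with auto ids."""

    def _make(values, unit="raw_tpm", cell_ids=None, gene_ids=None):
        values = np.asarray(values, dtype=float)
        cells = cell_ids or [f"c{i}" for i in range(values.shape[0])]
        genes = gene_ids or [f"g{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(values, cells, genes, unit)

    return _make


@pytest.fixture
def single_chrom_genes():
    """Factory for a gene table on one chromosome in id order."""

    def _make(n, chrom="chr1"):
        return pd.DataFrame(
            {
                "gene_id": [f"g{j}" for j in range(n)],
                "chromosome": chrom,
                "start": np.arange(1, n + 1) * 100,
                "order_index": np.arange(1, n + 1),
            }
        )

    return _make
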