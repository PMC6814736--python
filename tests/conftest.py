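import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bpa.bpa_core import ExpressionMatrix
from bpa.geneset_io import GeneSet, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """20 genes x 5 cells, strictly positive, tie-free within columns."""
    values = rng.uniform(0.1, 6.0, size=(20, 5))
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{j}" for j in range(5)],
        values=values,
    )


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        sets=[
            GeneSet("S1", "d", ("g0", "g1", "g2", "g3", "g4")),
            GeneSet("S2", "d", ("g5", "g6", "g7", "g8", "g9", "g10")),
            GeneSet("S3", "d", tuple(f"g{i}" for i in range(20))),
        ]
    )


@pytest.fixture
def gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
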