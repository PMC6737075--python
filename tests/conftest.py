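import numpy as np
import pandas as pd
import pytest

from bbmprofiler.groups import GROUP_ORDER
from bbmprofiler.tables import AnnotationMap, SpectralCountTable


def make_count_table(counts, ids=None, symbols=None) -> SpectralCountTable:
    """Build a SpectralCountTable from an (n, 4) array of counts."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = ids or [f"P{i}" for i in range(n)]
    symbols = symbols or [f"Gene{i}" for i in range(n)]
    return SpectralCountTable(
        pd.DataFrame(
            {
                "protein_id": ids,
                "gene_symbol": symbols,
                **{g: counts[:, j] for j, g in enumerate(GROUP_ORDER)},
            }
        )
    )


@pytest.fixture
def small_table() -> SpectralCountTable:
    return make_count_table(
        [[10, 30, 10, 10], [20, 20, 60, 60], [5, 5, 5, 5]],
        ids=["villin_like", "irtks_like", "flat"],
        symbols=["Vil1", "Baiap2l1", "Flat1"],
    )


@pytest.fixture
def small_annotation() -> AnnotationMap:
    return AnnotationMap(
        {
            "actin_filament": frozenset({"Vil1", "Baiap2l1"}),
            "other": frozenset({"Flat1"}),
        }
    )
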