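import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from binplex.binning import BinGrid, PseudoCountMatrix
from binplex.differential import BinaryCoding


@pytest.fixture
def make_matrix():
    """Factory for small PseudoCountMatrix objects from raw count arrays."""

    def _make(counts, markers, section_id="S1", resolution_um=0.325, bin_side_px=31):
        counts = np.asarray(counts, dtype=float)
        n = counts.shape[0]
        grid = BinGrid(
            bin_side_px=bin_side_px, n_rows=1, n_cols=n, resolution_um=resolution_um
        )
        return PseudoCountMatrix(
            section_id=section_id,
            counts=counts,
            markers=tuple(markers),
            grid=grid,
            coords=grid.coordinates(),
        )

    return _make


@pytest.fixture
def make_coding():
    """Factory for BinaryCoding objects from raw 0/1 arrays."""

    def _make(values, markers, section_id="S1", group="A"):
        values = np.asarray(values, dtype=np.uint8)
        n = values.shape[0]
        grid = BinGrid(bin_side_px=31, n_rows=1, n_cols=n, resolution_um=0.325)
        return BinaryCoding(
            section_id=section_id,
            group=group,
            values=values,
            markers=tuple(markers),
            coords=grid.coordinates(),
            alpha_bin=0.05,
            lambdas=pd.Series(1.0, index=list(markers)),
        )

    return _make
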