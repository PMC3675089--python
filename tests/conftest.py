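import numpy as np
import pytest

from alauda.landscape import ElementType, LandscapeGrid, Plot, Polygon, VegetationState
from alauda.params import SkylarkParams


@pytest.fixture
def params():
    return SkylarkParams()


def uniform_grid(
    nrows: int,
    ncols: int,
    element_type: ElementType = ElementType.FIELD,
    cell_size: float = 1.0,
    veg: VegetationState | None = None,
    **poly_kwargs,
) -> LandscapeGrid:
    """A single-polygon rectangular landscape for arithmetic oracles."""
    ids = np.ones((nrows, ncols), dtype=np.int32)
    poly = Polygon(
        poly_id=1,
        element_type=element_type,
        veg=veg or VegetationState(),
        **poly_kwargs,
    )
    return LandscapeGrid(ids, [poly], cell_size=cell_size)


@pytest.fixture
def bare_grid():
    """100 x 100 m of bare earth at 1 m cells (one territory block)."""
    return uniform_grid(100, 100)
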