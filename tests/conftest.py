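import numpy as np
import pytest

from ndendo.geometry import IrregularPolygon


@pytest.fixture
def unit_square() -> IrregularPolygon:
    return IrregularPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))


@pytest.fixture
def l_shape() -> IrregularPolygon:
    """Non-convex hexagon with one reflex vertex at (1, 1)."""
    return IrregularPolygon(
        np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float)
    )
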