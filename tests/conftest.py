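import numpy as np
import pytest

from skinperm import CellGeometry, MembraneParams
from skinperm.datasets import reference_tables


@pytest.fixture(scope="session")
def tables():
    """Packaged reference tables for the eight-paraben benchmark."""
    return reference_tables()


@pytest.fixture
def geometry():
    """Default static-cell geometry with a 0.5 mL aliquot."""
    return CellGeometry(sample_volume=0.5)


@pytest.fixture
def membrane():
    """A slab realising kp = 0.01 cm/h with a 0.1 h lag."""
    return MembraneParams.from_permeability(kp=0.01, lag_time=0.1)


def pearson_r2(x, y):
    """Hand-rolled squared Pearson correlation (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    return r**2
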