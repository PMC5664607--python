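import numpy as np
import pytest

from cropsuit import GridRaster, Mask


@pytest.fixture
def rng():
    return np.random.default_rng(20170923)


def make_mask(values, cell_size_m=30.0, origin=(0.0, 0.0)):
    return Mask(np.asarray(values, dtype=bool), cell_size_m, origin)


def random_mask(rng, shape, p=0.3, cell_size_m=30.0):
    return Mask(rng.random(shape) < p, cell_size_m)


@pytest.fixture
def make_raster():
    def _make(values, cell_size_m=30.0, nodata=None, kind="continuous"):
        return GridRaster(np.asarray(values, dtype=float), cell_size_m,
                          nodata=nodata, kind=kind)
    return _make
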