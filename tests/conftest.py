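import numpy as np
import pytest

from echoplan.phantom import PhantomSpec
from echoplan.transducer import TransducerGeometry
from echoplan.volume import Grid


@pytest.fixture
def slab_spec():
    """5 mm slab centered 82.5 mm below the transducer (surface at 80 mm)."""
    return PhantomSpec(shape="flat_slab", center=(0.0, 0.0, -82.5), thickness=5.0)


@pytest.fixture
def coarse_grid():
    """0.5 mm isotropic grid around the slab, 60 x 60 x 50 mm."""
    return Grid((120, 120, 100), (0.5, 0.5, 0.5), (-30.0, -30.0, -105.0))


@pytest.fixture
def geom():
    """Transducer at the origin firing along -z (standard 250 kHz bowl)."""
    return TransducerGeometry(origin=(0.0, 0.0, 0.0), propagation=(0.0, 0.0, -1.0))
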