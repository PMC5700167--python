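import numpy as np
import pytest

from memcurve import Composition
from memcurve.frame import MembraneFrame


def bare_frame(positions, names=None, resnames=None, resids=None,
               elements=None, leaflet=None, box=(30.0, 30.0, 30.0)):
    """Minimal frame for constructed analysis inputs: one atom per residue
    unless stated otherwise."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    return MembraneFrame(
        names=np.array(names if names is not None else ["P"] * n, dtype=object),
        resnames=np.array(resnames if resnames is not None else ["PC"] * n,
                          dtype=object),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        elements=np.array(elements if elements is not None else ["C"] * n,
                          dtype=object),
        leaflet=np.array(leaflet if leaflet is not None else ["outer"] * n,
                         dtype=object),
        positions=positions,
        box=np.asarray(box, dtype=float),
    )


@pytest.fixture
def table3_composition():
    """Asymmetric plasma-membrane composition (default)."""
    return Composition()


@pytest.fixture
def pc_only_composition():
    """Cholesterol-free single-species composition for clean APL geometry."""
    return Composition({"PC": (60, 60), "CHOL": (0, 0)})
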