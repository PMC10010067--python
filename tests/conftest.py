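import numpy as np
import pytest

from rgcstim import cable, morphology


@pytest.fixture(scope="session")
def default_cell():
    """Dendrite-free standard cell, assembled and settled; shared across
    tests (read-only: simulate() never mutates the cached state)."""
    morph = morphology.build_rgc()
    system = cable.assemble(morph)
    cable.equilibrate(system)
    return system


@pytest.fixture(scope="session")
def soma_compartment():
    """Single 20 x 20 um soma compartment as a one-node cable system."""
    m = morphology.Morphology(
        x=np.array([0.0]), y=np.array([0.0]), z=np.array([-35.0]),
        length=np.array([20.0]), d_prox=np.array([20.0]), d_dist=np.array([20.0]),
        region=np.array(["soma"], dtype=object), parent=np.array([-1]),
        arc=np.array([10.0]))
    system = cable.assemble(m)
    cable.equilibrate(system)
    return system
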