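import numpy as np
import pytest

from dmportrait import PoreSpec, make_c4_pore, build_pore_axis

# residue numbers whose Ca quadruplets define the synthetic pore axis
AXIS_RESIDUES = [3, 7, 11, 15, 19]


@pytest.fixture(scope="session")
def pore23():
    """Synthetic C4 pore with a 2.3 A lumen (hydrophobic Ile gate)."""
    return make_c4_pore(PoreSpec(lumen_radius=2.3))


@pytest.fixture(scope="session")
def pore23_axis(pore23):
    return build_pore_axis(pore23, AXIS_RESIDUES)


@pytest.fixture(scope="session")
def pore10():
    """Narrow synthetic pore (1.0 A lumen), the closed-gate analogue."""
    return make_c4_pore(PoreSpec(lumen_radius=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
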