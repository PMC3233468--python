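import numpy as np
import pytest

from remdens.geometry import InternalCoordinates, build_backbone
from remdens.sequence import N_RESIDUES
from remdens.synthetic import generate_ensemble, hairpin_template, spiked_hairpin_specs


def make_ic(phi_value: float, psi_value: float) -> InternalCoordinates:
    """Uniform internal coordinates with proper terminal NaN markers."""
    phi = np.full(N_RESIDUES, phi_value)
    psi = np.full(N_RESIDUES, psi_value)
    phi[0] = np.nan
    psi[-1] = np.nan
    return InternalCoordinates(phi=phi, psi=psi)


@pytest.fixture(scope="session")
def helix_conf():
    return build_backbone(make_ic(-63.0, -43.0))


@pytest.fixture(scope="session")
def extended_conf():
    return build_backbone(make_ic(-179.0, 179.0))


@pytest.fixture(scope="session")
def hairpin1_ref():
    return hairpin_template("hairpin1")[1]


@pytest.fixture(scope="session")
def hairpin2_ref():
    return hairpin_template("hairpin2")[1]


@pytest.fixture(scope="session")
def spiked_ensemble_small():
    """1,000-frame 7% hairpin1 spike used by several clustering tests."""
    specs, ref = spiked_hairpin_specs("hairpin1", 0.07)
    return generate_ensemble(specs, 1000, 278.0, seed=77), ref
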