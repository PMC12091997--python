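import numpy as np
import pytest

import mesocoat as mc


@pytest.fixture
def single_carbon() -> mc.Structure:
    return mc.Structure(
        [mc.Atom(1, "C", "UNK", 1, "A", np.zeros(3), "C", 1.7)], id="one-atom"
    )


@pytest.fixture
def two_carbons_10A() -> mc.Structure:
    return mc.Structure(
        [
            mc.Atom(1, "C", "UNK", 1, "A", np.array([0.0, 0.0, 0.0]), "C", 1.7),
            mc.Atom(2, "C", "UNK", 2, "A", np.array([0.0, 0.0, 10.0]), "C", 1.7),
        ],
        id="two-atoms",
    )


@pytest.fixture
def helix20() -> mc.Structure:
    return mc.gen_toy_structure("ideal-helix", 20)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))
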