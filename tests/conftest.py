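import numpy as np
import pytest

from soomp.dictionaries import build_trig_dictionary
from soomp.synthetic import gaussian_dictionary, make_joint_sparse


@pytest.fixture(scope="session")
def trig_small():
    """Coherent trigonometric dictionary, 64 atoms of length 16."""
    return build_trig_dictionary(16, 32)


@pytest.fixture(scope="session")
def gauss_dict():
    """Incoherent random dictionary, 64 x 128."""
    return gaussian_dictionary(64, 128, seed=1234)


@pytest.fixture()
def joint_sparse_set(gauss_dict):
    """Four signals sharing a 5-atom support, noiseless."""
    return make_joint_sparse(4, 64, gauss_dict, 5, seed=42)


def lstsq_projection(atoms_selected: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Independent least-squares oracle: orthogonal projection of each
    signal (column) onto the span of the selected atoms."""
    coef, *_ = np.linalg.lstsq(atoms_selected, signals, rcond=None)
    return atoms_selected @ coef
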