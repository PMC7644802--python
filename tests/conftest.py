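import json

import numpy as np
import pytest

from blockfold.design_model import DesignScene
from blockfold.fixtures import ToyLibraryConfig, generate_toy_library
from blockfold.module_library import load_library


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("toylib")
    generate_toy_library(ToyLibraryConfig(), out)
    return out


@pytest.fixture(scope="session")
def toy_lib(toy_dir):
    return load_library(toy_dir / "library.json")


@pytest.fixture(scope="session")
def ground_truth(toy_dir):
    with open(toy_dir / "ground_truth.json") as fh:
        return json.load(fh)


@pytest.fixture()
def scene(toy_lib):
    return DesignScene(toy_lib)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random proper rotation (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
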