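import numpy as np
import pytest

from fieldpot import AtomicSystem, FeatureParams, FieldModel
from fieldpot.synthetic import ToyModelParams, gen_polarizable_molecule_dataset


@pytest.fixture(scope="session")
def toy():
    return ToyModelParams()


@pytest.fixture(scope="session")
def feat_small():
    return FeatureParams(r_c=3.0, L=2, n_rad=4, n_features=6, seed=1)


@pytest.fixture(scope="session")
def molecule_records(toy):
    return gen_polarizable_molecule_dataset(toy, 24, seed=5)


@pytest.fixture(scope="session")
def model_small(feat_small, molecule_records):
    """Untrained but calibrated model with one message-passing iteration."""
    model = FieldModel(("H", "O"), feat_small, hidden=10, n_iterations=1, seed=2)
    model.calibrate([r.system for r in molecule_records[:8]])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_system(rng, n_atoms=None, field_scale=0.3):
    n = int(n_atoms if n_atoms is not None else rng.integers(2, 7))
    species = tuple(rng.choice(["H", "O"], n))
    return AtomicSystem(
        species,
        rng.uniform(-1.5, 1.5, (n, 3)),
        field=rng.normal(0.0, field_scale, 3),
    )
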