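import numpy as np
import pytest

from ligandfield import fieldgen, pharmacophore, qsar, synthdata


@pytest.fixture(scope="session")
def qsar_series():
    """The default planted-truth congeneric series (deterministic seed)."""
    return synthdata.make_qsar_series()


@pytest.fixture(scope="session")
def fitted_qsar(qsar_series):
    """(FieldMatrix, FieldPLS, FieldPLSResults) for the default series."""
    mols, truth = qsar_series
    fm = fieldgen.assemble_field_matrix(mols, grid=truth["grid"],
                                        method="comsia")
    spec = qsar.FieldPLS.from_field_matrix(fm, [m.activity for m in mols])
    return fm, spec, spec.fit()


@pytest.fixture(scope="session")
def toy_complex():
    return synthdata.make_toy_complex(seed=1, n_frames=3, frame_jitter=0.02)


@pytest.fixture(scope="session")
def toy_model(toy_complex):
    return pharmacophore.perceive_features(toy_complex)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
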