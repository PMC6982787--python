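import numpy as np
import pytest

from admetnet.mol import fingerprint_matrix, mol_to_graph
from admetnet.preprocess import build_assay_matrix
from admetnet.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def tiny_study():
    """120-compound study for fast pipeline tests."""
    return generate_study(GeneratorConfig(n_compounds=120, seed=7))


@pytest.fixture(scope="session")
def tiny_matrix(tiny_study):
    matrix, molecules = build_assay_matrix(tiny_study.records, tiny_study.specs,
                                           canonical_tautomer=False)
    return matrix, molecules


@pytest.fixture(scope="session")
def tiny_fps(tiny_matrix):
    _, molecules = tiny_matrix
    return fingerprint_matrix(molecules)


@pytest.fixture(scope="session")
def tiny_graphs(tiny_matrix):
    _, molecules = tiny_matrix
    return [mol_to_graph(m) for m in molecules]


@pytest.fixture(scope="session")
def study2000():
    """Full-size synthetic study at the generator's default conditions."""
    study = generate_study(GeneratorConfig(seed=0))
    matrix, molecules = build_assay_matrix(study.records, study.specs,
                                           canonical_tautomer=False)
    return study, matrix, molecules


@pytest.fixture(scope="session")
def fps2000(study2000):
    _, _, molecules = study2000
    return fingerprint_matrix(molecules)
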