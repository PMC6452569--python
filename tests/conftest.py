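import warnings

import pytest

from laborsig import preprocess, simulate, svd

# saga emits convergence warnings at the loose tolerance used for penalty
# ranking; they are expected and drown out real failures
warnings.filterwarnings("ignore", message=".*onvergence.*")


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=1)


@pytest.fixture(scope="session")
def collection(sim_config):
    """Default three-study synthetic collection plus ground truth."""
    return simulate.generate_study_collection(sim_config)


@pytest.fixture(scope="session")
def processed(collection):
    studies, _ = collection
    return [preprocess.log_transform(preprocess.filter_genes(s)) for s in studies]


@pytest.fixture(scope="session")
def combined(processed):
    return preprocess.merge_studies(processed)


@pytest.fixture(scope="session")
def svd_result(combined):
    return svd.run_svd(combined)


@pytest.fixture(scope="session")
def gene_sets(sim_config, collection):
    _, truth = collection
    return simulate.generate_gene_sets(sim_config, truth)


@pytest.fixture(scope="session")
def network(sim_config, collection):
    _, truth = collection
    return simulate.generate_signaling_network(sim_config, truth)
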