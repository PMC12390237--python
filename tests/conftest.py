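import dataclasses

import pytest

from dualtrace import paper_scenario, simulate_experiment


@pytest.fixture(scope="session")
def paper_config():
    config, _ = paper_scenario()
    return config


@pytest.fixture(scope="session")
def paper_truth():
    _, truth = paper_scenario()
    return truth


@pytest.fixture(scope="session")
def noisefree_truth(paper_truth):
    return dataclasses.replace(paper_truth, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisefree_table(paper_config, noisefree_truth):
    return simulate_experiment(paper_config, noisefree_truth, seed=0)


@pytest.fixture(scope="session")
def noisy_table(paper_config, paper_truth):
    truth = dataclasses.replace(paper_truth, noise_cv=0.05)
    return simulate_experiment(paper_config, truth, seed=42)
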