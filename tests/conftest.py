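import pytest

from brmcda import datasets


@pytest.fixture(scope="session")
def example():
    """Shipped sinomenine assessment: tree, profiles, reproduction settings."""
    return datasets.sinomenine_example()


@pytest.fixture(scope="session")
def tree(example):
    return example.tree


@pytest.fixture(scope="session")
def published():
    return datasets.load_published_scores()
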