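import pytest

from bnstab import example1_network, example2_network, load_model


@pytest.fixture(scope="session")
def ex1():
    return example1_network()


@pytest.fixture(scope="session")
def ex2():
    return example2_network()


@pytest.fixture(scope="session")
def metastasis():
    return load_model("metastasis")


@pytest.fixture(scope="session")
def mapk():
    return load_model("mapk")
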