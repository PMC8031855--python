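import pytest

from c9allele.genemodel import build_registry, default_gene_model
from c9allele.haplomap import packaged_map


@pytest.fixture(scope="session")
def hap_map():
    return packaged_map()


@pytest.fixture(scope="session")
def model():
    return default_gene_model()


@pytest.fixture(scope="session")
def registry(model):
    return build_registry(model)
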